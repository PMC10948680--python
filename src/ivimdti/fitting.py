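"""The two IVIM-DTI parameter-estimation pipelines and SNR-based QC.

Full (IVIM-corrected) fit, three stages per study:

A. biexponential IVIM fit to the direction- and mask-averaged signal,
   yielding a shared pseudo-diffusion coefficient D*;
B. voxel-wise biexponential fit with D* fixed, yielding per-voxel
   (s0_ivim, f, D);
C. subtraction of the perfusion component
   ``S_DTI = S - s0_ivim * f * exp(-b D*)`` followed by a 7-parameter
   nonlinear tensor fit to the corrected signal over all b-values.

High-b fit: discard all measurements with b below a threshold (default
200 s/mm^2), where the perfusion compartment has decayed away, and fit
the tensor directly to the remaining data — inherently IVIM-corrected,
with no perfusion-fraction estimate.

All nonlinear fits are bounded trust-region (or Levenberg-Marquardt for
the unconstrained tensor) least squares with analytic Jacobians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammaln

from .signal_model import AcquisitionScheme, DiffusionTensor, ScalarMaps
from .synthetic import DWIStudy

__all__ = [
    "FitConfig",
    "FitResult",
    "IVIMFit",
    "VoxelIVIMMaps",
    "TensorFit",
    "estimate_snr",
    "qc_exclude",
    "fit_ivim_mean",
    "fit_ivim_voxelwise",
    "subtract_ivim",
    "fit_dti_nlls",
    "dti_design",
    "pipeline_full",
    "pipeline_highb",
]


@dataclass(frozen=True)
class FitConfig:
    """Fitting thresholds, bounds and initial values.

    Diffusivities in mm^2/s. Bounds bracket reported skeletal-muscle
    values with wide margins; ``b_high_threshold = 0`` degenerates the
    high-b fit into an uncorrected all-b tensor fit (useful to expose the
    perfusion bias).
    """

    #: tol is the step/parameter convergence tolerance of the nonlinear fits;
    #: the bounded IVIM stages additionally run the gradient criterion down
    #: to 1e-14 so boundary solutions (f = 0) are resolved sharply.
    b_high_threshold: float = 200.0
    snr_exclusion_threshold: float = 20.0
    f_bounds: tuple[float, float] = (0.0, 0.4)
    d_bounds: tuple[float, float] = (0.1e-3, 4.0e-3)
    dstar_bounds: tuple[float, float] = (3e-3, 300e-3)
    f_init: float = 0.05
    d_init: float = 1.7e-3
    dstar_init: float = 30e-3
    max_iter: int = 500
    tol: float = 1e-10
    weighted_dti: bool = False
    shell_average: str = "geometric"

    def __post_init__(self) -> None:
        for name in ("f_bounds", "d_bounds", "dstar_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be ordered (lo < hi)")
        if self.b_high_threshold < 0:
            raise ValueError("b_high_threshold must be non-negative")
        if self.snr_exclusion_threshold < 0:
            raise ValueError("snr_exclusion_threshold must be non-negative")
        if self.shell_average not in ("geometric", "arithmetic"):
            raise ValueError("shell_average must be 'geometric' or 'arithmetic'")


class IVIMFit(NamedTuple):
    """Stage-A result: shared IVIM parameters of the averaged signal."""

    s0: float
    f: float
    d: float
    d_star: float
    cost: float


@dataclass
class VoxelIVIMMaps:
    """Stage-B result: per-voxel IVIM maps (grids; NaN outside the mask)."""

    s0: np.ndarray
    f: np.ndarray
    d: np.ndarray
    converged: np.ndarray
    d_star: float


class TensorFit(NamedTuple):
    tensor: DiffusionTensor
    s0: float
    converged: bool
    cost: float
    init_cost: float


@dataclass
class FitResult:
    """Per-voxel outcome maps of one method on one study."""

    maps: ScalarMaps
    s0: np.ndarray
    converged: np.ndarray
    method: str  # 'full' or 'high_b'
    snr: float
    excluded: bool
    flags: dict = field(default_factory=dict)


def _c4(n: int) -> float:
    """Small-sample bias factor of the Gaussian sample SD (E[s] = c4 * sigma)."""
    return float(np.sqrt(2.0 / (n - 1)) * np.exp(gammaln(n / 2) - gammaln((n - 1) / 2)))


def estimate_snr(study: DWIStudy, mask: np.ndarray | None = None) -> float:
    """SNR at b = 0 from the repeated unweighted volumes.

    Ratio of the mask-mean b = 0 signal to the mask-mean per-voxel SD
    across the b = 0 repeats, the SD corrected for small-sample bias.
    Returns ``inf`` for noise-free data.
    """
    mask = study.mask_union() if mask is None else np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    b0 = study.scheme.bvals == 0
    n_rep = int(b0.sum())
    if n_rep < 2:
        raise ValueError(f"need >= 2 b = 0 volumes to estimate SNR, got {n_rep}")
    vols = study.signal[mask][:, b0]
    mean_signal = float(vols.mean(axis=1).mean())
    mean_sd = float((vols.std(axis=1, ddof=1) / _c4(n_rep)).mean())
    if mean_sd == 0.0:
        return np.inf
    return mean_signal / mean_sd


def qc_exclude(snr: float, config: FitConfig | None = None) -> bool:
    """True (exclude the study) iff SNR is strictly below the threshold."""
    if snr < 0:
        raise ValueError("SNR must be non-negative")
    threshold = (config or FitConfig()).snr_exclusion_threshold
    return snr < threshold


def _biexp_residual_jac(b: np.ndarray, data: np.ndarray):
    """Residual/Jacobian pair for the 4-parameter biexponential."""

    def fun(x):
        s0, f, d, ds = x
        return s0 * ((1 - f) * np.exp(-b * d) + f * np.exp(-b * ds)) - data

    def jac(x):
        s0, f, d, ds = x
        ed, es = np.exp(-b * d), np.exp(-b * ds)
        return np.column_stack(
            [(1 - f) * ed + f * es, s0 * (es - ed), -s0 * (1 - f) * b * ed, -s0 * f * b * es]
        )

    return fun, jac


def fit_ivim_mean(
    study: DWIStudy,
    mask: np.ndarray | None = None,
    config: FitConfig | None = None,
) -> IVIMFit:
    """Stage A: IVIM fit to the direction- and mask-averaged signal.

    The signal is averaged over the mask (both legs by default) and over
    directions within each b-shell, then fitted to
    ``s0 [(1-f) exp(-b D) + f exp(-b D*)]`` by bounded least squares.
    """
    config = config or FitConfig()
    mask = study.mask_union() if mask is None else np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    bu, shell = study.scheme.shell_average(
        study.signal[mask].mean(axis=0), kind=config.shell_average
    )
    if bu.size < 4:
        raise ValueError(f"need >= 4 distinct b-values, got {bu.size}")
    s0_init = float(shell.max())
    x0 = np.array([s0_init, config.f_init, config.d_init, config.dstar_init])
    lo = np.array([1e-12, config.f_bounds[0], config.d_bounds[0], config.dstar_bounds[0]])
    hi = np.array([np.inf, config.f_bounds[1], config.d_bounds[1], config.dstar_bounds[1]])
    fun, jac = _biexp_residual_jac(bu, shell)
    res = least_squares(
        fun, x0, jac=jac, bounds=(lo, hi), method="trf",
        xtol=config.tol, ftol=None, gtol=1e-14,
        x_scale=[max(s0_init, 1e-12), 0.1, 1e-3, 3e-2],
        max_nfev=config.max_iter,
    )
    if res.status <= 0:
        raise RuntimeError(
            f"stage-A IVIM fit did not converge: status={res.status}, "
            f"message='{res.message}', cost={res.cost:.3e}"
        )
    s0, f, d, ds = res.x
    return IVIMFit(s0=float(s0), f=float(f), d=float(d), d_star=float(ds), cost=float(res.cost))


def fit_ivim_voxelwise(
    study: DWIStudy,
    d_star_fixed: float,
    mask: np.ndarray | None = None,
    config: FitConfig | None = None,
) -> VoxelIVIMMaps:
    """Stage B: per-voxel (s0, f, D) with the pseudo-diffusion D* held fixed.

    Operates on the direction-averaged per-shell signal of each voxel.
    Non-converged voxels are flagged, not fatal.
    """
    config = config or FitConfig()
    mask = study.mask_union() if mask is None else np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if not d_star_fixed > 0:
        raise ValueError("d_star_fixed must be positive")
    bu, shells = study.scheme.shell_average(
        study.signal[mask], kind=config.shell_average
    )

    grid = study.grid_shape
    s0_map = np.full(grid, np.nan)
    f_map = np.full(grid, np.nan)
    d_map = np.full(grid, np.nan)
    conv = np.zeros(grid, dtype=bool)
    idx = np.argwhere(mask)

    es = np.exp(-bu * d_star_fixed)
    lo = np.array([1e-12, config.f_bounds[0], config.d_bounds[0]])
    hi = np.array([np.inf, config.f_bounds[1], config.d_bounds[1]])
    for k, (i, j, l) in enumerate(idx):
        data = shells[k]
        if not np.any(data > 0):
            continue  # degenerate voxel stays NaN / unconverged

        def fun(x, data=data):
            s0, f, d = x
            return s0 * ((1 - f) * np.exp(-bu * d) + f * es) - data

        def jac(x, data=data):
            s0, f, d = x
            ed = np.exp(-bu * d)
            return np.column_stack(
                [(1 - f) * ed + f * es, s0 * (es - ed), -s0 * (1 - f) * bu * ed]
            )

        x0 = np.array([max(float(data.max()), 1e-9), config.f_init, config.d_init])
        res = least_squares(
            fun, x0, jac=jac, bounds=(lo, hi), method="trf",
            xtol=config.tol, ftol=None, gtol=1e-14,
            x_scale=[x0[0], 0.1, 1e-3], max_nfev=config.max_iter,
        )
        s0_map[i, j, l], f_map[i, j, l], d_map[i, j, l] = res.x
        conv[i, j, l] = bool(res.status > 0)
    return VoxelIVIMMaps(s0=s0_map, f=f_map, d=d_map, converged=conv, d_star=float(d_star_fixed))


def subtract_ivim(signal, scheme: AcquisitionScheme, s0_ivim, f, d_star):
    """Stage C: remove the perfusion component from the measured signal.

    ``S_DTI = S - s0_ivim * f * exp(-b D*)``, element-wise in scheme
    order. ``s0_ivim`` and ``f`` may be scalars or per-voxel arrays
    broadcast against the leading axes of ``signal``.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] != len(scheme):
        raise ValueError("signal length does not match scheme")
    perf = np.exp(-scheme.bvals * d_star)
    amp = np.asarray(s0_ivim, float) * np.asarray(f, float)
    return signal - amp[..., None] * perf


def dti_design(scheme: AcquisitionScheme) -> np.ndarray:
    """(n, 6) design matrix mapping (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) to b g^T D g."""
    b, g = scheme.bvals, scheme.bvecs
    return np.column_stack(
        [
            b * g[:, 0] ** 2,
            b * g[:, 1] ** 2,
            b * g[:, 2] ** 2,
            2 * b * g[:, 0] * g[:, 1],
            2 * b * g[:, 0] * g[:, 2],
            2 * b * g[:, 1] * g[:, 2],
        ]
    )


def _check_dti_scheme(scheme: AcquisitionScheme, design: np.ndarray) -> None:
    if len(scheme) < 7:
        raise ValueError("tensor fit needs >= 7 measurements")
    a = np.column_stack([np.ones(len(scheme)), design])
    if np.linalg.matrix_rank(a) < 7:
        raise ValueError("rank-deficient direction set: tensor is not identifiable")


def _fit_dti_prepared(
    signal: np.ndarray, design: np.ndarray, config: FitConfig
) -> TensorFit:
    """7-parameter NLLS tensor fit; assumes the scheme was already validated."""
    eps = 1e-10 * max(float(signal.max()), 1e-30)
    s = np.maximum(signal, eps)
    # weighted log-linear start (weights = signal^2, the standard WLLS choice)
    a = np.column_stack([np.ones_like(s), -design])
    w = s
    coef, *_ = np.linalg.lstsq(a * w[:, None], np.log(s) * w, rcond=None)
    coef[0] = min(coef[0], 700.0)
    x0 = np.concatenate([[np.exp(coef[0])], coef[1:]])

    weights = s if config.weighted_dti else None

    def fun(x):
        r = x[0] * np.exp(-(design @ x[1:])) - signal
        return r * weights if weights is not None else r

    def jac(x):
        e = np.exp(-(design @ x[1:]))
        j = np.empty((signal.size, 7))
        j[:, 0] = e
        j[:, 1:] = -x[0] * e[:, None] * design
        if weights is not None:
            j *= weights[:, None]
        return j

    init_cost = 0.5 * float(np.sum(fun(x0) ** 2))
    res = least_squares(
        fun, x0, jac=jac, method="lm",
        xtol=config.tol, ftol=config.tol, gtol=config.tol,
        max_nfev=config.max_iter,
    )
    dxx, dyy, dzz, dxy, dxz, dyz = res.x[1:]
    tensor = DiffusionTensor(
        np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    )
    return TensorFit(
        tensor=tensor,
        s0=float(res.x[0]),
        converged=bool(res.status > 0),
        cost=float(res.cost),
        init_cost=init_cost,
    )


def fit_dti_nlls(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
    config: FitConfig | None = None,
) -> TensorFit:
    """Nonlinear tensor fit ``s0 exp(-b g^T D g)`` to one voxel's signal.

    Initialised from the weighted log-linear estimate; the tensor is
    unconstrained (negative eigenvalues are the caller's QC concern).
    """
    config = config or FitConfig()
    signal = np.asarray(signal, dtype=float)
    if signal.shape != (len(scheme),):
        raise ValueError("signal must be a vector matching the scheme")
    design = dti_design(scheme)
    _check_dti_scheme(scheme, design)
    return _fit_dti_prepared(signal, design, config)


def _tensor_maps_from_voxels(
    grid: tuple[int, int, int],
    idx: np.ndarray,
    signals: np.ndarray,
    design: np.ndarray,
    config: FitConfig,
):
    """Run the prepared tensor fit over voxels and assemble grid maps."""
    l1 = np.full(grid, np.nan)
    l2 = np.full(grid, np.nan)
    l3 = np.full(grid, np.nan)
    s0 = np.full(grid, np.nan)
    conv = np.zeros(grid, dtype=bool)
    neg = np.zeros(grid, dtype=bool)
    for k, (i, j, l) in enumerate(idx):
        sig = signals[k]
        if not np.any(sig > 0):
            continue  # flagged NaN voxel
        tf = _fit_dti_prepared(sig, design, config)
        lam = tf.tensor.eigenvalues
        l1[i, j, l], l2[i, j, l], l3[i, j, l] = lam
        s0[i, j, l] = tf.s0
        conv[i, j, l] = tf.converged
        neg[i, j, l] = bool(lam[2] < 0)
    return l1, l2, l3, s0, conv, neg


def _scalar_maps(l1, l2, l3, f=None) -> ScalarMaps:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN outside the mask
        md = (l1 + l2 + l3) / 3.0
        lam = np.stack([l1, l2, l3], axis=-1)
        ss = np.sum(lam * lam, axis=-1)
        fa = np.sqrt(1.5 * np.sum((lam - md[..., None]) ** 2, axis=-1) / ss)
    return ScalarMaps(md=md, fa=fa, l1=l1, l2=l2, l3=l3, f=f)


def pipeline_full(
    study: DWIStudy,
    mask: np.ndarray | None = None,
    config: FitConfig | None = None,
    ivim_mask: np.ndarray | None = None,
) -> FitResult:
    """Three-stage IVIM-corrected DTI fit ("full fit").

    ``ivim_mask`` controls the stage-A averaging domain (defaults to the
    fitting mask, i.e. both muscle ROIs). The study-level SNR and its
    exclusion decision are recorded on the result; exclusion is left to
    the caller so that QC remains inspectable.
    """
    config = config or FitConfig()
    mask = study.mask_union() if mask is None else np.asarray(mask, bool)
    snr = estimate_snr(study, mask)
    excluded = qc_exclude(snr, config)

    stage_a = fit_ivim_mean(study, ivim_mask if ivim_mask is not None else mask, config)
    vox = fit_ivim_voxelwise(study, stage_a.d_star, mask, config)

    sig = study.signal[mask]
    corrected = subtract_ivim(
        sig, study.scheme, vox.s0[mask], vox.f[mask], stage_a.d_star
    )
    design = dti_design(study.scheme)
    _check_dti_scheme(study.scheme, design)
    idx = np.argwhere(mask)
    l1, l2, l3, s0, conv, neg = _tensor_maps_from_voxels(
        study.grid_shape, idx, corrected, design, config
    )
    f_map = vox.f.copy()
    f_map[~mask] = np.nan
    return FitResult(
        maps=_scalar_maps(l1, l2, l3, f=f_map),
        s0=s0,
        converged=conv & vox.converged,
        method="full",
        snr=snr,
        excluded=excluded,
        flags={
            "negative_eigenvalues": neg,
            "d_star": stage_a.d_star,
            "stage_a": stage_a._asdict(),
            "n_ivim_converged": int(vox.converged.sum()),
        },
    )


def pipeline_highb(
    study: DWIStudy,
    mask: np.ndarray | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """High-b DTI fit: tensor fit to the measurements at b >= threshold.

    The retained shells contain no perfusion signal to speak of, so no
    subtraction (and no f map) is needed; s0 is extrapolated by the fit.
    """
    config = config or FitConfig()
    mask = study.mask_union() if mask is None else np.asarray(mask, bool)
    snr = estimate_snr(study, mask) if study.scheme.n_b0 >= 2 else np.nan
    excluded = qc_exclude(snr, config) if np.isfinite(snr) or np.isinf(snr) else False

    sel = study.scheme.high_b_selection(config.b_high_threshold)
    sub = study.scheme.subset(sel)
    design = dti_design(sub)
    _check_dti_scheme(sub, design)
    idx = np.argwhere(mask)
    signals = study.signal[mask][:, sel]
    l1, l2, l3, s0, conv, neg = _tensor_maps_from_voxels(
        study.grid_shape, idx, signals, design, config
    )
    return FitResult(
        maps=_scalar_maps(l1, l2, l3, f=None),
        s0=s0,
        converged=conv,
        method="high_b",
        snr=snr,
        excluded=excluded,
        flags={"negative_eigenvalues": neg, "n_retained": int(sel.sum())},
    )
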
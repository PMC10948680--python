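"""Forward signal model and tensor algebra for IVIM-corrected diffusion MRI.

Diffusion-weighted MRI of perfused skeletal muscle is modelled as a
two-compartment intravoxel incoherent motion (IVIM) decay on top of an
anisotropic diffusion tensor:

    S(b, g) = S0 * [ (1 - f) * exp(-b * g^T D g) + f * exp(-b * D*) ]

where ``b`` is the diffusion weighting (s/mm^2), ``g`` the unit gradient
direction, ``D`` the 3x3 diffusion tensor (mm^2/s), ``f`` the signal
perfusion fraction and ``D*`` the (isotropic) pseudo-diffusion coefficient
of the microvascular compartment.

All diffusivities are carried internally in mm^2/s; the reporting layer
(:mod:`ivimdti.roi`) converts to the conventional 1e-3 mm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "DiffusionTensor",
    "IVIMParams",
    "ScalarMaps",
    "mean_diffusivity",
    "fractional_anisotropy",
    "ivim_dti_signal",
    "perfusion_component",
]

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class AcquisitionScheme:
    """Ordered list of diffusion measurements: b-values with unit directions.

    Parameters
    ----------
    bvals : (n,) array
        Diffusion weightings in s/mm^2, all non-negative.
    bvecs : (n, 3) array
        Gradient directions; unit vectors wherever ``b > 0``. Rows at
        ``b = 0`` may be zero.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.array(self.bvals, dtype=float)
        bvecs = np.array(self.bvecs, dtype=float)
        if bvals.ndim != 1:
            raise ValueError("bvals must be one-dimensional")
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvecs must have shape ({bvals.size}, 3), got {bvecs.shape}"
            )
        if not (np.all(np.isfinite(bvals)) and np.all(np.isfinite(bvecs))):
            raise ValueError("scheme contains non-finite entries")
        if np.any(bvals < 0):
            raise ValueError("negative b-values are not allowed")
        norms = np.linalg.norm(bvecs, axis=1)
        bad = (bvals > 0) & (np.abs(norms - 1.0) > _UNIT_TOL)
        if np.any(bad):
            idx = np.flatnonzero(bad).tolist()
            raise ValueError(f"non-unit gradient direction(s) at index {idx}")
        bvals.setflags(write=False)
        bvecs.setflags(write=False)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def n_b0(self) -> int:
        """Number of unweighted (b = 0) measurements."""
        return int(np.count_nonzero(self.bvals == 0))

    @property
    def unique_bvals(self) -> np.ndarray:
        """Sorted unique b-values (the shells)."""
        return np.unique(self.bvals)

    def subset(self, sel: np.ndarray) -> "AcquisitionScheme":
        """Scheme restricted to a boolean or index selection, order preserved."""
        sel = np.asarray(sel)
        return AcquisitionScheme(self.bvals[sel], self.bvecs[sel])

    def high_b_selection(self, threshold: float) -> np.ndarray:
        """Boolean mask of the measurements retained at ``b >= threshold``."""
        return self.bvals >= threshold

    def shell_average(
        self, signals: np.ndarray, kind: str = "arithmetic"
    ) -> tuple[np.ndarray, np.ndarray]:
        """Direction average of ``signals`` within each b-shell.

        ``signals`` has the measurement axis last; returns ``(unique_b,
        averaged)`` with the averaged array's last axis ordered by
        ascending b. ``kind='geometric'`` averages in the log domain
        (trace-weighted mean: for a balanced direction set the tensor
        compartment averages to exactly ``exp(-b * MD)``); signals are
        clipped to a small positive floor first.
        """
        signals = np.asarray(signals, dtype=float)
        if signals.shape[-1] != len(self):
            raise ValueError("signal length does not match scheme")
        bu = self.unique_bvals
        if kind == "arithmetic":
            shells = [signals[..., self.bvals == b].mean(axis=-1) for b in bu]
        elif kind == "geometric":
            logs = np.log(np.maximum(signals, 1e-300))
            shells = [np.exp(logs[..., self.bvals == b].mean(axis=-1)) for b in bu]
        else:
            raise ValueError(f"unknown shell average kind {kind!r}")
        return bu, np.stack(shells, axis=-1)


@dataclass(frozen=True)
class DiffusionTensor:
    """Symmetric 3x3 diffusion tensor with descending-ordered eigenvalues."""

    matrix: np.ndarray
    eigenvalues: np.ndarray = None  # type: ignore[assignment]
    eigenvectors: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        d = np.array(self.matrix, dtype=float)
        if d.shape != (3, 3):
            raise ValueError("tensor must be 3x3")
        if not np.all(np.isfinite(d)):
            raise ValueError("tensor contains non-finite entries")
        d = 0.5 * (d + d.T)  # exact symmetry by construction
        evals, evecs = np.linalg.eigh(d)
        order = np.argsort(evals)[::-1]  # lambda1 >= lambda2 >= lambda3
        evals = evals[order]
        evecs = evecs[:, order]
        for a in (d, evals, evecs):
            a.setflags(write=False)
        object.__setattr__(self, "matrix", d)
        object.__setattr__(self, "eigenvalues", evals)
        object.__setattr__(self, "eigenvectors", evecs)

    @classmethod
    def from_eigen(
        cls, eigenvalues: np.ndarray, eigenvectors: np.ndarray | None = None
    ) -> "DiffusionTensor":
        """Compose a tensor from eigenvalues and an orthonormal frame.

        ``eigenvectors`` columns are the principal axes; defaults to the
        laboratory frame.
        """
        lam = np.asarray(eigenvalues, dtype=float)
        if lam.shape != (3,):
            raise ValueError("need exactly three eigenvalues")
        v = np.eye(3) if eigenvectors is None else np.asarray(eigenvectors, float)
        return cls((v * lam) @ v.T)

    @property
    def md(self) -> float:
        return float(self.eigenvalues.mean())

    @property
    def fa(self) -> float:
        return float(fractional_anisotropy(*self.eigenvalues))


@dataclass(frozen=True)
class IVIMParams:
    """Perfusion compartment: fraction ``f``, pseudo-diffusion ``D*`` (mm^2/s)
    and the IVIM signal amplitude at b = 0."""

    f: float
    d_star: float
    s0_ivim: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f < 1.0):
            raise ValueError(f"perfusion fraction must be in [0, 1), got {self.f}")
        if not self.d_star > 0:
            raise ValueError(f"pseudo-diffusion D* must be positive, got {self.d_star}")
        if not self.s0_ivim > 0:
            raise ValueError(f"s0_ivim must be positive, got {self.s0_ivim}")


@dataclass
class ScalarMaps:
    """Per-voxel outcome maps in internal units (mm^2/s; FA and f unitless).

    ``f`` is only populated by the IVIM-corrected full fit; the high-b fit
    has no perfusion estimate by construction.
    """

    md: np.ndarray
    fa: np.ndarray
    l1: np.ndarray
    l2: np.ndarray
    l3: np.ndarray
    f: np.ndarray | None = None

    def as_dict(self) -> dict[str, np.ndarray]:
        out = {"md": self.md, "fa": self.fa, "l1": self.l1, "l2": self.l2, "l3": self.l3}
        if self.f is not None:
            out["f"] = self.f
        return out


def mean_diffusivity(l1, l2, l3):
    """Arithmetic mean of the three tensor eigenvalues (same units as input)."""
    l1, l2, l3 = (np.asarray(x, dtype=float) for x in (l1, l2, l3))
    if not all(np.all(np.isfinite(x)) for x in (l1, l2, l3)):
        raise ValueError("eigenvalues must be finite")
    md = (l1 + l2 + l3) / 3.0
    return md if md.ndim else float(md)

def fractional_anisotropy(l1, l2, l3):
    """FA = sqrt(3/2) * sqrt(sum((lambda_i - MD)^2) / sum(lambda_i^2)).

    Lies in [0, 1] for non-negative eigenvalues; 0 for exact isotropy.
    Negative eigenvalues are used as-is (QC flagging is the fitting
    layer's job), in which case the value may exceed 1.
    """
    lam = np.stack(np.broadcast_arrays(*(np.asarray(x, float) for x in (l1, l2, l3))), axis=-1)
    if not np.all(np.isfinite(lam)):
        raise ValueError("eigenvalues must be finite")
    ss = np.sum(lam * lam, axis=-1)
    if np.any(ss == 0):
        raise ValueError("FA undefined for all-zero eigenvalues")
    md = lam.mean(axis=-1)
    fa = np.sqrt(1.5 * np.sum((lam - md[..., None]) ** 2, axis=-1) / ss)
    return fa if fa.ndim else float(fa)

def ivim_dti_signal(
    scheme: AcquisitionScheme,
    tensor: DiffusionTensor,
    ivim: IVIMParams,
    s0: float = 1.0,
) -> np.ndarray:
    """Noise-free two-compartment signal, one value per scheme measurement.

    ``S(b,g) = s0 * [(1-f) exp(-b g^T D g) + f exp(-b D*)]``; the amplitude
    of the perfusion term uses the shared ``s0`` (``ivim.s0_ivim`` plays its
    role when the perfusion component is handled on its own).
    """
    if not s0 > 0:
        raise ValueError("s0 must be positive")
    q = np.einsum("mi,ij,mj->m", scheme.bvecs, tensor.matrix, scheme.bvecs)
    tissue = np.exp(-scheme.bvals * q)
    perf = np.exp(-scheme.bvals * ivim.d_star)
    return s0 * ((1.0 - ivim.f) * tissue + ivim.f * perf)

def perfusion_component(b, ivim: IVIMParams) -> np.ndarray:
    """Perfusion part of the signal, ``s0_ivim * f * exp(-b * D*)``.

    This is exactly the term subtracted from the full signal in the
    IVIM-corrected DTI fit.
    """
    b = np.asarray(b, dtype=float)
    out = ivim.s0_ivim * ivim.f * np.exp(-b * ivim.d_star)
    return out if out.ndim else float(out)
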
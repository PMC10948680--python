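"""Synthetic diffusion-weighted studies of injured and contralateral muscle.

Emulates the data this analysis expects from a scanner: two "legs" on a
3D grid, an ellipsoidal injured region in one leg with elevated
diffusivities and a mirrored healthy control region in the other, a
multi-shell IVIM-DTI acquisition scheme, and Rician magnitude noise at a
target b = 0 SNR. Ground-truth generating parameters are stored with
every study so that recovery and bias are directly measurable.

Default tissue parameters are the group means and between-subject SDs of
acutely injured hamstring muscle and its contralateral control (baseline,
standard acquisition): lambda = (2.19, 1.73, 1.48) vs (2.03, 1.56, 1.34)
x 1e-3 mm^2/s, perfusion fraction f = 0.06 +/- 0.02 in both tissues.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .signal_model import AcquisitionScheme, fractional_anisotropy

__all__ = [
    "DEFAULT_SHELLS",
    "TissueSpec",
    "PhantomSpec",
    "DWIStudy",
    "fibonacci_directions",
    "balanced_directions",
    "default_scheme",
    "add_rician_noise",
    "build_phantom",
    "draw_subject_tissue",
    "simulate_cohort",
]

#: b-value (s/mm^2) -> number of gradient directions, as acquired.
DEFAULT_SHELLS: tuple[tuple[float, int], ...] = (
    (0, 8), (5, 3), (10, 3), (20, 3), (50, 3), (100, 3),
    (200, 10), (400, 10), (600, 12),
)

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def fibonacci_directions(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors from the spherical Fibonacci lattice.

    Deterministic, so the scheme is identical across runs and platforms.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = _GOLDEN_ANGLE * i
    g = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def balanced_directions(n: int, max_iter: int = 200, tol: float = 1e-14) -> np.ndarray:
    """Rotationally balanced direction set: unit vectors with isotropic
    second moments (``sum_i g_i g_i^T = n/3 * I``), like well-designed
    scanner gradient tables.

    For such a set the direction-mean of ``g^T D g`` equals MD exactly for
    every tensor, which keeps direction-averaged (trace-weighted) fits
    consistent. Built by symmetrising a spherical Fibonacci set: whiten by
    the inverse matrix square root of the second-moment matrix, re-project
    to the unit sphere, repeat until converged. Deterministic.
    """
    if n < 3:
        raise ValueError("a balanced set needs at least three directions")
    g = fibonacci_directions(n)
    if n == 3:
        # the only balanced 3-sets are orthonormal triplets: take the
        # orthogonal matrix nearest the Fibonacci triplet
        u, _, vt = np.linalg.svd(g)
        return u @ vt
    target = n / 3.0
    for _ in range(max_iter):
        m = g.T @ g
        evals, evecs = np.linalg.eigh(m)
        if np.max(np.abs(evals - target)) < tol * target:
            break
        inv_sqrt = (evecs / np.sqrt(evals)) @ evecs.T * np.sqrt(target)
        g = g @ inv_sqrt
        g /= np.linalg.norm(g, axis=1, keepdims=True)
    return g


def default_scheme() -> AcquisitionScheme:
    """The study's multi-shell scheme: 55 measurements, 8 of them at b = 0.

    Shell multiplicities follow the acquired protocol (0 x8, 5 x3, 10 x3,
    20 x3, 50 x3, 100 x3, 200 x10, 400 x10, 600 x12); directions per shell
    are rotationally balanced spherical Fibonacci point sets.
    """
    bvals, bvecs = [], []
    for b, n in DEFAULT_SHELLS:
        bvals.extend([float(b)] * n)
        if b == 0:
            bvecs.append(np.zeros((n, 3)))
        else:
            bvecs.append(balanced_directions(n))
    return AcquisitionScheme(np.array(bvals), np.vstack(bvecs))


@dataclass(frozen=True)
class TissueSpec:
    """Generating parameters of one tissue class.

    Eigenvalues and their between-subject SDs are in mm^2/s (descending
    order); ``voxel_cv`` is the within-ROI eigenvalue jitter (coefficient
    of variation) and ``dispersion_deg`` the SD of the per-voxel fibre
    orientation scatter around ``orientation``.
    """

    label: str
    eigenvalues: tuple[float, float, float]
    eigenvalue_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)
    f_mean: float = 0.06
    f_sd: float = 0.02
    d_star: float = 30e-3
    orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    dispersion_deg: float = 10.0
    voxel_cv: float = 0.02

    def __post_init__(self) -> None:
        lam = np.asarray(self.eigenvalues, float)
        sd = np.asarray(self.eigenvalue_sd, float)
        if lam.shape != (3,) or sd.shape != (3,):
            raise ValueError("need three eigenvalue means and SDs")
        if np.any(np.diff(lam) > 0):
            raise ValueError("eigenvalue means must be ordered descending")
        if np.any(sd < 0) or self.f_sd < 0:
            raise ValueError("SDs must be non-negative")
        if not (0.0 <= self.f_mean < 1.0):
            raise ValueError("f_mean must be in [0, 1)")
        if not self.d_star > 0:
            raise ValueError("d_star must be positive")

    @classmethod
    def injured_baseline(cls, **overrides) -> "TissueSpec":
        """Acutely injured hamstring muscle, group baseline values."""
        kw = dict(
            label="injured",
            eigenvalues=(2.19e-3, 1.73e-3, 1.48e-3),
            eigenvalue_sd=(0.14e-3, 0.15e-3, 0.15e-3),
            f_mean=0.06,
            f_sd=0.02,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def healthy_baseline(cls, **overrides) -> "TissueSpec":
        """Contralateral healthy hamstring muscle, group baseline values."""
        kw = dict(
            label="healthy",
            eigenvalues=(2.03e-3, 1.56e-3, 1.34e-3),
            eigenvalue_sd=(0.14e-3, 0.09e-3, 0.10e-3),
            f_mean=0.06,
            f_sd=0.02,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, acquisition and noise level of one synthetic study.

    Two cylindrical legs on an (nx, ny, nz) grid; the injured region is an
    ellipsoid centred in the left leg spanning up to ``n_injury_slices``
    axial slices (clipped to the grid), mirrored into the right leg as the
    healthy control region.
    """

    shape: tuple[int, int, int] = (32, 32, 8)
    leg_radius: float = 6.0
    injury_semiaxes: tuple[float, float] = (4.0, 4.0)
    n_injury_slices: int = 14
    scheme: AcquisitionScheme | None = None
    snr: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be three positive integers")
        if not self.snr > 0:
            raise ValueError("snr must be positive (np.inf for noise-free)")
        if self.leg_radius <= 0 or any(a <= 0 for a in self.injury_semiaxes):
            raise ValueError("geometry parameters must be positive")


@dataclass
class DWIStudy:
    """A 4D diffusion-weighted study with its scheme, masks and truth maps."""

    signal: np.ndarray
    scheme: AcquisitionScheme
    masks: dict[str, np.ndarray]
    truth: dict[str, np.ndarray] | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, measurement)")
        if self.signal.shape[-1] != len(self.scheme):
            raise ValueError(
                f"signal has {self.signal.shape[-1]} volumes but the scheme "
                f"lists {len(self.scheme)} measurements"
            )
        grid = self.signal.shape[:3]
        for name, m in self.masks.items():
            m = np.asarray(m)
            if m.shape != grid:
                raise ValueError(f"mask '{name}' shape {m.shape} != grid {grid}")
            self.masks[name] = m.astype(bool)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    def mask_union(self) -> np.ndarray:
        """Union of all named masks (the default fitting domain)."""
        out = np.zeros(self.grid_shape, dtype=bool)
        for m in self.masks.values():
            out |= m
        return out


def add_rician_noise(signal, sigma, seed=None, rng=None):
    """Magnitude-MRI (Rician) noise: ``sqrt((S + n1)^2 + n2^2)``.

    ``n1, n2`` are independent zero-mean Gaussians with SD ``sigma``.
    Deterministic for a given ``seed`` (or pass an existing ``rng``).
    """
    signal = np.asarray(signal, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return signal.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2 ** 2)


def _base_frame(orientation: np.ndarray) -> np.ndarray:
    """Orthonormal frame whose first column is the fibre orientation."""
    e1 = np.asarray(orientation, float)
    e1 = e1 / np.linalg.norm(e1)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def _sample_voxel_tensors(rng: np.random.Generator, tissue: TissueSpec, n: int):
    """Per-voxel eigenvalues (descending, (n,3)) and tensors ((n,3,3))."""
    lam = np.asarray(tissue.eigenvalues, float)
    lam_v = lam * (1.0 + tissue.voxel_cv * rng.standard_normal((n, 3)))
    lam_v = np.sort(lam_v, axis=1)[:, ::-1]
    lam_v = np.clip(lam_v, 1e-6, None)
    frame = _base_frame(np.asarray(tissue.orientation, float))
    axes = rng.standard_normal((n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = np.deg2rad(tissue.dispersion_deg) * rng.standard_normal(n)
    rot = Rotation.from_rotvec(axes * angles[:, None]).as_matrix()
    # columns of V are the eigenvectors; first column is the jittered fibre axis
    v = np.einsum("nij,jk->nik", rot, frame)
    d = np.einsum("nik,nk,njk->nij", v, lam_v, v)
    return lam_v, d


def build_phantom(
    spec: PhantomSpec,
    injured: TissueSpec | None = None,
    healthy: TissueSpec | None = None,
) -> DWIStudy:
    """Simulate one two-leg study with an injured and a control region.

    Each leg voxel gets a tensor drawn around its tissue's eigenvalues
    (within-ROI jitter + orientation dispersion), the two-compartment
    signal is evaluated on the scheme, and Rician noise with
    ``sigma = s0 / snr`` is added. Ground-truth parameter maps are stored
    under ``study.truth``.
    """
    injured = injured if injured is not None else TissueSpec.injured_baseline()
    healthy = healthy if healthy is not None else TissueSpec.healthy_baseline()
    scheme = spec.scheme if spec.scheme is not None else default_scheme()
    if scheme.n_b0 < 1:
        raise ValueError("simulation scheme requires at least one b = 0 entry")
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape

    x, y, z = np.indices(spec.shape, dtype=float)
    cxl, cxr = (nx - 1) * 0.25, (nx - 1) * 0.75
    cy, cz = (ny - 1) * 0.5, (nz - 1) * 0.5
    left = (x - cxl) ** 2 + (y - cy) ** 2 <= spec.leg_radius ** 2
    right = (x - cxr) ** 2 + (y - cy) ** 2 <= spec.leg_radius ** 2
    ax, ay = spec.injury_semiaxes
    az = 0.5 * min(spec.n_injury_slices, nz)
    inj_mask = left & (
        ((x - cxl) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0
    )
    heal_mask = right & (
        ((x - cxr) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0
    )
    if np.any(inj_mask & heal_mask):
        raise ValueError("injured and healthy regions overlap")
    if not (inj_mask.any() and heal_mask.any()):
        raise ValueError("injured and healthy regions must both be non-empty")

    leg = left | right
    tissue_of = np.where(inj_mask, 1, 0)  # 1 = injured, 0 = healthy, within legs
    s0 = 1.0
    signal = np.zeros(spec.shape + (len(scheme),), dtype=float)
    truth = {
        k: np.full(spec.shape, np.nan)
        for k in ("l1", "l2", "l3", "md", "fa", "f", "d_star")
    }

    g, b = scheme.bvecs, scheme.bvals
    for cls_id, tissue in ((1, injured), (0, healthy)):
        vox = leg & (tissue_of == cls_id)
        n = int(vox.sum())
        if n == 0:
            continue
        lam_v, d_v = _sample_voxel_tensors(rng, tissue, n)
        q = np.einsum("mi,nij,mj->nm", g, d_v, g)
        perf = np.exp(-b * tissue.d_star)
        f = tissue.f_mean
        signal[vox] = s0 * ((1.0 - f) * np.exp(-b[None, :] * q) + f * perf[None, :])
        truth["l1"][vox], truth["l2"][vox], truth["l3"][vox] = lam_v.T
        truth["md"][vox] = lam_v.mean(axis=1)
        truth["fa"][vox] = fractional_anisotropy(lam_v[:, 0], lam_v[:, 1], lam_v[:, 2])
        truth["f"][vox] = f
        truth["d_star"][vox] = tissue.d_star

    sigma = 0.0 if np.isinf(spec.snr) else s0 / spec.snr
    signal = add_rician_noise(signal, sigma, rng=rng)

    return DWIStudy(
        signal=signal,
        scheme=scheme,
        masks={"injured": inj_mask, "healthy": heal_mask},
        truth=truth,
    )


def draw_subject_tissue(rng: np.random.Generator, tissue: TissueSpec) -> TissueSpec:
    """One subject's tissue parameters drawn from the group distribution.

    Eigenvalue means are Gaussian around the group means (re-sorted
    descending after the draw); ``f`` is Gaussian, clipped to [0, 0.39].
    """
    lam = np.asarray(tissue.eigenvalues) + np.asarray(tissue.eigenvalue_sd) * (
        rng.standard_normal(3)
    )
    lam = np.clip(np.sort(lam)[::-1], 1e-6, None)
    f = float(np.clip(rng.normal(tissue.f_mean, tissue.f_sd), 0.0, 0.39))
    return dataclasses.replace(tissue, eigenvalues=tuple(lam), f_mean=f)


def simulate_cohort(
    n_subjects: int,
    injured: TissueSpec | None = None,
    healthy: TissueSpec | None = None,
    scheme: AcquisitionScheme | None = None,
    snr: float = 45.0,
    seed: int = 0,
    shape: tuple[int, int, int] = (32, 32, 8),
    leg_radius: float = 6.0,
    injury_semiaxes: tuple[float, float] = (4.0, 4.0),
    n_injury_slices: int = 14,
) -> list[DWIStudy]:
    """Paired cohort: each subject has an injured and a contralateral ROI.

    Per-subject tissue means are drawn from the between-subject
    distributions of the two TissueSpecs; everything is reproducible from
    ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    injured = injured if injured is not None else TissueSpec.injured_baseline()
    healthy = healthy if healthy is not None else TissueSpec.healthy_baseline()
    root = np.random.default_rng(seed)
    studies = []
    for _ in range(n_subjects):
        inj_s = draw_subject_tissue(root, injured)
        heal_s = draw_subject_tissue(root, healthy)
        sub_seed = int(root.integers(0, 2**31 - 1))
        spec = PhantomSpec(
            shape=shape,
            leg_radius=leg_radius,
            injury_semiaxes=injury_semiaxes,
            n_injury_slices=n_injury_slices,
            scheme=scheme,
            snr=snr,
            seed=sub_seed,
        )
        studies.append(build_phantom(spec, inj_s, heal_s))
    return studies
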
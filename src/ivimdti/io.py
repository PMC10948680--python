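"""NIfTI / FSL bval-bvec input and output.

On-disk layout follows the de-facto diffusion-MRI conventions: a 4D
NIfTI for the signal, one row of b-values and three rows of direction
components in whitespace-separated text files, binary NIfTI masks on the
same grid, and one NIfTI per fitted parameter map (reporting units) plus
a ``qc.json`` sidecar.
"""

from __future__ import annotations

import hashlib
import json
import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .fitting import FitConfig, FitResult
from .roi import REPORT_SCALE
from .signal_model import AcquisitionScheme
from .synthetic import DWIStudy

__all__ = [
    "read_bval_bvec",
    "write_bval_bvec",
    "read_dwi",
    "write_study",
    "write_maps",
    "config_hash",
]

_BVEC_TOL = 1e-3


def read_bval_bvec(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-convention b-value / b-vector text files.

    ``bval``: one whitespace-separated row; ``bvec``: three rows (x, y, z
    components). Directions at b > 0 are re-normalised to unit length;
    deviations beyond 1e-3, or zero vectors, are errors naming the file
    and the offending indices.
    """
    bvals = np.atleast_1d(np.loadtxt(bval_path, dtype=float))
    bvecs = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        pass  # FSL row convention assumed: rows are components
    if bvecs.shape != (bvals.size, 3):
        raise ValueError(
            f"{bvec_path}: expected 3 rows x {bvals.size} columns, got {bvecs.shape}"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    weighted = bvals > 0
    zero = weighted & (norms == 0)
    if np.any(zero):
        raise ValueError(
            f"{bvec_path}: zero direction at weighted measurement index "
            f"{np.flatnonzero(zero).tolist()}"
        )
    off = weighted & (np.abs(norms - 1.0) > _BVEC_TOL)
    if np.any(off):
        raise ValueError(
            f"{bvec_path}: non-unit direction (|norm - 1| > {_BVEC_TOL}) at index "
            f"{np.flatnonzero(off).tolist()}"
        )
    bvecs = bvecs.copy()
    bvecs[weighted] /= norms[weighted, None]
    bvecs[~weighted] = 0.0
    return bvals, bvecs


def write_bval_bvec(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.17g")


def read_dwi(
    dwi_path, bval_path, bvec_path, mask_paths: dict[str, str] | None = None
) -> DWIStudy:
    """Assemble a study from a 4D NIfTI plus bval/bvec (and optional masks)."""
    img = nib.load(str(dwi_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{dwi_path}: expected a 4D volume, got {data.ndim}D")
    bvals, bvecs = read_bval_bvec(bval_path, bvec_path)
    if bvals.size != data.shape[-1]:
        raise ValueError(
            f"{bval_path}: {bvals.size} b-values but {dwi_path} holds "
            f"{data.shape[-1]} volumes"
        )
    masks = {}
    for name, path in (mask_paths or {}).items():
        m = np.asarray(nib.load(str(path)).get_fdata())
        if m.shape != data.shape[:3]:
            raise ValueError(
                f"{path}: mask shape {m.shape} does not match grid {data.shape[:3]}"
            )
        masks[name] = m > 0.5
    return DWIStudy(
        signal=data,
        scheme=AcquisitionScheme(bvals, bvecs),
        masks=masks,
        affine=np.asarray(img.affine),
    )


def _save_nifti(data: np.ndarray, affine: np.ndarray, path: Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def write_study(study: DWIStudy, out_dir, config: dict | None = None) -> Path:
    """Write a simulated study: signal, scheme, masks, truth maps, config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _save_nifti(study.signal, study.affine, out / "dwi.nii.gz")
    write_bval_bvec(study.scheme, out / "dwi.bval", out / "dwi.bvec")
    for name, m in study.masks.items():
        nib.save(
            nib.Nifti1Image(m.astype(np.uint8), study.affine),
            str(out / f"mask_{name}.nii.gz"),
        )
    for name, m in (study.truth or {}).items():
        _save_nifti(m, study.affine, out / f"truth_{name}.nii.gz")
    if config is not None:
        (out / "spec.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    return out


def config_hash(config: FitConfig) -> str:
    """Stable hash of the fit configuration, embedded in every output."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_maps(
    result: FitResult,
    out_dir,
    affine: np.ndarray | None = None,
    config: FitConfig | None = None,
    seed: int | None = None,
) -> Path:
    """One NIfTI per parameter map (reporting units) plus a qc.json sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    config = config or FitConfig()
    maps = result.maps.as_dict()
    for name, m in maps.items():
        _save_nifti(m * REPORT_SCALE[name], affine, out / f"{name}.nii.gz")
    _save_nifti(result.s0, affine, out / "s0.nii.gz")
    neg = result.flags.get("negative_eigenvalues")
    qc = {
        "method": result.method,
        "snr": None if not np.isfinite(result.snr) else float(result.snr),
        "snr_is_infinite": bool(np.isinf(result.snr)),
        "snr_exclusion_threshold": config.snr_exclusion_threshold,
        "excluded": bool(result.excluded),
        "n_voxels_fit": int(np.isfinite(maps["md"]).sum()),
        "n_converged": int(result.converged.sum()),
        "n_negative_eigenvalues": int(neg.sum()) if neg is not None else 0,
        "seed": seed,
        "config_hash": config_hash(config),
    }
    (out / "qc.json").write_text(json.dumps(qc, indent=2, sort_keys=True))
    return out
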
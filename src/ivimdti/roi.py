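"""ROI aggregation and the injured-minus-healthy sensitivity measure.

Outcome parameters are averaged over a segmentation mask
(segmentation-averaged MD, FA, eigenvalues, f) and reported in the
conventional units: diffusivities in 1e-3 mm^2/s, FA and f unitless.
The per-subject sensitivity to injury is the difference
``delta = injured - healthy`` of these ROI means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .fitting import FitResult

__all__ = ["ROIStats", "SensitivityDelta", "roi_means", "roi_means_from_maps", "delta_sensitivity"]

logger = logging.getLogger(__name__)

#: internal (mm^2/s) -> reporting scale per parameter
REPORT_SCALE = {"md": 1e3, "l1": 1e3, "l2": 1e3, "l3": 1e3, "fa": 1.0, "f": 1.0}


@dataclass(frozen=True)
class ROIStats:
    """Mask-averaged parameters of one muscle (reporting units)."""

    values: dict[str, float]
    n_voxels: int
    n_excluded: int
    method: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.n_voxels <= 0:
            raise ValueError("ROI must contain at least one voxel")


@dataclass(frozen=True)
class SensitivityDelta:
    """Per-parameter injured-minus-healthy difference for one subject."""

    deltas: dict[str, float]
    method: str | None = None
    subject: str | int | None = None
    timepoint: str | None = None


def roi_means_from_maps(
    maps: dict[str, np.ndarray], mask: np.ndarray, method: str | None = None,
    label: str | None = None,
) -> ROIStats:
    """Arithmetic mask-mean of already-scaled parameter maps.

    NaN voxels (flagged by the fit) are excluded from the averages and
    counted; a warning is raised when they exceed half the ROI.
    """
    mask = np.asarray(mask, bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask is empty")
    values: dict[str, float] = {}
    n_excluded = 0
    for name, m in maps.items():
        vals = np.asarray(m, float)[mask]
        finite = np.isfinite(vals)
        if not finite.any():
            raise ValueError(f"no finite voxels for parameter '{name}' in the ROI")
        values[name] = float(vals[finite].mean())
        n_excluded = max(n_excluded, int((~finite).sum()))
    if n_excluded > 0.5 * n:
        warnings.warn(
            f"{n_excluded}/{n} ROI voxels are QC-flagged; the ROI mean may be unreliable",
            stacklevel=2,
        )
    return ROIStats(values=values, n_voxels=n, n_excluded=n_excluded, method=method, label=label)


def roi_means(result: FitResult, mask: np.ndarray, label: str | None = None) -> ROIStats:
    """Segmentation-averaged parameters of a fit result, in reporting units."""
    mask = np.asarray(mask, bool)
    internal = result.maps.as_dict()
    if mask.shape != internal["md"].shape:
        raise ValueError("mask shape does not match the parameter maps")
    scaled = {k: v * REPORT_SCALE[k] for k, v in internal.items()}
    return roi_means_from_maps(scaled, mask, method=result.method, label=label)


def delta_sensitivity(
    injured: ROIStats,
    healthy: ROIStats,
    subject: str | int | None = None,
    timepoint: str | None = None,
) -> SensitivityDelta:
    """Element-wise ``injured - healthy`` over the parameters both ROIs share.

    Parameters present on only one side (e.g. f for the high-b method)
    are omitted and logged.
    """
    if injured.method is not None and healthy.method is not None:
        if injured.method != healthy.method:
            raise ValueError(
                f"method mismatch: {injured.method!r} vs {healthy.method!r}"
            )
    common = [k for k in injured.values if k in healthy.values]
    skipped = set(injured.values) ^ set(healthy.values)
    if skipped:
        logger.info("delta_sensitivity: omitting unmatched parameter(s) %s", sorted(skipped))
    deltas = {k: injured.values[k] - healthy.values[k] for k in common}
    return SensitivityDelta(
        deltas=deltas, method=injured.method or healthy.method,
        subject=subject, timepoint=timepoint,
    )
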
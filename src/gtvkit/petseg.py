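"""Contrast-oriented adaptive-threshold PET tumour segmentation.

The segmentation threshold is a linear function of two measured uptake
levels: the mean SUV over the 70 %-of-SUV_max isocontour set inside a
user-supplied tumour ROI, and the mean SUV of a background region,

    T = a * mean70 + b * BG

with scanner-specific coefficients (a, b) obtained by least squares from
phantom measurements of spheres with known volume.  The tumour mask is the
set of ROI voxels with SUV >= T, post-processed (by default) to the largest
26-connected component so that satellite physiologic-uptake blobs inside
the ROI are suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import Modality, ObserverRole, StructureMask, VoxelGrid

__all__ = [
    "PETVolume",
    "ROI",
    "SUVStats",
    "ThresholdResult",
    "suv_stats",
    "schaefer_threshold",
    "segment_pet",
    "calibrate_coefficients",
    "background_shell",
    "DegenerateThresholdError",
]

ISOCONTOUR_FRACTION = 0.70


class DegenerateThresholdError(ValueError):
    """Threshold falls outside (0, SUV_max): segmentation would be empty or all-ROI."""


@dataclass
class PETVolume:
    """SUV scalar field on a voxel grid plus the two scanner calibration slopes."""

    grid: VoxelGrid
    suv: np.ndarray
    coeff_a: float
    coeff_b: float

    def __post_init__(self) -> None:
        self.suv = np.asarray(self.suv, dtype=float)
        if self.suv.shape != self.grid.dims:
            raise ValueError("SUV array shape does not match grid dims")
        if not np.all(np.isfinite(self.suv)) or np.any(self.suv < 0):
            raise ValueError("SUV values must be finite and non-negative")
        if not (np.isfinite(self.coeff_a) and np.isfinite(self.coeff_b)):
            raise ValueError("calibration coefficients must be finite")


@dataclass
class ROI:
    """Tumour search region and disjoint background region on the PET grid."""

    tumour: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        self.tumour = np.asarray(self.tumour, dtype=bool)
        self.background = np.asarray(self.background, dtype=bool)
        if not self.tumour.any():
            raise ValueError("empty ROI")
        if not self.background.any():
            raise ValueError("empty background ROI")
        if (self.tumour & self.background).any():
            raise ValueError("tumour ROI and background ROI must be disjoint")


@dataclass(frozen=True)
class SUVStats:
    suv_max: float
    mean70: float
    n70: int  # voxels in the 70 % isocontour set


@dataclass(frozen=True)
class ThresholdResult:
    """Adaptive threshold with its audit trail."""

    threshold: float
    suv_max: float
    mean70: float
    background_mean: float
    coeff_a: float
    coeff_b: float

    def as_dict(self) -> dict[str, float]:
        return {
            "threshold": self.threshold,
            "suv_max": self.suv_max,
            "mean70": self.mean70,
            "background_mean": self.background_mean,
            "coeff_a": self.coeff_a,
            "coeff_b": self.coeff_b,
        }


def suv_stats(pet: PETVolume, roi: ROI) -> SUVStats:
    """SUV_max in the tumour ROI and the mean over its 70 % isocontour set.

    The isocontour set (voxels with SUV >= 0.70 * SUV_max) always contains
    the maximum voxel, so mean70 is well defined.
    """
    vals = pet.suv[roi.tumour]
    suv_max = float(vals.max())
    iso = vals[vals >= ISOCONTOUR_FRACTION * suv_max]
    return SUVStats(suv_max=suv_max, mean70=float(iso.mean()), n70=int(iso.size))


def schaefer_threshold(pet: PETVolume, roi: ROI) -> ThresholdResult:
    """Adaptive threshold T = a * mean70 + b * background_mean (SUV units)."""
    stats = suv_stats(pet, roi)
    bg = float(pet.suv[roi.background].mean())
    t = pet.coeff_a * stats.mean70 + pet.coeff_b * bg
    if t <= 0 or t >= stats.suv_max:
        raise DegenerateThresholdError(
            f"degenerate threshold T={t:.4g} outside (0, SUV_max={stats.suv_max:.4g})"
        )
    return ThresholdResult(
        threshold=float(t),
        suv_max=stats.suv_max,
        mean70=stats.mean70,
        background_mean=bg,
        coeff_a=pet.coeff_a,
        coeff_b=pet.coeff_b,
    )


# 26-connectivity in 3-D
_CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)


def segment_pet(
    pet: PETVolume,
    roi: ROI,
    patient_id: str = "",
    keep_largest_component: bool = True,
) -> tuple[StructureMask, ThresholdResult]:
    """Segment the tumour: ROI voxels with SUV >= T, largest component kept.

    Threshold comparison is inclusive (>=).  Returns the PET structure mask
    (observer "auto") together with the threshold audit record.
    """
    result = schaefer_threshold(pet, roi)
    seg = roi.tumour & (pet.suv >= result.threshold)
    if not seg.any():
        raise ValueError("no voxels above threshold")
    if keep_largest_component:
        labels, n = ndimage.label(seg, structure=_CONNECTIVITY)
        if n > 1:
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            seg = labels == int(np.argmax(counts))
    mask = StructureMask(
        grid=pet.grid,
        voxels=seg,
        patient_id=patient_id,
        modality=Modality.PET,
        observer_id="auto",
        observer_role=ObserverRole.AUTO,
    )
    return mask, result


def calibrate_coefficients(
    phantom_measurements: list[tuple[float, float, float]],
) -> tuple[float, float, np.ndarray]:
    """Least-squares fit of the two threshold slopes from phantom data.

    Each measurement is (mean70, background_mean, true_threshold), where the
    true threshold is the SUV level that recovers the known phantom volume.
    Returns (coeff_a, coeff_b, residuals).  Requires >= 2 measurements with
    a non-collinear design.
    """
    data = np.asarray(phantom_measurements, dtype=float)
    if data.ndim != 2 or data.shape[1] != 3 or data.shape[0] < 2:
        raise ValueError("need >= 2 (mean70, background, threshold) measurements")
    design = data[:, :2]
    target = data[:, 2]
    if np.linalg.matrix_rank(design, tol=1e-10 * np.abs(design).max()) < 2:
        raise ValueError("unidentifiable calibration: collinear (mean70, background) design")
    coeffs, *_ = np.linalg.lstsq(design, target, rcond=None)
    residuals = target - design @ coeffs
    return float(coeffs[0]), float(coeffs[1]), residuals


def background_shell(
    tumour_roi: np.ndarray,
    grid: VoxelGrid,
    distance_mm: float = 12.0,
    thickness_voxels: int = 2,
) -> np.ndarray:
    """Background region builder: a shell outside the tumour ROI.

    The shell starts ``distance_mm`` outside the ROI boundary and is
    ``thickness_voxels`` voxels thick (measured in the smallest spacing).
    """
    tumour_roi = np.asarray(tumour_roi, dtype=bool)
    dist = ndimage.distance_transform_edt(~tumour_roi, sampling=grid.spacing_mm)
    thickness_mm = thickness_voxels * min(grid.spacing_mm)
    shell = (dist > distance_mm) & (dist <= distance_mm + thickness_mm)
    if not shell.any():
        raise ValueError("background shell is empty; reduce distance or enlarge grid")
    return shell
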
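"""Voxel-grid geometry and binary structure masks.

Everything downstream — concordance metrics, PET auto-segmentation, volume
statistics — operates on axis-aligned regular voxel grids.  A grid is fully
described by its integer dimensions, the physical spacing of the voxels
(mm along each axis) and the physical position of the centre of voxel
``(0, 0, 0)``.  Physical position of voxel index ``i`` along an axis is
``origin + i * spacing``; oblique orientation matrices are deliberately not
supported (they are rejected at I/O time).

A :class:`StructureMask` is a boolean field on such a grid tagged with the
study coordinates (patient, imaging modality, observer) that every
aggregation step keys on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "Modality",
    "ObserverRole",
    "VoxelGrid",
    "StructureMask",
    "RigidTransform",
    "EmptyStructureError",
    "GridMismatchError",
    "volume_cm3",
    "centroid_mm",
    "resample_to_grid",
]

GRID_TOL_MM = 1e-6


class Modality(str, Enum):
    """Imaging modality a contour was delineated on."""

    CT = "CT"
    MR = "MR"
    CTMR = "CTMR"
    PET = "PET"


class ObserverRole(str, Enum):
    RADIOLOGIST = "radiologist"
    ONCOLOGIST = "oncologist"
    AUTO = "auto"  # algorithmic PET segmentation, not a human observer


class EmptyStructureError(ValueError):
    """Raised when an operation requires a non-empty mask."""


class GridMismatchError(ValueError):
    """Raised when two masks are compared on incompatible grids."""


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned regular voxel grid.

    Parameters
    ----------
    dims
        Number of voxels along (x, y, z); all >= 1.
    spacing_mm
        Physical voxel size in mm along each axis; all > 0.
    origin_mm
        Physical position (mm) of the centre of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positives, got {self.spacing_mm}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    def compatible_with(self, other: "VoxelGrid", tol: float = GRID_TOL_MM) -> bool:
        """True iff dims equal and spacing/origin agree within ``tol`` mm."""
        return (
            self.dims == other.dims
            and all(abs(a - b) <= tol for a, b in zip(self.spacing_mm, other.spacing_mm))
            and all(abs(a - b) <= tol for a, b in zip(self.origin_mm, other.origin_mm))
        )

    def index_to_mm(self, index: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of voxel-centre indices (..., 3)."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin_mm) + index * np.asarray(self.spacing_mm)

    def mm_to_index(self, coords_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel index of physical coordinates (..., 3)."""
        coords_mm = np.asarray(coords_mm, dtype=float)
        return (coords_mm - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)


@dataclass
class StructureMask:
    """Binary 3-D structure (GTV) on a voxel grid, with study coordinates."""

    grid: VoxelGrid
    voxels: np.ndarray
    patient_id: str = ""
    modality: Modality = Modality.CT
    observer_id: str = ""
    observer_role: ObserverRole = ObserverRole.ONCOLOGIST

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {self.voxels.shape} does not match grid dims {self.grid.dims}"
            )
        self.modality = Modality(self.modality)
        self.observer_role = ObserverRole(self.observer_role)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    def label(self) -> str:
        return f"{self.patient_id}/{self.modality.value}/{self.observer_id}"

    def with_voxels(self, voxels: np.ndarray) -> "StructureMask":
        return replace(self, voxels=np.asarray(voxels, dtype=bool))


@dataclass(frozen=True)
class RigidTransform:
    """4x4 homogeneous rigid transform mapping source-frame mm to target-frame mm."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))
    source_frame: str = ""
    target_frame: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        object.__setattr__(self, "matrix", m)
        self.validate()

    def validate(self, tol: float = 1e-6) -> None:
        m = self.matrix
        r = m[:3, :3]
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=tol):
            raise ValueError("transform not rigid: bottom row must be [0,0,0,1]")
        if not np.allclose(r @ r.T, np.eye(3), atol=tol):
            raise ValueError("transform not rigid: rotation block not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=tol):
            raise ValueError("transform not rigid: determinant must be +1 (no reflection)")

    @classmethod
    def identity(cls, frame: str = "") -> "RigidTransform":
        return cls(np.eye(4), source_frame=frame, target_frame=frame)

    @classmethod
    def from_rotation_translation(
        cls,
        rotation: np.ndarray | None = None,
        translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
        source_frame: str = "",
        target_frame: str = "",
    ) -> "RigidTransform":
        m = np.eye(4)
        if rotation is not None:
            m[:3, :3] = np.asarray(rotation, dtype=float)
        m[:3, 3] = translation_mm
        return cls(m, source_frame=source_frame, target_frame=target_frame)

    def inverse(self) -> "RigidTransform":
        r = self.matrix[:3, :3]
        t = self.matrix[:3, 3]
        m = np.eye(4)
        m[:3, :3] = r.T
        m[:3, 3] = -r.T @ t
        return RigidTransform(m, source_frame=self.target_frame, target_frame=self.source_frame)

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        points_mm = np.asarray(points_mm, dtype=float)
        return points_mm @ self.matrix[:3, :3].T + self.matrix[:3, 3]


def volume_cm3(mask: StructureMask) -> float:
    """Volume of the structure in cm^3 (voxel count x voxel volume).

    An empty mask is allowed here and has volume 0.
    """
    return mask.n_voxels * mask.grid.voxel_volume_mm3 / 1000.0


def centroid_mm(mask: StructureMask) -> np.ndarray:
    """Unweighted centroid (geometric centre) of the true voxel centres, in mm."""
    if mask.is_empty:
        raise EmptyStructureError(f"empty structure: {mask.label()}")
    idx = np.argwhere(mask.voxels).mean(axis=0)
    return mask.grid.index_to_mm(idx)


def resample_to_grid(
    mask: StructureMask,
    transform: RigidTransform,
    target: VoxelGrid,
) -> StructureMask:
    """Resample a binary mask onto ``target`` through a rigid transform.

    Nearest-neighbour semantics: a target voxel is set iff its physical
    centre, mapped back through the inverse transform, falls inside a true
    source voxel.  Binariness is preserved exactly; an identity transform
    onto a compatible grid returns a voxel-identical mask.
    """
    transform.validate()
    if (
        target.compatible_with(mask.grid)
        and np.allclose(transform.matrix, np.eye(4), atol=GRID_TOL_MM)
    ):
        return replace(mask, grid=target, voxels=mask.voxels.copy())

    inv = transform.inverse()
    nx, ny, nz = target.dims
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    centres = target.index_to_mm(np.stack([ix, iy, iz], axis=-1).reshape(-1, 3))
    src = mask.grid.mm_to_index(inv.apply(centres))
    src_idx = np.rint(src).astype(np.int64)
    dims = np.asarray(mask.grid.dims)
    inside = np.all((src_idx >= 0) & (src_idx < dims), axis=1)
    out = np.zeros(nx * ny * nz, dtype=bool)
    sel = src_idx[inside]
    out[inside] = mask.voxels[sel[:, 0], sel[:, 1], sel[:, 2]]
    return replace(mask, grid=target, voxels=out.reshape(target.dims))
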
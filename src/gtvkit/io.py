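"""Reading and writing masks, SUV volumes, ROIs and study manifests.

Masks and SUV volumes are stored as NIfTI with an axis-aligned affine
(scale + translation only; oblique orientation matrices are rejected with
a clear error), or — for small fixtures — as a plain JSON list of true-voxel
indices.  The study manifest is a CSV inventory of
(patient, modality, observer, role, mask path) rows; PET rows reference the
already-segmented PET mask, with the SUV volume, ROI labels and threshold
audit kept alongside as separate files.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import Modality, ObserverRole, StructureMask, VoxelGrid
from .petseg import PETVolume, ROI

__all__ = [
    "save_mask_nifti",
    "load_mask_nifti",
    "save_suv_nifti",
    "load_suv_nifti",
    "save_roi_nifti",
    "load_roi_nifti",
    "mask_to_json",
    "mask_from_json",
    "save_mask_json",
    "load_mask_json",
    "load_manifest",
    "save_manifest",
    "completeness_report",
    "polygons_to_mask",
]

MANIFEST_COLUMNS = ["patient_id", "modality", "observer_id", "observer_role", "mask_path"]


# ---------------------------------------------------------------------------
# NIfTI round trip (axis-aligned affines only)
# ---------------------------------------------------------------------------

def _affine_from_grid(grid: VoxelGrid) -> np.ndarray:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = grid.spacing_mm
    affine[:3, 3] = grid.origin_mm
    return affine


def _grid_from_affine(affine: np.ndarray, shape) -> VoxelGrid:
    affine = np.asarray(affine, dtype=float)
    rot = affine[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-6):
        raise ValueError(
            "oblique orientation matrices are not supported: affine must be "
            "axis-aligned scale + translation"
        )
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise ValueError("affine must have positive scales on the diagonal")
    return VoxelGrid(
        dims=tuple(int(s) for s in shape),
        spacing_mm=tuple(float(s) for s in spacing),
        origin_mm=tuple(float(o) for o in affine[:3, 3]),
    )


def save_mask_nifti(mask: StructureMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine_from_grid(mask.grid))
    nib.save(img, str(path))


def load_mask_nifti(
    path: str | Path,
    patient_id: str = "",
    modality: Modality = Modality.CT,
    observer_id: str = "",
    observer_role: ObserverRole = ObserverRole.ONCOLOGIST,
) -> StructureMask:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    voxels = np.asarray(img.dataobj) > 0
    return StructureMask(
        grid=grid,
        voxels=voxels,
        patient_id=patient_id,
        modality=modality,
        observer_id=observer_id,
        observer_role=observer_role,
    )


def save_suv_nifti(pet: PETVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(pet.suv.astype(np.float32), _affine_from_grid(pet.grid))
    nib.save(img, str(path))


def load_suv_nifti(path: str | Path, coeff_a: float, coeff_b: float) -> PETVolume:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    return PETVolume(
        grid=grid,
        suv=np.asarray(img.dataobj, dtype=float),
        coeff_a=coeff_a,
        coeff_b=coeff_b,
    )


def save_roi_nifti(roi: ROI, grid: VoxelGrid, path: str | Path) -> None:
    """ROI stored as a label volume: 1 = tumour search region, 2 = background."""
    labels = np.zeros(grid.dims, dtype=np.uint8)
    labels[roi.tumour] = 1
    labels[roi.background] = 2
    nib.save(nib.Nifti1Image(labels, _affine_from_grid(grid)), str(path))


def load_roi_nifti(path: str | Path) -> ROI:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    return ROI(tumour=labels == 1, background=labels == 2)


# ---------------------------------------------------------------------------
# JSON fixture format: {dims, spacing, origin, true_voxels}
# ---------------------------------------------------------------------------

def mask_to_json(mask: StructureMask) -> dict:
    return {
        "dims": list(mask.grid.dims),
        "spacing_mm": list(mask.grid.spacing_mm),
        "origin_mm": list(mask.grid.origin_mm),
        "patient_id": mask.patient_id,
        "modality": mask.modality.value,
        "observer_id": mask.observer_id,
        "observer_role": mask.observer_role.value,
        "true_voxels": np.argwhere(mask.voxels).tolist(),
    }


def mask_from_json(payload: dict) -> StructureMask:
    grid = VoxelGrid(
        dims=tuple(payload["dims"]),
        spacing_mm=tuple(payload["spacing_mm"]),
        origin_mm=tuple(payload.get("origin_mm", (0.0, 0.0, 0.0))),
    )
    voxels = np.zeros(grid.dims, dtype=bool)
    idx = np.asarray(payload["true_voxels"], dtype=int)
    if idx.size:
        voxels[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return StructureMask(
        grid=grid,
        voxels=voxels,
        patient_id=payload.get("patient_id", ""),
        modality=Modality(payload.get("modality", "CT")),
        observer_id=payload.get("observer_id", ""),
        observer_role=ObserverRole(payload.get("observer_role", "oncologist")),
    )


def save_mask_json(mask: StructureMask, path: str | Path) -> None:
    Path(path).write_text(json.dumps(mask_to_json(mask), sort_keys=True))


def load_mask_json(path: str | Path) -> StructureMask:
    return mask_from_json(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Study manifest
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    """Load and validate a study manifest CSV.

    Enforces unique (patient, modality, observer) keys, known modalities
    and roles, at most one PET entry per patient, and (optionally) that
    every referenced mask file exists relative to the manifest directory.
    Missing cells are simply absent rows.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    missing_cols = [c for c in MANIFEST_COLUMNS[:4] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest missing columns: {missing_cols}")
    bad_mod = set(df["modality"]) - {m.value for m in Modality}
    if bad_mod:
        raise ValueError(f"invalid modality: {sorted(bad_mod)}")
    bad_role = set(df["observer_role"]) - {r.value for r in ObserverRole}
    if bad_role:
        raise ValueError(f"invalid observer role: {sorted(bad_role)}")
    keys = df[["patient_id", "modality", "observer_id"]]
    dup = keys[keys.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate entry: {dup.iloc[0].tolist()}")
    pet = df[df["modality"] == Modality.PET.value]
    if pet["patient_id"].duplicated().any():
        raise ValueError("PET must have at most one entry per patient")
    if check_files and "mask_path" in df.columns:
        base = path.parent
        for p in df["mask_path"]:
            if p and not (base / p).exists():
                raise FileNotFoundError(f"mask file referenced by manifest not found: {p}")
    return df


def save_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def completeness_report(manifest: pd.DataFrame, n_patients: int, n_observers: int) -> dict:
    """Completed-contour bookkeeping: per human modality, 'completed/expected'."""
    out = {}
    for m in (Modality.CT, Modality.MR, Modality.CTMR):
        n = int((manifest["modality"] == m.value).sum())
        out[m.value] = f"{n}/{n_patients * n_observers}"
    out[Modality.PET.value] = f"{int((manifest['modality'] == Modality.PET.value).sum())}/{n_patients}"
    return out


# ---------------------------------------------------------------------------
# Planar contour (polygon) voxelisation — minimal structure-set import
# ---------------------------------------------------------------------------

def polygons_to_mask(slices: dict, grid: VoxelGrid, **mask_tags) -> StructureMask:
    """Voxelise planar contours: {z_index: [list of (x_mm, y_mm) rings]}.

    A voxel on slice z is set iff its centre lies inside (or on the
    boundary of) any of that slice's polygons — the usual centre-inclusion
    voxelisation rule.  Intended as a convenience for importing simple
    structure-set exports; full treatment-planning dialects are out of scope.
    """
    from matplotlib.path import Path as MplPath

    voxels = np.zeros(grid.dims, dtype=bool)
    nx, ny, _ = grid.dims
    xs = grid.origin_mm[0] + np.arange(nx) * grid.spacing_mm[0]
    ys = grid.origin_mm[1] + np.arange(ny) * grid.spacing_mm[1]
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    centres = np.column_stack([gx.ravel(), gy.ravel()])
    for z, rings in slices.items():
        z = int(z)
        if not 0 <= z < grid.dims[2]:
            raise ValueError(f"slice index {z} outside grid")
        plane = np.zeros(nx * ny, dtype=bool)
        for ring in rings:
            path = MplPath(np.asarray(ring, dtype=float))
            # radius>0 makes boundary points count as inside
            plane |= path.contains_points(centres, radius=1e-9)
        voxels[:, :, z] = plane.reshape(nx, ny)
    return StructureMask(grid=grid, voxels=voxels, **mask_tags)
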
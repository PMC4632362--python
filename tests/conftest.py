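"""Shared fixtures: small mask builders and an independent brute-force oracle."""

from __future__ import annotations

import numpy as np
import pytest

from gtvkit.grid import Modality, ObserverRole, StructureMask, VoxelGrid


def make_grid(dims=(8, 8, 8), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> VoxelGrid:
    return VoxelGrid(dims=dims, spacing_mm=spacing, origin_mm=origin)


def make_mask(
    indices,
    dims=(8, 8, 8),
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    **tags,
) -> StructureMask:
    """Mask from an explicit list of true voxel indices."""
    grid = make_grid(dims, spacing, origin)
    voxels = np.zeros(dims, dtype=bool)
    for idx in indices:
        voxels[tuple(idx)] = True
    tags.setdefault("patient_id", "P01")
    tags.setdefault("observer_id", "O1")
    return StructureMask(grid=grid, voxels=voxels, **tags)


def cube_mask(corner, size, dims=(8, 8, 8), spacing=(1.0, 1.0, 1.0), **tags) -> StructureMask:
    """Axis-aligned solid cube of ``size`` voxels with its low corner at ``corner``."""
    grid = make_grid(dims, spacing)
    voxels = np.zeros(dims, dtype=bool)
    sl = tuple(slice(c, c + size) for c in corner)
    voxels[sl] = True
    tags.setdefault("patient_id", "P01")
    tags.setdefault("observer_id", "O1")
    return StructureMask(grid=grid, voxels=voxels, **tags)


def random_mask_pair(rng, max_dim=16, spacing=(1.0, 1.0, 1.0)):
    """Random non-empty, overlapping-or-not blob pair on a shared small grid."""
    dims = tuple(int(d) for d in rng.integers(4, max_dim + 1, size=3))
    grid = make_grid(dims, spacing)

    def blob():
        v = np.zeros(dims, dtype=bool)
        n_seeds = int(rng.integers(1, 4))
        for _ in range(n_seeds):
            c = rng.integers(0, dims)
            r = int(rng.integers(1, 4))
            idx = np.indices(dims)
            d2 = sum((idx[k] - c[k]) ** 2 for k in range(3))
            v |= d2 <= r**2
        if not v.any():
            v[tuple(rng.integers(0, dims))] = True
        return v

    a = StructureMask(grid=grid, voxels=blob(), patient_id="P", observer_id="a")
    b = StructureMask(grid=grid, voxels=blob(), patient_id="P", observer_id="b")
    return a, b


# ---------------------------------------------------------------------------
# Brute-force oracle: set arithmetic + explicit nearest-point search, entirely
# independent of the distance-transform implementation under test.
# ---------------------------------------------------------------------------

def brute_force_metrics(a: StructureMask, b: StructureMask) -> dict:
    spacing = np.asarray(a.grid.spacing_mm)
    origin = np.asarray(a.grid.origin_mm)
    A = {tuple(i) for i in np.argwhere(a.voxels)}
    B = {tuple(i) for i in np.argwhere(b.voxels)}
    inter = A & B
    union = A | B
    ci = len(inter) / len(union)
    dice = 2 * len(inter) / (len(A) + len(B))
    se = len(inter) / len(A)
    incl = len(inter) / len(B)

    def pts(S):
        return origin + np.asarray(sorted(S), dtype=float) * spacing

    cgd = float(np.linalg.norm(pts(A).mean(axis=0) - pts(B).mean(axis=0)))

    sym = (A - B) | (B - A)
    if not sym:
        mdc = 0.0
    else:
        a_pts, b_pts = pts(A), pts(B)
        dists = []
        for v in A - B:
            p = origin + np.asarray(v, dtype=float) * spacing
            dists.append(np.min(np.linalg.norm(b_pts - p, axis=1)))
        for v in B - A:
            p = origin + np.asarray(v, dtype=float) * spacing
            dists.append(np.min(np.linalg.norm(a_pts - p, axis=1)))
        mdc = float(np.mean(dists))
    return {"CI": ci, "DICE": dice, "SeIdx": se, "InclIdx": incl, "CGD": cgd, "MDC": mdc}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
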
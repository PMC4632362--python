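"""Synthetic multi-observer, multi-modality delineation study generator.

Real delineation studies of this kind — a small head-and-neck cohort,
several clinicians contouring the same primary tumour on CT, MR and fused
CT-MR, plus one algorithmically segmented PET contour per patient — cannot
be redistributed.  This module generates complete synthetic studies with
the same statistical skeleton so that every downstream stage (metrics,
PET segmentation, mixed models, tables) runs end-to-end:

* one smooth random "true" tumour per patient (a superposition of
  overlapping ellipsoids, smoothed and level-set thresholded), volume drawn
  from a log-normal distribution;
* a systematically grown/shrunk *modality truth* per imaging modality,
  obtained by shifting the tumour's signed-distance level set until the
  volume matches a configured multiplier (modalities see systematically
  different tumour extents);
* per-observer contours produced by perturbing the modality truth boundary
  with a smooth radial field — a global inflation/deflation draw plus
  band-limited local noise — with modality-dependent amplitude (largest on
  CT) and a role-dependent bias (oncologists contour systematically larger
  than radiologists);
* a blurred, noisy PET phantom of the PET-modality truth with uniform
  background uptake, together with tumour and background ROIs, ready for
  adaptive-threshold segmentation.

Identical (config, seed) regenerates a bit-identical study; every random
stream is keyed on the seed plus the patient/observer/modality coordinates.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import Modality, ObserverRole, StructureMask, VoxelGrid
from .petseg import (
    PETVolume,
    ROI,
    background_shell,
    calibrate_coefficients,
    segment_pet,
    suv_stats,
)

__all__ = [
    "StudyConfig",
    "GroundTruth",
    "SyntheticStudy",
    "generate_truth",
    "simulate_observer",
    "render_pet",
    "generate_study",
    "sphere_phantom",
    "calibrate_from_phantoms",
    "signed_distance_mm",
    "refined_signed_distance_mm",
    "DEFAULT_OBSERVERS",
    "DEFAULT_COEFFICIENTS",
]

DEFAULT_OBSERVERS: tuple[tuple[str, ObserverRole], ...] = (
    ("R1", ObserverRole.RADIOLOGIST),
    ("R2", ObserverRole.RADIOLOGIST),
    ("O1", ObserverRole.ONCOLOGIST),
    ("O2", ObserverRole.ONCOLOGIST),
    ("O3", ObserverRole.ONCOLOGIST),
)

#: Threshold slopes for the default PET render settings (2 mm grid, 7 mm
#: FWHM blur, 8:1 contrast), fitted once by :func:`calibrate_from_phantoms`
#: on noiseless spheres of radius 5-15 mm at background SUV 1-3.
DEFAULT_COEFFICIENTS = (0.257884, 2.088423)

_MODALITY_ORDER = (Modality.CT, Modality.MR, Modality.CTMR, Modality.PET)


@dataclass
class StudyConfig:
    """All knobs of the synthetic study; defaults emulate the target design.

    Volume multipliers and observer-noise amplitudes default to values that
    order mean volumes PET < CT < MR < CT-MR and inter-observer volume SDs
    CT > CT-MR > MR, the structure the analysis stages are built to detect.
    Effect-size units: multipliers are volume ratios relative to the base
    tumour; noise amplitudes and role biases are radial offsets in mm
    applied to the contour boundary.
    """

    n_patients: int = 11
    observers: tuple[tuple[str, ObserverRole], ...] = DEFAULT_OBSERVERS
    grid_dims: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    # base tumour volume distribution (cm^3): log-normal
    volume_median_cm3: float = 12.0
    volume_sigma: float = 0.55
    # systematic modality volume multipliers (relative to base volume)
    modality_multipliers: dict = field(
        default_factory=lambda: {
            Modality.CT: 1.00,
            Modality.MR: 1.07,
            Modality.CTMR: 1.19,
            Modality.PET: 0.80,
        }
    )
    # observer boundary noise (mm): whole-contour inflation draw + local field
    noise_global_mm: dict = field(
        default_factory=lambda: {Modality.CT: 1.45, Modality.CTMR: 1.1, Modality.MR: 0.25}
    )
    noise_local_mm: dict = field(
        default_factory=lambda: {Modality.CT: 0.95, Modality.CTMR: 0.8, Modality.MR: 0.25}
    )
    noise_correlation_mm: float = 10.0
    role_bias_mm: dict = field(
        default_factory=lambda: {
            ObserverRole.RADIOLOGIST: -0.9,
            ObserverRole.ONCOLOGIST: 0.55,
        }
    )
    # PET phantom rendering
    pet_background_suv: float = 2.0
    pet_contrast_ratio: float = 8.0
    pet_blur_fwhm_mm: float = 7.0
    pet_noise_sd: float = 0.10
    pet_roi_margin_mm: float = 8.0
    pet_bg_distance_mm: float = 12.0
    coeff_a: float = DEFAULT_COEFFICIENTS[0]
    coeff_b: float = DEFAULT_COEFFICIENTS[1]
    # per-modality probability that a human contour was not completed
    missingness: dict = field(
        default_factory=lambda: {Modality.CT: 0.0, Modality.MR: 0.073, Modality.CTMR: 0.236}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if any(m <= 0 for m in self.modality_multipliers.values()):
            raise ValueError("modality multipliers must be > 0")
        if any(a < 0 for a in self.noise_global_mm.values()):
            raise ValueError("noise amplitudes must be >= 0")
        if any(not (0.0 <= p < 1.0) for p in self.missingness.values()):
            raise ValueError("infeasible design: missingness rates must be in [0, 1)")

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(dims=self.grid_dims, spacing_mm=self.spacing_mm)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Per-patient truth: the base tumour and its per-modality systematic variants."""

    patient_id: str
    grid: VoxelGrid
    base: np.ndarray  # boolean
    volume_cm3: float
    centroid_mm: tuple[float, float, float]
    modality_truth: dict  # Modality -> boolean array


@dataclass
class SyntheticStudy:
    """A complete generated study: manifest, masks, PET volumes and truths."""

    config: StudyConfig
    manifest: pd.DataFrame
    masks: dict  # (patient_id, modality_value, observer_id) -> StructureMask
    pet: dict  # patient_id -> (PETVolume, ROI)
    pet_audit: dict  # patient_id -> ThresholdResult
    truths: dict  # patient_id -> GroundTruth
    notes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Random-stream helpers: every stream is keyed on (seed, tag, coordinates)
# ---------------------------------------------------------------------------

_TAG_TRUTH = 101
_TAG_OBSERVER = 202
_TAG_PET = 303
_TAG_MISSING = 404


def _stream(config: StudyConfig, tag: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), tag, *[int(k) % (2**31) for k in keys]])


def _id_key(identifier: str) -> int:
    return zlib.crc32(identifier.encode())


def signed_distance_mm(voxels: np.ndarray, spacing) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary: negative inside."""
    voxels = np.asarray(voxels, dtype=bool)
    outside = ndimage.distance_transform_edt(~voxels, sampling=spacing)
    inside = ndimage.distance_transform_edt(voxels, sampling=spacing)
    return outside - inside


def refined_signed_distance_mm(
    voxels: np.ndarray, spacing, smooth_sigma_mm: float = 2.0
) -> np.ndarray:
    """Sub-voxel signed distance surrogate for level-set operations (mm).

    The plain voxel EDT is quantised: entire boundary shells share one
    distance value, so thresholding it moves the contour in whole-shell
    jumps and sub-voxel offsets have no effect.  Instead, the indicator is
    blurred with a Gaussian of ``smooth_sigma_mm``; for a locally flat
    boundary the blurred value at signed distance d is Phi(-d / sigma), so
    ``-sigma * Phi^{-1}(g)`` recovers a continuous distance estimate that
    is accurate to fractions of a voxel near the surface (curvature bias
    O(sigma^2 * curvature)) and saturates smoothly around +/- 6.7 sigma
    far from it.  The sign is snapped to the mask, so the zero level set
    reproduces the input mask exactly and thresholding at any offset gives
    nested, smoothly growing contours.
    """
    from scipy.special import ndtri

    voxels = np.asarray(voxels, dtype=bool)
    g = ndimage.gaussian_filter(
        voxels.astype(float), sigma=smooth_sigma_mm / np.asarray(spacing)
    )
    d_est = -smooth_sigma_mm * ndtri(np.clip(g, 1e-11, 1.0 - 1e-11))
    sign = np.where(voxels, -1.0, 1.0)
    return sign * np.maximum(1e-6, sign * d_est)


def _level_set_at_count(field: np.ndarray, n: int, descending: bool) -> np.ndarray:
    """Boolean mask of the ``n`` most extreme voxels of a scalar field."""
    flat = np.sort(field.ravel())
    if descending:
        level = flat[-n]
        return field >= level
    level = flat[n - 1]
    return field <= level


def generate_truth(config: StudyConfig, patient_index: int) -> GroundTruth:
    """Generate one patient's base tumour and its per-modality variants.

    The base tumour is the top-volume level set of a smoothed union of 2-4
    overlapping random ellipsoids; modality variants are signed-distance
    level-set shifts calibrated so each variant's volume matches the
    configured multiplier (within voxel quantisation).
    """
    rng = _stream(config, _TAG_TRUTH, patient_index)
    grid = config.grid
    spacing = np.asarray(grid.spacing_mm)
    extent = np.asarray(grid.dims) * spacing

    target_cm3 = config.volume_median_cm3 * float(
        np.exp(rng.normal(0.0, config.volume_sigma))
    )
    vox_mm3 = grid.voxel_volume_mm3
    n_target = int(round(target_cm3 * 1000.0 / vox_mm3))
    max_mult = max(config.modality_multipliers.values())
    if n_target < 8 or n_target * max_mult > 0.2 * np.prod(grid.dims):
        raise ValueError(
            f"grid too coarse: target volume {target_cm3:.1f} cm^3 not representable "
            f"on {grid.dims} at {grid.spacing_mm} mm"
        )

    r0 = (3.0 * target_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    centre = extent / 2.0 + rng.uniform(-2.0, 2.0, 3)
    n_ellipsoids = int(rng.integers(2, 5))

    idx = np.indices(grid.dims).astype(float)
    coords = idx * spacing[:, None, None, None]  # physical mm, origin 0
    union = np.zeros(grid.dims, dtype=bool)
    for _ in range(n_ellipsoids):
        c = centre + rng.uniform(-0.5, 0.5, 3) * r0
        semi = r0 * rng.uniform(0.7, 1.3, 3)
        q = sum(
            ((coords[ax] - c[ax]) / semi[ax]) ** 2 for ax in range(3)
        )
        union |= q <= 1.0
    if not union.any():
        union[tuple(np.round(centre / spacing).astype(int))] = True
    smooth = ndimage.gaussian_filter(union.astype(float), sigma=2.0 / spacing)
    base = _level_set_at_count(smooth, n_target, descending=True)

    sdist = refined_signed_distance_mm(base, spacing)
    modality_truth = {}
    for modality, mult in config.modality_multipliers.items():
        n_m = max(1, int(round(n_target * mult)))
        modality_truth[Modality(modality)] = _level_set_at_count(
            sdist, n_m, descending=False
        )

    from .grid import centroid_mm as _centroid  # local import avoids cycle at module load

    mask = StructureMask(grid=grid, voxels=base, patient_id=f"P{patient_index + 1:02d}")
    return GroundTruth(
        patient_id=f"P{patient_index + 1:02d}",
        grid=grid,
        base=base,
        volume_cm3=base.sum() * vox_mm3 / 1000.0,
        centroid_mm=tuple(_centroid(mask)),
        modality_truth=modality_truth,
    )


def _local_field(
    rng: np.random.Generator, dims, spacing, correlation_mm: float
) -> np.ndarray:
    """Band-limited unit-variance random field (smoothed white noise)."""
    white = rng.standard_normal(dims)
    sigma_vox = correlation_mm / np.asarray(spacing) / 2.3548
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox)
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def simulate_observer(
    truth_voxels: np.ndarray,
    role: ObserverRole,
    modality: Modality,
    config: StudyConfig,
    patient_index: int,
    observer_id: str,
    sdist: np.ndarray | None = None,
) -> StructureMask:
    """One observer's contour: a radial perturbation of the modality truth.

    The perturbation is ``role_bias + global_draw + local_field`` (mm)
    applied to the signed-distance level set, so contours stay smooth and
    connected.  The observer id and study coordinates key the random
    stream, so distinct observers get independent perturbations under the
    same study seed.
    """
    modality = Modality(modality)
    role = ObserverRole(role)
    grid = config.grid
    if sdist is None:
        sdist = refined_signed_distance_mm(truth_voxels, grid.spacing_mm)
    rng = _stream(
        config, _TAG_OBSERVER, patient_index, _id_key(observer_id), _id_key(modality.value)
    )
    bias = config.role_bias_mm.get(role, 0.0)
    amp_g = config.noise_global_mm.get(modality, 0.0)
    amp_l = config.noise_local_mm.get(modality, 0.0)
    for _ in range(5):
        offset = bias + rng.normal(0.0, amp_g)
        if amp_l > 0:
            offset = offset + amp_l * _local_field(
                rng, grid.dims, grid.spacing_mm, config.noise_correlation_mm
            )
        voxels = sdist <= offset
        if voxels.any():
            return StructureMask(
                grid=grid,
                voxels=voxels,
                patient_id=f"P{patient_index + 1:02d}",
                modality=modality,
                observer_id=observer_id,
                observer_role=role,
            )
    raise ValueError(
        f"observer perturbation annihilated the mask after 5 attempts "
        f"(patient {patient_index}, {observer_id}, {modality.value})"
    )


def render_pet(
    truth_voxels: np.ndarray,
    config: StudyConfig,
    patient_index: int,
) -> tuple[PETVolume, ROI]:
    """Render a PET phantom of the (PET-modality) truth with ROIs.

    SUV field = uniform background + (contrast-1) x background inside the
    tumour, convolved with an isotropic Gaussian point-spread function of
    the configured FWHM, plus white Gaussian noise (clipped at 0).
    """
    grid = config.grid
    rng = _stream(config, _TAG_PET, patient_index)
    bg = config.pet_background_suv
    clean = bg * (1.0 + (config.pet_contrast_ratio - 1.0) * truth_voxels.astype(float))
    if config.pet_blur_fwhm_mm > 0:
        sigma_vox = config.pet_blur_fwhm_mm / 2.3548 / np.asarray(grid.spacing_mm)
        clean = ndimage.gaussian_filter(clean, sigma=sigma_vox)
    suv = clean
    if config.pet_noise_sd > 0:
        suv = np.clip(clean + rng.normal(0.0, config.pet_noise_sd, grid.dims), 0.0, None)
    pet = PETVolume(grid=grid, suv=suv, coeff_a=config.coeff_a, coeff_b=config.coeff_b)
    sdist = signed_distance_mm(truth_voxels, grid.spacing_mm)
    tumour_roi = sdist <= config.pet_roi_margin_mm
    bg_roi = background_shell(tumour_roi, grid, distance_mm=config.pet_bg_distance_mm)
    return pet, ROI(tumour=tumour_roi, background=bg_roi)


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate the full cohort: truths, observer contours, PET phantoms and masks.

    Missingness is applied per human contour at the configured per-modality
    rate, but a patient x modality cell is never left with fewer than two
    observers (restored contours are noted); the PET contour is never
    removed.  Identical (config, seed) regenerates an identical study.
    """
    human_modalities = [m for m in _MODALITY_ORDER if m != Modality.PET]
    rows = []
    masks = {}
    pet = {}
    pet_audit = {}
    truths = {}
    notes = []
    miss_rng = _stream(config, _TAG_MISSING)

    for p in range(config.n_patients):
        truth = generate_truth(config, p)
        truths[truth.patient_id] = truth

        for modality in human_modalities:
            tv = truth.modality_truth[modality]
            sdist = refined_signed_distance_mm(tv, config.grid.spacing_mm)
            rate = config.missingness.get(modality, 0.0)
            drop = [
                bool(miss_rng.uniform() < rate) for _ in config.observers
            ]
            n_kept = sum(not d for d in drop)
            if n_kept < 2:
                need = 2 - n_kept
                dropped_idx = [i for i, d in enumerate(drop) if d]
                restore = miss_rng.choice(dropped_idx, size=need, replace=False)
                for i in np.atleast_1d(restore):
                    drop[int(i)] = False
                notes.append(
                    f"{truth.patient_id}/{modality.value}: restored {need} contour(s) "
                    "to keep >= 2 observers"
                )
            for (obs_id, role), dropped in zip(config.observers, drop):
                if dropped:
                    continue
                mask = simulate_observer(
                    tv, role, modality, config, p, obs_id, sdist=sdist
                )
                masks[(truth.patient_id, modality.value, obs_id)] = mask
                rows.append(
                    {
                        "patient_id": truth.patient_id,
                        "modality": modality.value,
                        "observer_id": obs_id,
                        "observer_role": role.value,
                    }
                )

        pet_vol, roi = render_pet(truth.modality_truth[Modality.PET], config, p)
        seg, audit = segment_pet(pet_vol, roi, patient_id=truth.patient_id)
        masks[(truth.patient_id, Modality.PET.value, "auto")] = seg
        pet[truth.patient_id] = (pet_vol, roi)
        pet_audit[truth.patient_id] = audit
        rows.append(
            {
                "patient_id": truth.patient_id,
                "modality": Modality.PET.value,
                "observer_id": "auto",
                "observer_role": ObserverRole.AUTO.value,
            }
        )

    manifest = pd.DataFrame(rows, columns=["patient_id", "modality", "observer_id", "observer_role"])
    return SyntheticStudy(
        config=config,
        manifest=manifest,
        masks=masks,
        pet=pet,
        pet_audit=pet_audit,
        truths=truths,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Phantom calibration of the adaptive-threshold coefficients
# ---------------------------------------------------------------------------

def sphere_phantom(
    radius_mm: float,
    config: StudyConfig,
    noise: bool = False,
    patient_index: int = 0,
) -> tuple[np.ndarray, PETVolume, ROI]:
    """A rendered sphere of known radius: (true mask, PET volume, ROIs)."""
    grid = config.grid
    spacing = np.asarray(grid.spacing_mm)
    centre = np.asarray(grid.dims) * spacing / 2.0
    idx = np.indices(grid.dims).astype(float)
    coords = idx * spacing[:, None, None, None]
    r2 = sum((coords[ax] - centre[ax]) ** 2 for ax in range(3))
    true = r2 <= radius_mm**2
    cfg = config if noise else _noiseless(config)
    pet, roi = render_pet(true, cfg, patient_index)
    return true, pet, roi


def _noiseless(config: StudyConfig) -> StudyConfig:
    import dataclasses

    return dataclasses.replace(config, pet_noise_sd=0.0)


def calibrate_from_phantoms(
    config: StudyConfig,
    radii_mm=(5.0, 7.5, 10.0, 12.5, 15.0),
    backgrounds_suv=(1.0, 2.0, 3.0),
) -> tuple[float, float, list[tuple[float, float, float]]]:
    """Fit the two threshold slopes from noiseless sphere phantoms.

    Phantoms are rendered over a grid of sphere radii and background
    uptake levels (varying the background decouples the two slopes).  For
    each phantom the "true" threshold is the SUV level at which the
    segmented volume equals the known sphere volume; the fit regresses it
    on (mean70, background mean) by least squares.  Returns (a, b) and the
    raw measurements.
    """
    import dataclasses

    measurements = []
    for bg_level in backgrounds_suv:
        cfg = dataclasses.replace(config, pet_background_suv=float(bg_level))
        for r in radii_mm:
            true, pet, roi = sphere_phantom(r, cfg, noise=False)
            stats = suv_stats(pet, roi)
            bg = float(pet.suv[roi.background].mean())
            n_true = int(true.sum())
            roi_vals = np.sort(pet.suv[roi.tumour])[::-1]
            if n_true > roi_vals.size:
                raise ValueError("tumour ROI smaller than the true sphere")
            t_star = float(roi_vals[n_true - 1])
            measurements.append((stats.mean70, bg, t_star))
    a, b, _ = calibrate_coefficients(measurements)
    return a, b, measurements
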
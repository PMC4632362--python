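"""Pairwise 3-D contour concordance metrics and their study-level aggregation.

Six metrics compare an ordered pair of binary structures (A, B) on a common
voxel grid:

* ``ci`` — conformity index, the Jaccard overlap |A∩B| / |A∪B|
* ``dice`` — Dice coefficient 2|A∩B| / (|A| + |B|)
* ``se_idx`` — sensitivity index, fraction of A contained in B (|A∩B| / |A|)
* ``incl_idx`` — inclusion index, fraction of B contained in A (|A∩B| / |B|)
* ``cgd_mm`` — centre-of-gravity distance: Euclidean distance between the
  two centroids, in mm
* ``mdc_mm`` — mean distance to conformity: over every voxel in the
  symmetric difference, the distance to the nearest voxel of the *other*
  structure, averaged; 0 for identical masks

CI and Dice are algebraically linked (``dice = 2 ci / (1 + ci)``), and
``se_idx(A, B) == incl_idx(B, A)``; both identities are exercised by the
test suite.

Aggregation follows a two-stage design: metrics are averaged over contour
pairs within each patient first, then the cohort mean and SD are taken
across patients, so every patient contributes equally regardless of how
many contour pairs it supplies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import (
    EmptyStructureError,
    GridMismatchError,
    Modality,
    StructureMask,
    centroid_mm,
)

__all__ = [
    "ConcordanceResult",
    "concordance",
    "overlap_metrics",
    "cgd_mm",
    "mdc_mm",
    "interobserver_summary",
    "intermodality_summary",
    "interobserver_pairs_table",
    "intermodality_pairs_table",
    "INTEROBSERVER_METRICS",
    "ALL_METRICS",
    "MODALITY_PAIR_COLUMNS",
]

#: Metrics reported for same-modality inter-observer comparisons.  The
#: directional containment indices are omitted there: with unordered
#: observer pairs they carry no meaningful direction.
INTEROBSERVER_METRICS = ("CI", "DICE", "CGD", "MDC")
ALL_METRICS = ("CI", "DICE", "SeIdx", "InclIdx", "CGD", "MDC")

#: Ordered modality pairs reported in the inter-modality comparison.  The
#: order fixes the direction of SeIdx (first within second) and InclIdx
#: (second within first).
MODALITY_PAIR_COLUMNS = (
    (Modality.CT, Modality.PET),
    (Modality.MR, Modality.PET),
    (Modality.CTMR, Modality.PET),
    (Modality.CT, Modality.MR),
    (Modality.CT, Modality.CTMR),
    (Modality.MR, Modality.CTMR),
)


@dataclass(frozen=True)
class ConcordanceResult:
    """The six metric values for one ordered pair of structures."""

    ci: float
    dice: float
    se_idx: float
    incl_idx: float
    cgd_mm: float
    mdc_mm: float
    pair: tuple[str, str] = ("", "")

    def as_dict(self) -> dict[str, float]:
        return {
            "CI": self.ci,
            "DICE": self.dice,
            "SeIdx": self.se_idx,
            "InclIdx": self.incl_idx,
            "CGD": self.cgd_mm,
            "MDC": self.mdc_mm,
        }


def _check_pair(a: StructureMask, b: StructureMask) -> None:
    if a.is_empty or b.is_empty:
        raise EmptyStructureError(
            f"empty structure in pair ({a.label()}, {b.label()})"
        )
    if not a.grid.compatible_with(b.grid):
        raise GridMismatchError(
            f"grid mismatch between {a.label()} and {b.label()}"
        )


def overlap_metrics(a: StructureMask, b: StructureMask) -> tuple[float, float, float, float]:
    """Return (ci, dice, se_idx, incl_idx) for the ordered pair (a, b)."""
    _check_pair(a, b)
    na = a.n_voxels
    nb = b.n_voxels
    inter = int(np.count_nonzero(a.voxels & b.voxels))
    union = na + nb - inter
    ci = inter / union
    dice = 2.0 * inter / (na + nb)
    return ci, dice, inter / na, inter / nb


def cgd_mm(a: StructureMask, b: StructureMask) -> float:
    """Centre-of-gravity distance (mm) between the two structures."""
    _check_pair(a, b)
    return float(np.linalg.norm(centroid_mm(a) - centroid_mm(b)))


def _bounding_slices(voxels: np.ndarray, shape: tuple[int, ...]) -> tuple[slice, ...]:
    idx = np.argwhere(voxels)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))


def mdc_mm(a: StructureMask, b: StructureMask) -> float:
    """Mean distance to conformity (mm).

    For each voxel of the symmetric difference, take the Euclidean distance
    from its centre to the nearest true voxel centre of the companion
    structure (a Euclidean distance transform with anisotropic sampling);
    the mean is over all such voxels pooled from both directions.
    Symmetric in (a, b); 0 when the masks coincide.
    """
    _check_pair(a, b)
    av, bv = a.voxels, b.voxels
    sym = av ^ bv
    if not sym.any():
        return 0.0
    # Distances only involve voxels inside the union's bounding box, so the
    # transforms can be computed on that crop without changing any value.
    box = _bounding_slices(av | bv, av.shape)
    av, bv = av[box], bv[box]
    spacing = a.grid.spacing_mm
    dist_to_b = ndimage.distance_transform_edt(~bv, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~av, sampling=spacing)
    d = np.concatenate([dist_to_b[av & ~bv], dist_to_a[bv & ~av]])
    return float(d.mean())


def concordance(a: StructureMask, b: StructureMask) -> ConcordanceResult:
    """All six metrics for the ordered pair (a, b)."""
    ci, dice, se, incl = overlap_metrics(a, b)
    return ConcordanceResult(
        ci=ci,
        dice=dice,
        se_idx=se,
        incl_idx=incl,
        cgd_mm=cgd_mm(a, b),
        mdc_mm=mdc_mm(a, b),
        pair=(a.label(), b.label()),
    )


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

MaskDict = dict  # (patient_id, modality, observer_id) -> StructureMask


def _masks_by_patient_modality(
    masks: dict, patient_id: str, modality: Modality
) -> dict[str, StructureMask]:
    out = {}
    for (pid, mod, obs), m in masks.items():
        if pid == patient_id and Modality(mod) == modality:
            out[obs] = m
    return out


def _patient_ids(masks: dict) -> list[str]:
    return sorted({pid for (pid, _, _) in masks})


def interobserver_pairs_table(masks: MaskDict, modality: Modality) -> pd.DataFrame:
    """Tidy per-pair metric values for all unordered same-modality observer pairs.

    Columns: patient_id, comparison, observer_a, observer_b, metric, value.
    Patients with fewer than two observers in the modality are skipped.
    """
    modality = Modality(modality)
    rows = []
    for pid in _patient_ids(masks):
        by_obs = _masks_by_patient_modality(masks, pid, modality)
        observers = sorted(by_obs)
        for oa, ob in itertools.combinations(observers, 2):
            res = concordance(by_obs[oa], by_obs[ob])
            for metric, value in res.as_dict().items():
                if metric in INTEROBSERVER_METRICS:
                    rows.append(
                        {
                            "patient_id": pid,
                            "comparison": modality.value,
                            "observer_a": oa,
                            "observer_b": ob,
                            "metric": metric,
                            "value": value,
                        }
                    )
    return pd.DataFrame(
        rows, columns=["patient_id", "comparison", "observer_a", "observer_b", "metric", "value"]
    )


def _summarise(per_pair: pd.DataFrame) -> pd.DataFrame:
    """Two-stage aggregation: mean per patient, then mean/SD across patients."""
    if per_pair.empty:
        return pd.DataFrame(columns=["comparison", "metric", "mean", "sd", "n_patients"])
    per_patient = (
        per_pair.groupby(["comparison", "metric", "patient_id"], sort=False)["value"]
        .mean()
        .reset_index()
    )
    out = (
        per_patient.groupby(["comparison", "metric"], sort=False)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n_patients="count")
        .reset_index()
    )
    out["n_patients"] = out["n_patients"].astype(int)
    return out


def interobserver_summary(masks: MaskDict, modality: Modality) -> pd.DataFrame:
    """Cohort inter-observer variability for one modality.

    All unordered observer pairs within the modality are compared per
    patient (CI, DICE, CGD, MDC); per-patient means are averaged across
    patients, with the across-patient SD reported alongside.  Missing
    observer contours simply contribute no pairs.
    """
    table = interobserver_pairs_table(masks, modality)
    if table.empty:
        raise ValueError(
            f"insufficient observers: no patient has >= 2 {Modality(modality).value} contours"
        )
    return _summarise(table)


def intermodality_pairs_table(
    masks: MaskDict,
    pairs: tuple = MODALITY_PAIR_COLUMNS,
) -> pd.DataFrame:
    """Tidy per-pair metric values for ordered modality pairs, same clinician.

    For each ordered modality pair and each patient, every clinician with a
    contour in both modalities contributes one comparison; pairs involving
    PET compare each clinician's contour against the single auto-segmented
    PET contour.  A clinician missing either contour is skipped.
    """
    rows = []
    for pid in _patient_ids(masks):
        per_modality = {m: _masks_by_patient_modality(masks, pid, m) for m in Modality}
        for m1, m2 in pairs:
            for obs in sorted(per_modality[m1]):
                a = per_modality[m1][obs]
                if m2 == Modality.PET:
                    if not per_modality[Modality.PET]:
                        continue
                    (b,) = per_modality[Modality.PET].values()
                else:
                    b = per_modality[m2].get(obs)
                    if b is None:
                        continue
                res = concordance(a, b)
                for metric, value in res.as_dict().items():
                    rows.append(
                        {
                            "patient_id": pid,
                            "comparison": f"{m1.value}-{m2.value}",
                            "observer_a": obs,
                            "observer_b": b.observer_id,
                            "metric": metric,
                            "value": value,
                        }
                    )
    return pd.DataFrame(
        rows, columns=["patient_id", "comparison", "observer_a", "observer_b", "metric", "value"]
    )


def intermodality_summary(
    masks: MaskDict, pairs: tuple = MODALITY_PAIR_COLUMNS
) -> pd.DataFrame:
    """Cohort inter-modality concordance for the ordered modality pairs.

    SeIdx is the fraction of the first-named structure inside the second;
    InclIdx the fraction of the second inside the first.  Aggregation is
    per-patient mean, then mean/SD across patients.
    """
    table = intermodality_pairs_table(masks, pairs)
    if table.empty:
        raise ValueError("no comparable pairs: no clinician has contours in both modalities")
    return _summarise(table)
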
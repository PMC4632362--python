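"""Study-level report tables and the end-to-end pipeline.

Four report shapes summarise a study:

* volume summary — per-modality mean / median / mean inter-observer SD /
  max / min volume (cm^3);
* SD table — per-patient inter-observer volume SD by modality with the
  column means, plus the ANOVA + Tukey comparison across modalities;
* inter-observer concordance — mean (SD) of CI / MDC / CGD / DICE per
  modality with the significant Tukey pairs;
* inter-modality concordance — mean (SD) of all six metrics per ordered
  modality pair (the directional indices keep the pair order's meaning).

``run_pipeline`` chains everything: volumes, SD table, mixed-effects
models, role contrast, normality check and both concordance summaries, and
``write_bundle`` serialises the lot deterministically (CSV + JSON with a
config-hash provenance stamp, no timestamps) so identical inputs produce
byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grid import Modality, volume_cm3
from .metrics import (
    ALL_METRICS,
    INTEROBSERVER_METRICS,
    MODALITY_PAIR_COLUMNS,
    interobserver_pairs_table,
    intermodality_summary,
)
from .stats import (
    AnovaTukeyResult,
    MixedModelResult,
    SDTable,
    VolumeRecord,
    compare_sd_across_modalities,
    fit_volume_model,
    normality_check,
    records_to_frame,
    role_contrast,
    sd_table,
)

__all__ = [
    "ReportBundle",
    "volume_records_from_masks",
    "volume_summary_table",
    "interobserver_report",
    "run_pipeline",
    "write_bundle",
]

HUMAN_MODALITIES = (Modality.CT, Modality.CTMR, Modality.MR)
MODALITY_REPORT_ORDER = ("CT", "CTMR", "MR", "PET")


def volume_records_from_masks(masks: dict) -> list[VolumeRecord]:
    """One VolumeRecord per mask (empty masks are rejected upstream)."""
    records = []
    for (pid, mod, obs), mask in sorted(masks.items()):
        records.append(
            VolumeRecord(
                patient_id=pid,
                modality=Modality(mod),
                observer_id=obs,
                observer_role=mask.observer_role,
                volume_cm3=volume_cm3(mask),
            )
        )
    return records


def volume_summary_table(records, table: SDTable | None = None) -> pd.DataFrame:
    """Per-modality volume summary: mean, median, mean SD, max, min (cm^3)."""
    df = records_to_frame(records)
    rows = []
    for m in MODALITY_REPORT_ORDER:
        sub = df[df["modality"] == m]
        if sub.empty:
            continue
        mean_sd = np.nan
        if table is not None and m in table.column_means.index:
            mean_sd = float(table.column_means[m])
        rows.append(
            {
                "modality": m,
                "mean_cm3": sub["volume_cm3"].mean(),
                "median_cm3": sub["volume_cm3"].median(),
                "mean_sd_cm3": mean_sd,
                "max_cm3": sub["volume_cm3"].max(),
                "min_cm3": sub["volume_cm3"].min(),
            }
        )
    return pd.DataFrame(rows)


def _metric_anova(per_pair: pd.DataFrame, metric: str) -> AnovaTukeyResult | None:
    """ANOVA + Tukey across modalities on per-patient mean metric values."""
    sub = per_pair[per_pair["metric"] == metric]
    per_patient = (
        sub.groupby(["patient_id", "comparison"])["value"].mean().unstack("comparison")
    )
    if per_patient.shape[1] < 2 or (per_patient.notna().sum() < 2).any():
        return None
    table = SDTable(per_patient=per_patient, column_means=per_patient.mean())
    try:
        return compare_sd_across_modalities(table)
    except ValueError:
        return None


def interobserver_report(masks: dict) -> tuple[pd.DataFrame, dict]:
    """Inter-observer concordance summary plus per-metric Tukey comparisons.

    Returns the tidy summary (comparison, metric, mean, sd, n_patients) for
    every human modality with >= 2 observers somewhere, and a dict
    metric -> AnovaTukeyResult across modalities.
    """
    frames = []
    for m in HUMAN_MODALITIES:
        table = interobserver_pairs_table(masks, m)
        if not table.empty:
            frames.append(table)
    if not frames:
        raise ValueError("insufficient observers in every human modality")
    per_pair = pd.concat(frames, ignore_index=True)
    per_patient = (
        per_pair.groupby(["comparison", "metric", "patient_id"], sort=False)["value"]
        .mean()
        .reset_index()
    )
    summary = (
        per_patient.groupby(["comparison", "metric"], sort=False)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n_patients="count")
        .reset_index()
    )
    summary["n_patients"] = summary["n_patients"].astype(int)
    anovas = {}
    for metric in INTEROBSERVER_METRICS:
        res = _metric_anova(per_pair, metric)
        if res is not None:
            anovas[metric] = res
    return summary, anovas


@dataclass
class ReportBundle:
    """Everything the pipeline computes, ready for serialisation."""

    provenance: dict
    volume_records: pd.DataFrame
    volume_summary: pd.DataFrame
    sd_table: SDTable | None
    sd_anova: AnovaTukeyResult | None
    human_model: MixedModelResult | None
    pet_model: MixedModelResult | None
    role_contrast: pd.DataFrame | None
    normality: dict | None
    interobserver: pd.DataFrame | None
    interobserver_anova: dict = field(default_factory=dict)
    intermodality: pd.DataFrame | None = None
    warnings: list = field(default_factory=list)


def run_pipeline(masks: dict, provenance: dict | None = None) -> ReportBundle:
    """Run the complete volume + positional analysis on a mask inventory.

    ``masks`` maps (patient_id, modality_value, observer_id) ->
    StructureMask, all on a common frame.  Stages that cannot run on the
    given inventory (e.g. no PET masks, or a single modality) are recorded
    as warnings rather than aborting the rest.
    """
    warnings_log: list[str] = []
    provenance = dict(provenance or {})
    provenance.setdefault("gtvkit_version", __version__)

    records = volume_records_from_masks(masks)
    rec_frame = records_to_frame(records)

    table = None
    sd_anova = None
    try:
        table = sd_table(records)
        sd_anova = compare_sd_across_modalities(table)
    except ValueError as exc:
        warnings_log.append(f"sd-table stage skipped: {exc}")

    human_model = None
    pet_model = None
    try:
        human_model = fit_volume_model(records, include_pet=False)
    except ValueError as exc:
        warnings_log.append(f"human volume model skipped: {exc}")
    has_pet = (rec_frame["modality"] == Modality.PET.value).any()
    if has_pet:
        try:
            pet_model = fit_volume_model(records, include_pet=True)
        except ValueError as exc:
            warnings_log.append(f"PET volume model skipped: {exc}")
    else:
        warnings_log.append("no PET masks: PET model and PET comparisons omitted")

    roles = None
    try:
        roles = role_contrast(records)
    except ValueError as exc:
        warnings_log.append(f"role contrast skipped: {exc}")

    normality = None
    human = rec_frame[rec_frame["modality"] != Modality.PET.value]
    if len(human) >= 3:
        try:
            r, ok = normality_check(human["volume_cuberoot"])
            normality = {"statistic": r, "pass": ok, "n": int(len(human))}
        except ValueError as exc:
            warnings_log.append(f"normality check skipped: {exc}")

    interobs = None
    interobs_anova: dict = {}
    try:
        interobs, interobs_anova = interobserver_report(masks)
    except ValueError as exc:
        warnings_log.append(f"inter-observer concordance skipped: {exc}")

    pairs = MODALITY_PAIR_COLUMNS
    if not has_pet:
        pairs = tuple(p for p in pairs if Modality.PET not in p)
    intermod = None
    try:
        intermod = intermodality_summary(masks, pairs)
    except ValueError as exc:
        warnings_log.append(f"inter-modality concordance skipped: {exc}")

    return ReportBundle(
        provenance=provenance,
        volume_records=rec_frame,
        volume_summary=volume_summary_table(records, table),
        sd_table=table,
        sd_anova=sd_anova,
        human_model=human_model,
        pet_model=pet_model,
        role_contrast=roles,
        normality=normality,
        interobserver=interobs,
        interobserver_anova=interobs_anova,
        intermodality=intermod,
        warnings=warnings_log,
    )


def _model_payload(model: MixedModelResult | None) -> dict | None:
    if model is None:
        return None
    return {
        "fixed_effects": {
            k: {"estimate": e, "se": s, "p_value": p}
            for k, (e, s, p) in model.fixed_effects.items()
        },
        "random_effect_variances": model.random_effect_variances,
        "residual_variance": model.residual_variance,
        "contrasts": model.contrasts,
        "transform": model.transform,
        "included_modalities": list(model.included_modalities),
        "include_pet": model.include_pet,
        "alpha": model.alpha,
        "converged": model.converged,
        "notes": model.notes,
    }


def _anova_payload(res: AnovaTukeyResult | None) -> dict | None:
    if res is None:
        return None
    return {
        "f_statistic": res.f_statistic,
        "p_value": res.p_value,
        "alpha": res.alpha,
        "tukey": res.tukey.to_dict(orient="records"),
        "significant_pairs": [list(p) for p in res.significant_pairs],
    }


def _wide(summary: pd.DataFrame, metrics, dp: int = 2) -> pd.DataFrame:
    """'mean (sd)' formatted wide table: rows metric, columns comparison."""
    out = {}
    for comparison, sub in summary.groupby("comparison", sort=False):
        col = {}
        for row in sub.itertuples():
            col[row.metric] = f"{row.mean:.{dp}f} ({row.sd:.{dp}f})"
        out[comparison] = col
    return pd.DataFrame(out).reindex([m for m in metrics])


def write_bundle(bundle: ReportBundle, outdir: str | Path) -> Path:
    """Write the report bundle (CSVs + one full-precision JSON) to ``outdir``.

    Output is deterministic: same bundle, byte-identical files.  Rounded
    CSVs mirror the conventional printed precision (volumes 1 dp, SDs 2 dp,
    metrics 2 dp); ``results.json`` keeps full precision.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    bundle.volume_records.to_csv(outdir / "volume_records.csv", index=False)
    bundle.volume_summary.round(1).to_csv(outdir / "volume_summary.csv", index=False)
    if bundle.sd_table is not None:
        bundle.sd_table.round(2).to_csv(outdir / "sd_table.csv")
    if bundle.interobserver is not None:
        bundle.interobserver.to_csv(outdir / "interobserver_summary.csv", index=False)
        _wide(bundle.interobserver, INTEROBSERVER_METRICS).to_csv(
            outdir / "interobserver_wide.csv"
        )
    if bundle.intermodality is not None:
        bundle.intermodality.to_csv(outdir / "intermodality_summary.csv", index=False)
        _wide(bundle.intermodality, ALL_METRICS).to_csv(outdir / "intermodality_wide.csv")
    if bundle.role_contrast is not None:
        bundle.role_contrast.to_csv(outdir / "role_contrast.csv", index=False)

    payload = {
        "provenance": bundle.provenance,
        "volume_summary": bundle.volume_summary.to_dict(orient="records"),
        "sd_table": None
        if bundle.sd_table is None
        else {
            "per_patient": {
                pid: {k: (None if pd.isna(v) else v) for k, v in row.items()}
                for pid, row in bundle.sd_table.per_patient.to_dict(orient="index").items()
            },
            "column_means": bundle.sd_table.column_means.to_dict(),
        },
        "sd_anova": _anova_payload(bundle.sd_anova),
        "human_model": _model_payload(bundle.human_model),
        "pet_model": _model_payload(bundle.pet_model),
        "role_contrast": None
        if bundle.role_contrast is None
        else bundle.role_contrast.to_dict(orient="records"),
        "normality": bundle.normality,
        "interobserver_anova": {
            k: _anova_payload(v) for k, v in bundle.interobserver_anova.items()
        },
        "warnings": bundle.warnings,
    }
    (outdir / "results.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return outdir
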
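"""End-to-end screen analysis: ingest -> metrics -> dose response ->
classification -> clustering (-> enrichment -> connectivity) -> report.

Every stage reads and writes documented flat-text tables so stages can be
re-run independently; identical config and seeds give byte-identical
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classification import (
    Sensitivity,
    StrainClassification,
    Thresholds,
    classify,
    fixed_thresholds,
    flag_slow_grower,
    make_thresholds,
)
from .clustering import (
    DEFAULT_FOCAL_DOSE,
    SOMParams,
    build_features,
    order_within_class,
    summarize_classes,
    train_som,
)
from .dose_response import (
    DoseResponseFit,
    StrainSummary,
    fits_from_curves,
    summarize_strain,
)
from .growth_metrics import (
    DEFAULT_LAG_THRESHOLD,
    LagCensoring,
    LagTime,
    lag_dose_slope,
    lag_time,
)
from .plate_io import (
    GrowthCurve,
    WellRecord,
    assemble_curves,
    blank_correct,
    read_od_timeseries,
    read_plate_layout,
)

logger = logging.getLogger(__name__)

CONTROL_ROLE_TO_STRAIN = {
    "control_mag1": "mag1",
    "control_rev1": "rev1",
    "control_rad14": "rad14",
    "wt_control": "WT",
}


@dataclass
class RunConfig:
    layout_path: str | Path
    readings_path: str | Path
    outdir: str | Path
    thresholds_mode: str = "from_controls"  # or "fixed"
    resistance_reference: str = "wt"
    lag_threshold: float = DEFAULT_LAG_THRESHOLD
    focal_dose: float = DEFAULT_FOCAL_DOSE
    som_seed: int = 0
    som_params: SOMParams = field(default_factory=SOMParams)
    cluster_sensitive_only: bool = True
    intercept_adjusted_gi50: bool = False


def load_run_config(path) -> RunConfig:
    """RunConfig from a flat YAML mapping; keys are the RunConfig field
    names, with ``som_params`` an optional nested mapping of SOMParams
    fields."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    som = data.pop("som_params", None)
    config = RunConfig(**data)
    if som:
        config.som_params = SOMParams(**som)
    return config


@dataclass
class ScreenResult:
    curves: list[GrowthCurve]
    fits: list[DoseResponseFit]
    summaries: dict[str, StrainSummary]
    thresholds: Thresholds
    classifications: dict[str, StrainClassification]
    som: object | None
    class_summary: dict | None
    heatmap_order: dict | None
    qc: dict


# ---------------------------------------------------------------------------
# analysis steps (library API; run_screen wires files through them)
# ---------------------------------------------------------------------------

def bundle_curves(bundle) -> list[GrowthCurve]:
    """Blank-correct and assemble a simulated bundle's plates in memory."""
    return assemble_curves(
        [blank_correct(p, bundle.layout) for p in bundle.plates], bundle.layout
    )

def untreated_lag(
    curves: Sequence[GrowthCurve], threshold: float = DEFAULT_LAG_THRESHOLD
) -> LagTime | None:
    """Per-strain untreated lag: mean of finite replicate lags, else the
    dominant censoring state."""
    lags = [lag_time(c.times, c.od, threshold) for c in curves if float(c.dose) == 0.0]
    if not lags:
        return None
    finite = [l for l in lags if l.is_finite]
    if finite:
        return LagTime(float(np.mean([l.hours for l in finite])), LagCensoring.NONE)
    right = [l for l in lags if l.censoring is LagCensoring.RIGHT]
    return right[0] if right else lags[0]


def strain_lag_dose_slope(
    curves: Sequence[GrowthCurve], threshold: float = DEFAULT_LAG_THRESHOLD
) -> float | None:
    """Slope of mean lag vs dose (h per %MMS) over doses with finite lags."""
    by_dose: dict[float, list[float]] = {}
    for c in curves:
        lag = lag_time(c.times, c.od, threshold)
        if lag.is_finite:
            by_dose.setdefault(float(c.dose), []).append(lag.hours)
    doses = sorted(by_dose)
    lags = [LagTime(float(np.mean(by_dose[d])), LagCensoring.NONE) for d in doses]
    return lag_dose_slope(doses, lags)


def summarize_all(
    curves: Sequence[GrowthCurve],
    *,
    lag_threshold: float = DEFAULT_LAG_THRESHOLD,
    intercept_adjusted: bool = False,
) -> tuple[list[DoseResponseFit], dict[str, StrainSummary]]:
    """Fit every replicate and aggregate per strain."""
    fits = fits_from_curves(curves, intercept_adjusted=intercept_adjusted)
    by_strain_fits: dict[str, list[DoseResponseFit]] = {}
    for f in fits:
        by_strain_fits.setdefault(f.strain_id, []).append(f)
    by_strain_curves: dict[str, list[GrowthCurve]] = {}
    for c in curves:
        by_strain_curves.setdefault(c.strain_id, []).append(c)
    summaries = {}
    for strain, sfits in sorted(by_strain_fits.items()):
        scurves = by_strain_curves.get(strain, [])
        summaries[strain] = summarize_strain(
            sfits,
            lag_untreated=untreated_lag(scurves, lag_threshold),
            lag_slope=strain_lag_dose_slope(scurves, lag_threshold),
        )
    return fits, summaries


def thresholds_from_summaries(
    summaries: Mapping[str, StrainSummary],
    layout: Sequence[WellRecord] | None = None,
    *,
    resistance_reference: str = "wt",
) -> Thresholds:
    """Anchor class boundaries on this batch's measured control GI50s."""
    control_ids = dict(CONTROL_ROLE_TO_STRAIN)
    if layout is not None:
        for rec in layout:
            if rec.role in control_ids and rec.strain_id:
                control_ids[rec.role] = rec.strain_id
    gi50s = {}
    for role, sid in control_ids.items():
        summ = summaries.get(sid)
        if summ is None or summ.gi50_mean is None:
            raise ValueError(f"control {sid} ({role}) has no valid GI50 in this batch")
        gi50s[role] = summ.gi50_mean
    return make_thresholds(
        gi50s["control_mag1"],
        gi50s["control_rev1"],
        gi50s["control_rad14"],
        gi50s["wt_control"],
        resistance_reference=resistance_reference,
    )


def classify_all(
    summaries: Mapping[str, StrainSummary], thresholds: Thresholds
) -> dict[str, StrainClassification]:
    return {
        sid: StrainClassification(
            sid,
            classify(s.gi50_mean, thresholds),
            flag_slow_grower(s.lag_untreated),
        )
        for sid, s in summaries.items()
    }


SENSITIVE_CATEGORIES = (
    Sensitivity.SEVERE,
    Sensitivity.INTERMEDIATE,
    Sensitivity.SLIGHT,
)


def cluster_sensitive(
    summaries: Mapping[str, StrainSummary],
    classifications: Mapping[str, StrainClassification],
    curves: Sequence[GrowthCurve],
    *,
    focal_dose: float = DEFAULT_FOCAL_DOSE,
    som_params: SOMParams | None = None,
    seed: int = 0,
    sensitive_only: bool = True,
):
    """SOM-cluster the (sensitive) strains' growth patterns at the focal dose."""
    if sensitive_only:
        keep = {
            sid: s
            for sid, s in summaries.items()
            if classifications[sid].category in SENSITIVE_CATEGORIES
        }
    else:
        keep = {sid: s for sid, s in summaries.items() if s.gi50_mean is not None}
    features = build_features(keep, curves, focal_dose)
    if len(features.strain_ids) < (som_params or SOMParams()).n_classes:
        return None, None, None, features
    som = train_som(features, som_params, seed)
    order = order_within_class(features, som.assignments)
    class_summary = summarize_classes(som.assignments, summaries)
    return som, class_summary, order, features


# ---------------------------------------------------------------------------
# file orchestration
# ---------------------------------------------------------------------------

def run_screen(config: RunConfig) -> ScreenResult:
    """Run the full analysis from layout + readings files, writing all
    result tables and an audit log under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("ingest")
        layout = read_plate_layout(config.layout_path)
        plates = read_od_timeseries(config.readings_path)
    except Exception as exc:
        raise RuntimeError(f"[ingest] {exc}") from exc

    try:
        stage("blank-correct + assemble")
        corrected = [blank_correct(p, layout) for p in plates]
        curves = assemble_curves(corrected, layout)
    except Exception as exc:
        raise RuntimeError(f"[curves] {exc}") from exc

    try:
        stage("dose response")
        fits, summaries = summarize_all(
            curves,
            lag_threshold=config.lag_threshold,
            intercept_adjusted=config.intercept_adjusted_gi50,
        )
    except Exception as exc:
        raise RuntimeError(f"[dose_response] {exc}") from exc

    try:
        stage("classification")
        if config.thresholds_mode == "fixed":
            thresholds = fixed_thresholds()
        else:
            thresholds = thresholds_from_summaries(
                summaries, layout, resistance_reference=config.resistance_reference
            )
        classifications = classify_all(summaries, thresholds)
    except Exception as exc:
        raise RuntimeError(f"[classification] {exc}") from exc

    try:
        stage("clustering")
        som, class_summary, order, _ = cluster_sensitive(
            summaries,
            classifications,
            curves,
            focal_dose=config.focal_dose,
            som_params=config.som_params,
            seed=config.som_seed,
            sensitive_only=config.cluster_sensitive_only,
        )
    except Exception as exc:
        raise RuntimeError(f"[clustering] {exc}") from exc

    n_tested = len(summaries)
    n_pass = sum(1 for s in summaries.values() if s.status == "ok")
    qc = {
        "version": __version__,
        "n_strains_tested": n_tested,
        "n_strains_passing": n_pass,
        "coverage_pct": _pct(n_pass, n_tested),
        "som_seed": config.som_seed,
        "thresholds_mode": config.thresholds_mode,
    }

    result = ScreenResult(
        curves, fits, summaries, thresholds, classifications, som, class_summary, order, qc
    )
    write_result_tables(result, outdir)
    return result


def write_result_tables(result: ScreenResult, outdir: Path) -> None:
    outdir = Path(outdir)
    from .growth_metrics import curve_metrics

    pd.DataFrame(
        [
            {
                "strain_id": c.strain_id,
                "dose": c.dose,
                "replicate_id": c.replicate_id,
                "auc": (m := curve_metrics(c.times, c.od)).auc,
                "lag_h": m.lag.hours,
                "lag_censoring": m.lag.censoring.value,
                "plateau": m.plateau,
            }
            for c in result.curves
        ]
    ).to_csv(outdir / "metrics.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "strain_id": f.strain_id,
                "replicate_id": f.replicate_id,
                "slope": f.slope,
                "intercept": f.intercept,
                "r2": f.r_squared,
                "gi50": f.gi50,
                "qc_pass": f.qc_pass,
            }
            for f in result.fits
        ]
    ).to_csv(outdir / "fits.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "strain_id": s.strain_id,
                "gi50_mean": s.gi50_mean,
                "gi50_sem": s.gi50_sem,
                "n_pass": s.n_pass,
                "n_total": s.n_total,
                "n_measurements": s.n_measurements,
                "status": s.status,
                "lag_untreated_h": s.lag_untreated.hours if s.lag_untreated else None,
                "lag_censoring": s.lag_untreated.censoring.value if s.lag_untreated else None,
                "lag_dose_slope": s.lag_dose_slope,
            }
            for s in result.summaries.values()
        ]
    ).to_csv(outdir / "summaries.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "strain_id": c.strain_id,
                "gi50_mean": result.summaries[c.strain_id].gi50_mean,
                "category": c.category.value,
                "slow_grower": c.slow_grower,
            }
            for c in result.classifications.values()
        ]
    ).to_csv(outdir / "classifications.tsv", sep="\t", index=False)

    if result.som is not None:
        pd.DataFrame(
            sorted(result.som.assignments.items()),
            columns=["strain_id", "som_class"],
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        rows = []
        for label, strains in result.heatmap_order.items():
            for pos, sid in enumerate(strains):
                rows.append({"som_class": label, "position": pos, "strain_id": sid})
        pd.DataFrame(rows).to_csv(outdir / "heatmap_order.tsv", sep="\t", index=False)

    with open(outdir / "run_log.txt", "w") as fh:
        for k, v in result.qc.items():
            fh.write(f"{k}\t{v}\n")


def _pct(num: int, den: int) -> float:
    """Percentage rounded half-up to one decimal (0.0 when den == 0)."""
    if den == 0:
        return 0.0
    return float(
        (Decimal(100) * Decimal(num) / Decimal(den)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def report(result: ScreenResult) -> str:
    """Plain-text summary: category counts with percentages, slow-grower
    fraction, and the control GI50 table."""
    lines = ["# Screen report", ""]
    summaries = result.summaries
    classifications = result.classifications
    analyzable = {
        sid for sid, c in classifications.items()
        if c.category is not Sensitivity.INSUFFICIENT_DATA
    }
    sensitive = [
        sid for sid in analyzable
        if classifications[sid].category in SENSITIVE_CATEGORIES
    ]
    lines.append(
        f"strains analyzed: {len(analyzable)} of {len(summaries)} tested "
        f"({_pct(len(analyzable), len(summaries))}% coverage)"
    )
    lines.append(
        f"sensitive strains: {len(sensitive)} of {len(analyzable)} "
        f"({_pct(len(sensitive), len(analyzable))}%)"
    )
    lines.append("")
    lines.append("category breakdown of sensitive strains:")
    for cat in SENSITIVE_CATEGORIES:
        n = sum(1 for sid in sensitive if classifications[sid].category is cat)
        lines.append(f"  {cat.value:<14} {n:>6}  ({_pct(n, len(sensitive))}%)")
    n_res = sum(
        1 for sid in analyzable if classifications[sid].category is Sensitivity.RESISTANT
    )
    lines.append(f"  {'resistant':<14} {n_res:>6}  ({_pct(n_res, len(analyzable))}%)")
    n_slow = sum(1 for c in classifications.values() if c.slow_grower)
    lines.append("")
    lines.append(
        f"slow-growers (untreated lag > 20 h): {n_slow} "
        f"({_pct(n_slow, len(summaries))}% of tested)"
    )
    lines.append("")
    lines.append("control GI50 (% MMS, mean +/- sem):")
    for sid in ("WT", "rad14", "rev1", "mag1"):
        s = summaries.get(sid)
        if s and s.gi50_mean is not None:
            sem = f"{s.gi50_sem:.4g}" if s.gi50_sem is not None else "nan"
            lines.append(f"  {sid:<6} {s.gi50_mean:.4g} +/- {sem}  (n={s.n_pass})")
    lines.append("")
    lines.append("thresholds (% MMS): severe<{0:g}, intermediate<{1:g}, slight<{2:g}, "
                 "resistant>{3:g}".format(
                     result.thresholds.severe_cut,
                     result.thresholds.intermediate_cut,
                     result.thresholds.slight_cut,
                     result.thresholds.resistance_cut,
                 ))
    if result.class_summary:
        lines.append("")
        lines.append("SOM growth-pattern classes (GI50 mean +/- sd):")
        for label, stats in sorted(result.class_summary.items()):
            mean = stats["gi50_mean"]
            sd = stats["gi50_sd"]
            lines.append(
                f"  class {label}: n={stats['n']}"
                + (f", GI50 {mean:.4g}" if mean is not None else "")
                + (f" +/- {sd:.4g}" if sd is not None else "")
            )
    return "\n".join(lines) + "\n"
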
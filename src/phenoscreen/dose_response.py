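"""AUC dose-response fitting, GI50 estimation and replicate aggregation.

For each replicate of a strain, the per-dose AUC is normalized by that
replicate's untreated (dose 0) AUC and regressed on dose by ordinary least
squares.  The regression's goodness of fit gates quality (R^2 > 0.7, strict),
and the slope yields the half-inhibitory dose via

    GI50 = -0.5 / slope        (defined only for negative slopes)

A strain summary (mean +/- s.e.m. of per-replicate GI50s) is reported only
when at least two replicates pass the gate.  An alternative GI50 reading
that accounts for a free intercept, (intercept - 0.5) / (-slope), is
available behind a switch and off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .growth_metrics import LagTime, lag_dose_slope, trapezoid_auc
from .plate_io import GrowthCurve

R2_QC_THRESHOLD = 0.7
MIN_PASSING_REPLICATES = 2


@dataclass(frozen=True)
class DoseResponseFit:
    """Per-replicate normalized-AUC regression."""

    strain_id: str
    replicate_id: str
    doses: tuple[float, ...]
    norm_auc: tuple[float, ...]
    slope: float | None
    intercept: float | None
    r_squared: float | None
    gi50: float | None
    qc_pass: bool
    n_timepoints: int = 0
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class StrainSummary:
    strain_id: str
    gi50_mean: float | None
    gi50_sem: float | None
    n_pass: int
    n_total: int
    n_measurements: int
    status: str  # "ok" | "insufficient_data"
    lag_untreated: LagTime | None = None
    lag_dose_slope: float | None = None
    essential_flag: bool = False


def normalize_aucs(aucs_by_dose: Mapping[float, float]) -> dict[float, float] | None:
    """Divide each dose's AUC by the same replicate's dose-0 AUC.

    Returns None when the untreated AUC is non-positive (the strain did not
    grow untreated; the replicate is unusable).
    """
    if 0.0 not in {float(d) for d in aucs_by_dose}:
        raise ValueError("dose 0 required for normalization")
    auc0 = next(v for d, v in aucs_by_dose.items() if float(d) == 0.0)
    if auc0 <= 0:
        return None
    return {float(d): v / auc0 for d, v in aucs_by_dose.items()}


def ols_fit(doses: Sequence[float], norm_auc: Sequence[float]) -> tuple[float, float, float | None]:
    """OLS of normalized AUC on dose with a free intercept.

    Returns (slope, intercept, r_squared); R^2 is None when the response is
    flat (zero total sum of squares), which downstream treats as a QC fail.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(norm_auc, dtype=float)
    if x.size < 3:
        raise ValueError("dose-response fit needs >=3 dose points")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("doses must not all coincide")
    slope = float(xc @ (y - y.mean()) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return slope, intercept, None
    ss_res = float(((y - (intercept + slope * x)) ** 2).sum())
    return slope, intercept, 1.0 - ss_res / ss_tot


def gi50_from_slope(
    slope: float, intercept: float = 1.0, *, intercept_adjusted: bool = False
) -> float | None:
    """Half-inhibition dose from the regression slope.

    Non-negative slopes (non-responsive or resistant replicates) yield None
    rather than an error so such replicates flow to the resistance rule.
    """
    if not math.isfinite(slope):
        raise ValueError("slope must be finite")
    if slope >= 0:
        return None
    if intercept_adjusted:
        return (intercept - 0.5) / (-slope)
    return -0.5 / slope


def replicate_qc(fit: DoseResponseFit) -> bool:
    """Pass iff R^2 strictly exceeds 0.7 and a GI50 is defined."""
    return (
        fit.r_squared is not None
        and fit.r_squared > R2_QC_THRESHOLD
        and fit.gi50 is not None
    )


def fit_replicate(
    strain_id: str,
    replicate_id: str,
    aucs_by_dose: Mapping[float, float],
    n_timepoints: int = 0,
    *,
    intercept_adjusted: bool = False,
) -> DoseResponseFit:
    """Normalize, regress and QC one replicate's dose series."""
    doses = tuple(sorted(float(d) for d in aucs_by_dose))
    norm = normalize_aucs(aucs_by_dose)
    if norm is None:
        return DoseResponseFit(
            strain_id, replicate_id, doses, (), None, None, None, None,
            qc_pass=False, n_timepoints=n_timepoints, flags=("no_untreated_growth",),
        )
    y = tuple(norm[d] for d in doses)
    slope, intercept, r2 = ols_fit(doses, y)
    gi50 = gi50_from_slope(slope, intercept, intercept_adjusted=intercept_adjusted)
    flags = []
    if gi50 is None:
        flags.append("non_responsive")
    if r2 is None:
        flags.append("flat_response")
    fit = DoseResponseFit(
        strain_id, replicate_id, doses, y, slope, intercept, r2, gi50,
        qc_pass=False, n_timepoints=n_timepoints, flags=tuple(flags),
    )
    return DoseResponseFit(**{**fit.__dict__, "qc_pass": replicate_qc(fit)})


def fits_from_curves(
    curves: Iterable[GrowthCurve], *, intercept_adjusted: bool = False
) -> list[DoseResponseFit]:
    """Group curves by (strain, replicate), compute per-dose AUCs and fit."""
    grouped: dict[tuple[str, str], dict[float, GrowthCurve]] = {}
    for c in curves:
        grouped.setdefault((c.strain_id, c.replicate_id), {})[float(c.dose)] = c
    fits = []
    for (strain, rep), by_dose in sorted(grouped.items()):
        if 0.0 not in by_dose or len(by_dose) < 3:
            continue
        aucs = {d: trapezoid_auc(c.times, c.od) for d, c in by_dose.items()}
        n_tp = sum(c.times.size for c in by_dose.values())
        fits.append(
            fit_replicate(strain, rep, aucs, n_tp, intercept_adjusted=intercept_adjusted)
        )
    return fits


def summarize_strain(
    fits: Sequence[DoseResponseFit],
    lag_untreated: LagTime | None = None,
    lag_slope: float | None = None,
    essential_flag: bool = False,
) -> StrainSummary:
    """Aggregate a strain's replicate fits into mean +/- s.e.m. GI50.

    The summary is marked ``insufficient_data`` unless at least two
    replicates pass QC; n_measurements counts OD readings in passing
    replicates only (10 time points x 5 doses x passing replicates).
    """
    if not fits:
        raise ValueError("at least one fit required")
    strain_id = fits[0].strain_id
    passing = [f for f in fits if f.qc_pass]
    n_measurements = sum(f.n_timepoints for f in passing)
    if len(passing) < MIN_PASSING_REPLICATES:
        return StrainSummary(
            strain_id, None, None, len(passing), len(fits), n_measurements,
            "insufficient_data", lag_untreated, lag_slope, essential_flag,
        )
    gi50s = np.array([f.gi50 for f in passing])
    sem = float(gi50s.std(ddof=1) / math.sqrt(gi50s.size))
    return StrainSummary(
        strain_id, float(gi50s.mean()), sem, len(passing), len(fits),
        n_measurements, "ok", lag_untreated, lag_slope, essential_flag,
    )


def subsample_timepoints(
    curves: Iterable[GrowthCurve], keep_times: Sequence[float]
) -> list[GrowthCurve]:
    """Restrict every curve to ``keep_times`` (must lie on the measured grid).

    Used to quantify how few time points the assay can afford; the downstream
    minimum-points drop rule still applies after subsampling.
    """
    keep = np.asarray(sorted(set(float(t) for t in keep_times)))
    if keep.size < 2:
        raise ValueError("keep_times must contain at least 2 time points")
    out = []
    for c in curves:
        mask = np.isin(c.times, keep)
        if mask.sum() != keep.size or not np.all(np.isin(keep, c.times)):
            raise ValueError(
                f"keep_times {keep.tolist()} not a subset of the measured grid "
                f"{c.times.tolist()}"
            )
        out.append(GrowthCurve(c.strain_id, c.dose, c.replicate_id, c.times[mask], c.od[mask]))
    return out


def gi50_concordance(
    summaries_a: Mapping[str, StrainSummary], summaries_b: Mapping[str, StrainSummary]
) -> float:
    """R^2 of OLS of dataset b's GI50s on dataset a's over common strains.

    The screen uses this to show a 6-point time grid reproduces the
    10-point GI50s.
    """
    common = [
        s
        for s in summaries_a
        if s in summaries_b
        and summaries_a[s].gi50_mean is not None
        and summaries_b[s].gi50_mean is not None
    ]
    if len(common) < 3:
        raise ValueError("need >=3 strains with defined GI50 in both datasets")
    a = [summaries_a[s].gi50_mean for s in common]
    b = [summaries_b[s].gi50_mean for s in common]
    _, _, r2 = ols_fit(a, b)
    if r2 is None:
        raise ValueError("GI50s constant across strains; concordance undefined")
    return r2
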
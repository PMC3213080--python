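"""Synthetic plate generator with known ground truth.

No raw screen data ships with this package, so every pipeline stage is
exercised against simulated 96-well plates: logistic growth curves over the
12-48 h window, five MMS doses, control strains at their fixed plate
positions, blank wells, replicates, and OD-reader-like noise (multiplicative
lognormal plus additive Gaussian).

Dose effect model
-----------------
Each strain carries a true GI50.  The target per-dose growth loss is

    g(d) = max(0, 1 - d / (2 * true_gi50))

so that the normalized AUC is linear in dose while positive and the
pipeline's GI50 = -0.5/slope recovers the truth exactly in the unclipped
regime (true GI50 >= d_max/2).  The *archetype* decides how that loss is
realized kinetically:

==============  ============================================================
linear_auc      whole curve scaled by g(d): pure amplitude, shape-invariant
wt_like         lag (midpoint) shifted until the grid AUC ratio equals g(d);
                plateau unchanged — the wild-type phenotype
class_i         amplitude scaled by g(d): reduced plateau, no induced lag
class_ii        growth rate reduced with dose, residual loss via amplitude —
                slower growth throughout
class_iii       midpoint strongly delayed and rate reduced with dose,
                residual via amplitude — long lag, slow recovery
profile         per-dose scale factors supplied explicitly
==============  ============================================================

For the kinetic archetypes the amplitude residual is calibrated against the
trapezoidal AUC on the configured time grid, so the noiseless pipeline sees
exactly linear (then clipped) normalized AUC for every archetype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .plate_io import (
    PlateTimeSeries,
    WellRecord,
    write_od_timeseries,
    write_plate_layout,
)

ARCHETYPES = ("wt_like", "class_i", "class_ii", "class_iii", "linear_auc", "profile")

#: printed control-strain GI50s (% MMS) used as generator defaults
CONTROL_GI50 = {"WT": 0.01, "rad14": 0.008, "rev1": 0.006, "mag1": 0.003}

#: fixed control well positions on every plate
CONTROL_WELLS = {
    "B11": ("WT", "wt_control"),
    "D3": ("WT", "wt_control"),
    "F5": ("WT", "wt_control"),
    "B12": ("rad14", "control_rad14"),
    "D4": ("rev1", "control_rev1"),
    "G5": ("mag1", "control_mag1"),
}
EMPTY_WELLS = ("A1", "H12")

# kinetic distortion strengths per unit s = dose / true_gi50.  Class ii
# pairs a strong rate reduction with a mild midpoint shift (slower growth
# pushes the half-maximum later), so its curves rise slowly through the
# whole window instead of saturating early like class i; class iii is
# dominated by the midpoint delay (long lag) with a slower recovery rate.
CLASS_II_RATE_FACTOR = 2.5
CLASS_II_LAG_SHIFT_H = 6.0
CLASS_III_LAG_SHIFT_H = 12.0
CLASS_III_RATE_FACTOR = 0.5

#: untreated midpoint giving a ~13 h visible-growth lag; slow growers use a
#: midpoint past 22.8 h so their untreated lag exceeds the 20 h rule
DEFAULT_GROWTH = dict(baseline=0.05, amplitude=1.0, rate=0.5, midpoint=16.0)
SLOW_GROWER_MIDPOINT = 26.0


@dataclass(frozen=True)
class GrowthParams:
    baseline: float   # OD of medium alone
    amplitude: float  # OD rise from baseline to plateau
    rate: float       # logistic steepness, per hour
    midpoint: float   # inflection time, hours

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.rate <= 0:
            raise ValueError("amplitude must be >=0 and rate > 0")


@dataclass(frozen=True)
class SimStrainSpec:
    strain_id: str
    true_gi50: float
    archetype: str = "linear_auc"
    growth: GrowthParams = GrowthParams(**DEFAULT_GROWTH)
    profile: tuple[float, ...] | None = None
    essential_flag: bool = False

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.true_gi50 <= 0:
            raise ValueError("true_gi50 must be positive")
        if self.archetype == "profile":
            if self.profile is None or abs(self.profile[0] - 1.0) > 1e-12:
                raise ValueError("profile archetype needs profile with profile[0] == 1")


@dataclass(frozen=True)
class SimConfig:
    doses: tuple[float, ...] = (0.0, 0.004, 0.008, 0.012, 0.016)
    times: tuple[float, ...] = tuple(float(t) for t in range(12, 49, 4))
    n_replicates: int = 3
    noise_sigma_mult: float = 0.05
    noise_sd_add: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if 0.0 not in self.doses:
            raise ValueError("doses must include 0")
        if min(self.times) < 12 or max(self.times) > 48:
            raise ValueError("times must lie within [12, 48] h")


def logistic_curve(params: GrowthParams, times: Sequence[float]) -> np.ndarray:
    """od(t) = baseline + amplitude / (1 + exp(-rate * (t - midpoint)))."""
    t = np.asarray(times, dtype=float)
    return params.baseline + params.amplitude / (
        1.0 + np.exp(-params.rate * (t - params.midpoint))
    )


def linear_auc_profile(true_gi50: float, doses: Sequence[float]) -> np.ndarray:
    """Per-dose scale factors g(d) = max(0, 1 - d/(2*true_gi50)).

    Scaling the blank-free signal by g(d) makes normalized AUC exactly
    linear in dose while positive.  When the top dose would need a negative
    factor (truth < d_max/2) the factor clips to 0 and a warning notes that
    the pipeline's GI50 estimate will be distorted for this strain.
    """
    if true_gi50 <= 0:
        raise ValueError("true_gi50 must be positive")
    d = np.asarray(doses, dtype=float)
    raw = 1.0 - d / (2.0 * true_gi50)
    if np.any(raw < 0):
        warnings.warn(
            f"true GI50 {true_gi50:g} < max dose/2: dose-response clipped at 0; "
            "GI50 estimates for this strain will exceed the truth",
            stacklevel=2,
        )
    return np.maximum(0.0, raw)


def _linear_target(true_gi50: float, dose: float) -> float:
    """g(d) without the public clipping warning (generator-internal)."""
    return max(0.0, 1.0 - dose / (2.0 * true_gi50))


def _grid_auc_unit(rate: float, midpoint: float, times: np.ndarray) -> float:
    """Trapezoidal AUC of the unit-amplitude logistic on the grid."""
    y = 1.0 / (1.0 + np.exp(-rate * (times - midpoint)))
    return float(np.trapezoid(y, times))


def apply_archetype(
    spec: SimStrainSpec, dose: float, times: Sequence[float] | None = None
) -> GrowthParams:
    """Growth parameters of ``spec`` at ``dose``.

    ``times`` is the measurement grid used to calibrate the amplitude
    residual (defaults to the standard 12-48 h, 4 h grid).  At dose 0 the
    untreated parameters are returned unchanged.
    """
    grid = np.asarray(
        times if times is not None else SimConfig().times, dtype=float
    )
    g0 = spec.growth
    if dose == 0:
        return g0
    if spec.archetype == "profile":
        doses_cfg = SimConfig().doses
        raise ValueError("profile archetype is resolved in simulate_well, not here")

    target = _linear_target(spec.true_gi50, dose)
    if spec.archetype == "linear_auc":
        return replace(g0, amplitude=g0.amplitude * target)
    if target == 0.0:
        return replace(g0, amplitude=0.0)

    s = dose / spec.true_gi50
    auc0 = _grid_auc_unit(g0.rate, g0.midpoint, grid)
    if spec.archetype == "class_i":
        # no induced lag: the whole loss is plateau reduction
        return replace(g0, amplitude=g0.amplitude * target)
    if spec.archetype == "wt_like":
        # prolonged lag, unchanged plateau: shift the midpoint until the
        # grid AUC ratio hits the target
        def f(m: float) -> float:
            return _grid_auc_unit(g0.rate, m, grid) / auc0 - target

        hi = grid[-1] + 200.0
        m = brentq(f, g0.midpoint, hi) if f(hi) < 0 else hi
        return replace(g0, midpoint=float(m))
    if spec.archetype == "class_ii":
        rate = g0.rate / (1.0 + CLASS_II_RATE_FACTOR * s)
        midpoint = g0.midpoint + CLASS_II_LAG_SHIFT_H * s
        ratio = _grid_auc_unit(rate, midpoint, grid) / auc0
        amp_scale = min(1.0, target / ratio)
        return replace(g0, rate=rate, midpoint=midpoint, amplitude=g0.amplitude * amp_scale)
    if spec.archetype == "class_iii":
        rate = g0.rate / (1.0 + CLASS_III_RATE_FACTOR * s)
        midpoint = g0.midpoint + CLASS_III_LAG_SHIFT_H * s
        ratio = _grid_auc_unit(rate, midpoint, grid) / auc0
        amp_scale = min(1.0, target / ratio)
        return replace(g0, rate=rate, midpoint=midpoint, amplitude=g0.amplitude * amp_scale)
    raise ValueError(f"unknown archetype {spec.archetype!r}")


def noiseless_signal(
    spec: SimStrainSpec, dose: float, times: Sequence[float], doses: Sequence[float]
) -> np.ndarray:
    """Blank-inclusive OD trace of a strain at one dose (no noise)."""
    t = np.asarray(times, dtype=float)
    g0 = spec.growth
    if spec.archetype == "profile":
        d_sorted = sorted(float(x) for x in doses)
        if len(spec.profile) != len(d_sorted):
            raise ValueError(
                f"{spec.strain_id}: profile length {len(spec.profile)} != "
                f"{len(d_sorted)} doses"
            )
        scale = dict(zip(d_sorted, spec.profile))[float(dose)]
        base = logistic_curve(g0, t)
        return g0.baseline + scale * (base - g0.baseline)
    params = apply_archetype(spec, dose, times)
    return logistic_curve(params, t)


# ---------------------------------------------------------------------------
# plates and libraries
# ---------------------------------------------------------------------------

_ROWS = "ABCDEFGH"
_ALL_WELLS = [f"{r}{c}" for r in _ROWS for c in range(1, 13)]
_QUERY_WELLS = [w for w in _ALL_WELLS if w not in CONTROL_WELLS and w not in EMPTY_WELLS]
MAX_QUERY_STRAINS = len(_QUERY_WELLS)  # 88


#: configured dose-response profiles for the severe controls.  Their true
#: GI50s (0.006, 0.003 % MMS) lie below half the top dose, where -0.5/slope
#: cannot return the truth for any normalized-AUC profile in [0, 1] on this
#: dose grid; these profiles instead give steep, QC-passing responses whose
#: measured GI50s (~0.00714, ~0.00690) keep the control ordering
#: mag1 < rev1 < rad14 so batch-anchored thresholds remain usable.
SEVERE_CONTROL_PROFILES = {
    "rev1": (1.0, 0.8, 0.25, 0.0, 0.0),
    "mag1": (1.0, 0.9, 0.1, 0.0, 0.0),
}


def control_specs() -> dict[str, SimStrainSpec]:
    """Default control-strain specs: WT and rad14 in exact linear-AUC mode
    (the pipeline recovers their printed GI50s exactly), rev1 and mag1 with
    configured steep dose-response profiles (see
    :data:`SEVERE_CONTROL_PROFILES`)."""
    return {
        "WT": SimStrainSpec("WT", CONTROL_GI50["WT"], "linear_auc"),
        "rad14": SimStrainSpec("rad14", CONTROL_GI50["rad14"], "linear_auc"),
        "rev1": SimStrainSpec(
            "rev1", CONTROL_GI50["rev1"], "profile", profile=SEVERE_CONTROL_PROFILES["rev1"]
        ),
        "mag1": SimStrainSpec(
            "mag1", CONTROL_GI50["mag1"], "profile", profile=SEVERE_CONTROL_PROFILES["mag1"]
        ),
    }


def plate_layout(
    plate_id: str, query_strains: Sequence[str]
) -> list[WellRecord]:
    """Layout with controls at their fixed wells, two blanks, and query
    strains filling the remaining wells row-major."""
    if len(query_strains) > MAX_QUERY_STRAINS:
        raise ValueError(
            f"at most {MAX_QUERY_STRAINS} query strains per plate, got {len(query_strains)}"
        )
    records = [
        WellRecord(plate_id, w, strain, role) for w, (strain, role) in CONTROL_WELLS.items()
    ]
    records += [WellRecord(plate_id, w, None, "empty") for w in EMPTY_WELLS]
    records += [
        WellRecord(plate_id, w, s, "query") for w, s in zip(_QUERY_WELLS, query_strains)
    ]
    records.sort(key=lambda r: (_ROWS.index(r.well[0]), int(r.well[1:])))
    return records


def simulate_plate(
    specs: Sequence[SimStrainSpec],
    config: SimConfig,
    *,
    plate_id: str = "P1",
    replicate_id: str = "R1",
    rng: np.random.Generator | None = None,
    include_controls: bool = True,
) -> tuple[list[WellRecord], list[PlateTimeSeries]]:
    """One plate (all doses) for one replicate.

    Controls occupy their fixed wells (their specs come from
    :func:`control_specs` unless a spec of the same strain_id is supplied),
    blanks emit baseline-only signal, and noise is applied as
    ``od * exp(eps_mult) + eps_add`` with seeded draws.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    spec_map = {s.strain_id: s for s in specs}
    ctrl = control_specs()
    if include_controls:
        for name, spec in ctrl.items():
            spec_map.setdefault(name, spec)
    query = [s.strain_id for s in specs if s.strain_id not in ctrl]
    layout = plate_layout(plate_id, query) if include_controls else [
        WellRecord(plate_id, w, s, "query") for w, s in zip(_QUERY_WELLS, query)
    ] + [WellRecord(plate_id, w, None, "empty") for w in EMPTY_WELLS]

    times = np.asarray(config.times)
    baseline = GrowthParams(**DEFAULT_GROWTH).baseline
    plates = []
    for dose in config.doses:
        readings: dict[str, np.ndarray] = {}
        for rec in layout:
            if rec.role == "empty":
                clean = np.full(times.shape, baseline)
            else:
                spec = spec_map[rec.strain_id]
                clean = noiseless_signal(spec, dose, times, config.doses)
            if config.noise_sigma_mult > 0 or config.noise_sd_add > 0:
                mult = np.exp(rng.normal(0.0, config.noise_sigma_mult, times.shape)) \
                    if config.noise_sigma_mult > 0 else 1.0
                add = rng.normal(0.0, config.noise_sd_add, times.shape) \
                    if config.noise_sd_add > 0 else 0.0
                clean = clean * mult + add
            readings[rec.well] = clean
        plates.append(PlateTimeSeries(plate_id, float(dose), replicate_id, times.copy(), readings))
    return layout, plates


@dataclass
class SimBundle:
    layout: list[WellRecord]
    plates: list[PlateTimeSeries]
    truth: pd.DataFrame  # strain_id, true_gi50, archetype, class_label, slow_grower, essential_flag
    config: SimConfig


#: per-archetype (mean, sd) of true GI50 draws, % MMS — class values follow
#: the observed per-cluster GI50 distributions of the screen
DEFAULT_TRUTH_DISTRIBUTIONS = {
    "wt_like": (0.01, 0.002),
    "linear_auc": (0.01, 0.002),
    "class_i": (0.0067, 0.0016),
    "class_ii": (0.0071, 0.0010),
    "class_iii": (0.0053, 0.0016),
}
_MIN_TRUE_GI50 = 5e-4


def simulate_library(
    n_strains: int,
    class_mixture: Mapping[str, float],
    config: SimConfig,
    *,
    slow_grower_fraction: float = 0.067,
    truth_distributions: Mapping[str, tuple[float, float]] | None = None,
    essential_fraction: float = 0.0,
    plate_prefix: str = "P",
) -> SimBundle:
    """Multi-plate, multi-replicate library with a ground-truth table.

    ``class_mixture`` maps archetype names to fractions summing to 1; true
    GI50s are drawn per archetype from ``truth_distributions`` (normal,
    truncated below at 5e-4 % MMS).  A ``slow_grower_fraction`` of strains
    gets an untreated midpoint past the 20 h lag rule.  Replicates are
    separate plate sets with independent seeded noise; all randomness flows
    from ``config.seed``.
    """
    fracs = dict(class_mixture)
    if abs(sum(fracs.values()) - 1.0) > 1e-9:
        raise ValueError(f"mixture fractions must sum to 1, got {sum(fracs.values())}")
    for a in fracs:
        if a not in ARCHETYPES:
            raise ValueError(f"unknown archetype {a!r} in mixture")
    dists = dict(DEFAULT_TRUTH_DISTRIBUTIONS)
    if truth_distributions:
        dists.update(truth_distributions)

    rng = np.random.default_rng(config.seed)
    # deterministic largest-remainder allocation of strains to archetypes
    archetypes = sorted(fracs)
    quotas = {a: fracs[a] * n_strains for a in archetypes}
    counts = {a: int(np.floor(quotas[a])) for a in archetypes}
    rest = n_strains - sum(counts.values())
    for a in sorted(archetypes, key=lambda a: quotas[a] - counts[a], reverse=True)[:rest]:
        counts[a] += 1

    specs: list[SimStrainSpec] = []
    truth_rows = []
    i = 0
    for arche in archetypes:
        mu, sd = dists[arche]
        for _ in range(counts[arche]):
            i += 1
            sid = f"S{i:04d}"
            gi50 = float(np.clip(rng.normal(mu, sd), _MIN_TRUE_GI50, None))
            slow = bool(rng.random() < slow_grower_fraction)
            essential = bool(rng.random() < essential_fraction)
            growth = GrowthParams(**{**DEFAULT_GROWTH,
                                     **({"midpoint": SLOW_GROWER_MIDPOINT} if slow else {})})
            specs.append(SimStrainSpec(sid, gi50, arche, growth, essential_flag=essential))
            truth_rows.append(
                {
                    "strain_id": sid,
                    "true_gi50": gi50,
                    "archetype": arche,
                    "class_label": arche if arche.startswith("class_") else "",
                    "slow_grower": slow,
                    "essential_flag": essential,
                }
            )

    layout_all: list[WellRecord] = []
    plates_all: list[PlateTimeSeries] = []
    n_plates = max(1, int(np.ceil(len(specs) / MAX_QUERY_STRAINS)))
    for p in range(n_plates):
        plate_specs = specs[p * MAX_QUERY_STRAINS:(p + 1) * MAX_QUERY_STRAINS]
        plate_id = f"{plate_prefix}{p + 1}"
        for r in range(config.n_replicates):
            rep_rng = np.random.default_rng([config.seed, p, r])
            layout, plates = simulate_plate(
                plate_specs, config, plate_id=plate_id,
                replicate_id=f"R{r + 1}", rng=rep_rng,
            )
            if r == 0:
                layout_all.extend(layout)
            plates_all.extend(plates)

    truth = pd.DataFrame(truth_rows)
    return SimBundle(layout_all, plates_all, truth, config)


def write_bundle(bundle: SimBundle, outdir) -> dict[str, Path]:
    """Write layout TSV, readings CSV and ground-truth TSV under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "layout": outdir / "layout.tsv",
        "readings": outdir / "readings.csv",
        "truth": outdir / "ground_truth.tsv",
    }
    write_plate_layout(bundle.layout, paths["layout"])
    write_od_timeseries(bundle.plates, paths["readings"])
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
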
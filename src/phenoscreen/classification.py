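"""Control-anchored sensitivity classification and slow-grower flagging.

The three sensitive control strains anchor the class boundaries: the severe
cut is the mag1-null GI50, the intermediate cut the rev1-null GI50 and the
slight cut the rad14-null GI50.  Resistance is called above a threshold
reflected about the slight cut:

    resistance_cut = GI50_ref + (GI50_ref - GI50_rad14)

where the reference is the wild-type mean by default ("wt" mode); reading it
as the three-control average is available ("controls" mode) but puts the
threshold below WT, so it is not the default.  Boundary ties resolve toward
the less-sensitive class (strict ``<`` at every cut).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .growth_metrics import LagCensoring, LagTime

SLOW_GROWER_LAG_H = 20.0

#: published class boundaries (% MMS) for the fixed-thresholds mode
FIXED_SEVERE = 0.003
FIXED_INTERMEDIATE = 0.006
FIXED_SLIGHT = 0.008
FIXED_WT = 0.01


class Sensitivity(str, Enum):
    SEVERE = "severe"
    INTERMEDIATE = "intermediate"
    SLIGHT = "slight"
    NOT_SENSITIVE = "not_sensitive"
    RESISTANT = "resistant"
    INSUFFICIENT_DATA = "insufficient_data"


#: ordering from most to least sensitive, for monotonicity checks
SENSITIVITY_ORDER = (
    Sensitivity.SEVERE,
    Sensitivity.INTERMEDIATE,
    Sensitivity.SLIGHT,
    Sensitivity.NOT_SENSITIVE,
    Sensitivity.RESISTANT,
)


@dataclass(frozen=True)
class Thresholds:
    severe_cut: float
    intermediate_cut: float
    slight_cut: float
    resistance_cut: float

    def __post_init__(self) -> None:
        cuts = (self.severe_cut, self.intermediate_cut, self.slight_cut, self.resistance_cut)
        if not (0 < cuts[0] < cuts[1] < cuts[2] < cuts[3]):
            raise ValueError(f"thresholds must be strictly increasing and positive: {cuts}")


@dataclass(frozen=True)
class StrainClassification:
    strain_id: str
    category: Sensitivity
    slow_grower: bool


def make_thresholds(
    gi50_mag1: float,
    gi50_rev1: float,
    gi50_rad14: float,
    gi50_wt: float,
    *,
    resistance_reference: str = "wt",
) -> Thresholds:
    """Build class boundaries from measured control GI50s.

    Controls must order mag1 < rev1 < rad14; a violation means the control
    strains failed in this batch and the run cannot be anchored.  Note the
    "controls" resistance reference (2*mean(controls) - rad14) can never
    exceed rad14 for a validly ordered triple, so that reading always fails
    threshold validation; it exists to document the rejected interpretation.
    """
    if not (0 < gi50_mag1 < gi50_rev1 < gi50_rad14):
        raise ValueError(
            "control GI50 ordering violated (need mag1 < rev1 < rad14): "
            f"{gi50_mag1}, {gi50_rev1}, {gi50_rad14}"
        )
    if resistance_reference == "wt":
        ref = gi50_wt
    elif resistance_reference == "controls":
        ref = (gi50_mag1 + gi50_rev1 + gi50_rad14) / 3.0
    else:
        raise ValueError(f"unknown resistance_reference {resistance_reference!r}")
    resistance_cut = ref + (ref - gi50_rad14)
    return Thresholds(gi50_mag1, gi50_rev1, gi50_rad14, resistance_cut)


def fixed_thresholds() -> Thresholds:
    """The published boundaries (0.003/0.006/0.008, resistance 0.012 % MMS)."""
    return make_thresholds(FIXED_SEVERE, FIXED_INTERMEDIATE, FIXED_SLIGHT, FIXED_WT)


def classify(gi50: float | None, thresholds: Thresholds) -> Sensitivity:
    """Total step function of GI50 onto sensitivity categories."""
    if gi50 is None:
        return Sensitivity.INSUFFICIENT_DATA
    if gi50 < thresholds.severe_cut:
        return Sensitivity.SEVERE
    if gi50 < thresholds.intermediate_cut:
        return Sensitivity.INTERMEDIATE
    if gi50 < thresholds.slight_cut:
        return Sensitivity.SLIGHT
    if gi50 > thresholds.resistance_cut:
        return Sensitivity.RESISTANT
    return Sensitivity.NOT_SENSITIVE


def flag_slow_grower(lag_untreated: LagTime | None) -> bool:
    """Slow-grower: untreated lag strictly exceeding 20 h, or a lag that
    never crossed the growth threshold inside the window (right-censored)."""
    if lag_untreated is None:
        return False
    if lag_untreated.censoring is LagCensoring.RIGHT:
        return True
    return lag_untreated.is_finite and lag_untreated.hours > SLOW_GROWER_LAG_H
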
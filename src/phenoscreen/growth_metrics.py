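"""Per-curve growth summaries: AUC, lag time, lag-dose slope, plateau.

The area under the blank-corrected growth curve over the measured 12-48 h
window is the screen's primary growth readout; lag time (first crossing of a
visible-growth OD threshold) is the secondary one.  Lag values that never
cross the threshold inside the window are censored at the window bounds and
flagged as such rather than silently clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.integrate import trapezoid

#: default blank-corrected OD regarded as "visible growth"
DEFAULT_LAG_THRESHOLD = 0.2


class LagCensoring(str, Enum):
    NONE = "none"
    LEFT = "left"    # already above threshold at the first sample
    RIGHT = "right"  # never crosses the threshold in the window


@dataclass(frozen=True)
class LagTime:
    hours: float
    censoring: LagCensoring

    @property
    def is_finite(self) -> bool:
        return self.censoring is LagCensoring.NONE


@dataclass(frozen=True)
class CurveMetrics:
    auc: float
    lag: LagTime
    plateau: float


def trapezoid_auc(times: Sequence[float], od: Sequence[float]) -> float:
    """Trapezoidal integral of OD over the measured window, floored at 0.

    Flooring keeps normalized AUC meaningful when a no-growth trace sits
    slightly below the blank.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and od must have equal length")
    if t.size < 2:
        raise ValueError("AUC needs at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must strictly increase")
    return max(0.0, float(trapezoid(y, t)))


def lag_time(
    times: Sequence[float],
    od: Sequence[float],
    od_threshold: float = DEFAULT_LAG_THRESHOLD,
) -> LagTime:
    """Earliest time the curve reaches ``od_threshold``.

    Linearly interpolated between the bracketing samples.  A curve already at
    or above the threshold at the first sample is left-censored at the window
    start; one that never reaches it is right-censored at the window end.
    """
    if od_threshold <= 0:
        raise ValueError("od_threshold must be positive")
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if y[0] >= od_threshold:
        return LagTime(float(t[0]), LagCensoring.LEFT)
    above = np.nonzero(y >= od_threshold)[0]
    if above.size == 0:
        return LagTime(float(t[-1]), LagCensoring.RIGHT)
    i = int(above[0])
    t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
    crossing = t0 + (t1 - t0) * (od_threshold - y0) / (y1 - y0)
    return LagTime(float(crossing), LagCensoring.NONE)


def lag_dose_slope(doses: Sequence[float], lags: Sequence[LagTime]) -> float | None:
    """OLS slope of lag time vs dose (h per %MMS) over non-censored lags.

    Returns None (undefined, to be flagged) with fewer than 3 finite lags.
    """
    pairs = [(d, l.hours) for d, l in zip(doses, lags) if l.is_finite]
    if len(pairs) < 3:
        return None
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def plateau(od: Sequence[float]) -> float:
    """Mean of the last two measured OD values — the end-of-window plateau."""
    y = np.asarray(od, dtype=float)
    if y.size < 2:
        raise ValueError("plateau needs at least 2 points")
    return float(y[-2:].mean())


def curve_metrics(
    times: Sequence[float],
    od: Sequence[float],
    od_threshold: float = DEFAULT_LAG_THRESHOLD,
) -> CurveMetrics:
    return CurveMetrics(
        auc=trapezoid_auc(times, od),
        lag=lag_time(times, od, od_threshold),
        plateau=plateau(od),
    )
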
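"""Plate layouts, OD600 time-series I/O, blank correction and curve assembly.

The screen's raw data are 96-well microtiter plates read every 4 h between
12 and 48 h after transfer to drug-containing medium.  This module turns the
two on-disk artifacts — a plate layout (which strain sits in which well, plus
control and blank wells) and a long-format table of OD readings — into
blank-corrected per-strain growth curves that the downstream dose-response
machinery consumes.

File formats
------------
layout TSV    columns: plate_id, well, strain_id, role
readings CSV  columns: plate_id, replicate_id, dose_pct_mms, well, time_h, od600
curves TSV    columns: strain_id, dose, replicate_id, time_h, od_corrected
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WELL_RE = re.compile(r"^[A-H](1[0-2]|[1-9])$")

ROLES = frozenset(
    {"query", "wt_control", "control_rad14", "control_rev1", "control_mag1", "empty"}
)
CONTROL_ROLES = frozenset({"wt_control", "control_rad14", "control_rev1", "control_mag1"})

#: minimum number of time points for a curve to enter the analysis
MIN_TIMEPOINTS = 6


class PlateParseError(ValueError):
    """Raised for malformed layout or readings files (message names the line)."""


@dataclass(frozen=True)
class WellRecord:
    """One well of a plate layout."""

    plate_id: str
    well: str
    strain_id: str | None
    role: str

    def __post_init__(self) -> None:
        if not WELL_RE.match(self.well):
            raise PlateParseError(f"malformed well address {self.well!r} (expected A1..H12)")
        if self.role not in ROLES:
            raise PlateParseError(f"unknown role {self.role!r} for well {self.well}")
        if self.role == "empty" and self.strain_id:
            raise PlateParseError(f"empty well {self.well} must not carry a strain_id")
        if self.role != "empty" and not self.strain_id:
            raise PlateParseError(f"non-empty well {self.well} requires a strain_id")


@dataclass
class PlateTimeSeries:
    """OD600 readings of one plate at one dose for one replicate.

    ``readings`` maps well address to an OD vector on the shared ``times``
    grid; all wells of a plate share the same strictly increasing grid.
    """

    plate_id: str
    dose: float
    replicate_id: str
    times: np.ndarray
    readings: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"plate {self.plate_id}: time points must strictly increase")
        for well, od in self.readings.items():
            od = np.asarray(od, dtype=float)
            if od.shape != self.times.shape:
                raise ValueError(
                    f"plate {self.plate_id} well {well}: "
                    f"{od.size} readings for {self.times.size} time points"
                )
            if not np.all(np.isfinite(od)):
                raise ValueError(f"plate {self.plate_id} well {well}: non-finite OD")
            self.readings[well] = od


@dataclass(frozen=True)
class GrowthCurve:
    """Blank-corrected OD trajectory of one strain at one dose in one replicate."""

    strain_id: str
    dose: float
    replicate_id: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "od", np.asarray(self.od, dtype=float))
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have equal length")


# ---------------------------------------------------------------------------
# layout I/O
# ---------------------------------------------------------------------------

def read_plate_layout(path, *, strict: bool = False) -> list[WellRecord]:
    """Parse a layout TSV into :class:`WellRecord` s.

    Duplicate (plate_id, well) pairs and grammar violations raise
    :class:`PlateParseError` naming the offending line.  With ``strict=True``
    every plate must carry at least two blank wells and at least one well per
    control role, mirroring the screen's plate design.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["plate_id", "well", "strain_id", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PlateParseError(f"{path}: layout missing columns {missing}")

    records: list[WellRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = (row.plate_id, row.well)
        if key in seen:
            raise PlateParseError(f"{path}:{i}: duplicate well {row.well} on plate {row.plate_id}")
        seen.add(key)
        try:
            records.append(
                WellRecord(row.plate_id, row.well, row.strain_id or None, row.role)
            )
        except PlateParseError as exc:
            raise PlateParseError(f"{path}:{i}: {exc}") from None

    if strict:
        _validate_plate_design(records)
    return records


def _validate_plate_design(records: Sequence[WellRecord]) -> None:
    by_plate: dict[str, list[WellRecord]] = {}
    for rec in records:
        by_plate.setdefault(rec.plate_id, []).append(rec)
    for plate_id, recs in by_plate.items():
        n_empty = sum(r.role == "empty" for r in recs)
        if n_empty < 2:
            raise PlateParseError(f"plate {plate_id}: needs >=2 empty wells, found {n_empty}")
        present = {r.role for r in recs}
        absent = CONTROL_ROLES - present
        if absent:
            raise PlateParseError(f"plate {plate_id}: missing control roles {sorted(absent)}")


def write_plate_layout(records: Iterable[WellRecord], path) -> None:
    pd.DataFrame(
        [
            {"plate_id": r.plate_id, "well": r.well, "strain_id": r.strain_id or "", "role": r.role}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# readings I/O
# ---------------------------------------------------------------------------

def read_od_timeseries(path) -> list[PlateTimeSeries]:
    """Read a long-format OD CSV into one :class:`PlateTimeSeries` per
    (plate, replicate, dose), enforcing a common time grid per plate."""
    df = pd.read_csv(path)
    required = ["plate_id", "replicate_id", "dose_pct_mms", "well", "time_h", "od600"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PlateParseError(f"{path}: readings missing columns {missing}")
    for col in ("dose_pct_mms", "time_h", "od600"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna()].index[0] + 2
            raise PlateParseError(f"{path}:{bad}: non-numeric value in column {col}")
        df[col] = vals

    out: list[PlateTimeSeries] = []
    for (plate_id, rep, dose), grp in df.groupby(
        ["plate_id", "replicate_id", "dose_pct_mms"], sort=True
    ):
        grids = {
            well: tuple(np.sort(g["time_h"].to_numpy()))
            for well, g in grp.groupby("well")
        }
        unique_grids = set(grids.values())
        if len(unique_grids) != 1:
            raise PlateParseError(
                f"{path}: inconsistent time grid across wells of plate {plate_id} "
                f"(replicate {rep}, dose {dose})"
            )
        times = np.array(next(iter(unique_grids)), dtype=float)
        readings = {}
        for well, g in grp.groupby("well"):
            g = g.sort_values("time_h")
            readings[str(well)] = g["od600"].to_numpy(dtype=float)
        out.append(PlateTimeSeries(str(plate_id), float(dose), str(rep), times, readings))
    return out


def write_od_timeseries(plates: Iterable[PlateTimeSeries], path) -> None:
    rows = []
    for p in plates:
        for well in sorted(p.readings):
            for t, od in zip(p.times, p.readings[well]):
                rows.append(
                    {
                        "plate_id": p.plate_id,
                        "replicate_id": p.replicate_id,
                        "dose_pct_mms": p.dose,
                        "well": well,
                        "time_h": t,
                        "od600": od,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# blank correction and curve assembly
# ---------------------------------------------------------------------------

def blank_correct(plate: PlateTimeSeries, layout: Sequence[WellRecord]) -> PlateTimeSeries:
    """Subtract the per-time-point mean OD of this plate's empty wells from
    every well.  Negative corrected values are retained, not floored."""
    empty_wells = [
        r.well for r in layout if r.plate_id == plate.plate_id and r.role == "empty"
    ]
    empty_present = [w for w in empty_wells if w in plate.readings]
    if not empty_present:
        raise ValueError(f"plate {plate.plate_id}: no empty wells available for blanking")
    blank = np.mean([plate.readings[w] for w in empty_present], axis=0)
    corrected = {w: od - blank for w, od in plate.readings.items()}
    return PlateTimeSeries(plate.plate_id, plate.dose, plate.replicate_id, plate.times.copy(), corrected)


def assemble_curves(
    plates: Iterable[PlateTimeSeries],
    layout: Sequence[WellRecord],
    *,
    min_timepoints: int = MIN_TIMEPOINTS,
) -> list[GrowthCurve]:
    """Join blank-corrected plates against the layout into per-strain curves.

    One curve per (strain, dose, replicate).  Curves with fewer than
    ``min_timepoints`` samples are dropped with a logged warning; a well with
    readings but no layout entry is an error.
    """
    layout_map: dict[tuple[str, str], WellRecord] = {
        (r.plate_id, r.well): r for r in layout
    }
    curves: list[GrowthCurve] = []
    for plate in plates:
        for well, od in plate.readings.items():
            rec = layout_map.get((plate.plate_id, well))
            if rec is None:
                raise ValueError(
                    f"plate {plate.plate_id} well {well}: readings present but well "
                    "not in layout"
                )
            if rec.role == "empty":
                continue
            if plate.times.size < min_timepoints:
                logger.warning(
                    "dropping curve %s dose=%g replicate=%s: only %d time points (<%d)",
                    rec.strain_id, plate.dose, plate.replicate_id,
                    plate.times.size, min_timepoints,
                )
                continue
            curves.append(
                GrowthCurve(rec.strain_id, plate.dose, plate.replicate_id, plate.times, od)
            )
    return curves


def write_curves(curves: Iterable[GrowthCurve], path) -> None:
    rows = []
    for c in curves:
        for t, od in zip(c.times, c.od):
            rows.append(
                {
                    "strain_id": c.strain_id,
                    "dose": c.dose,
                    "replicate_id": c.replicate_id,
                    "time_h": t,
                    "od_corrected": od,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
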
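"""Capture--recapture records and their reduction to per-individual growth intervals.

The raw datum is a capture event: a marked individual, its sex, the capture
date, and its snout--vent length (SVL, mm).  Growth is measured between two
captures of the same animal as

    GR = (SVL2 - SVL1) / elapsed days,

taken by default from the first to the last capture of each individual, and
retained only when the elapsed time falls inside a configurable window
(30--100 days by default).  Each interval also carries the reference length
used as the model predictor (midpoint of SVL1 and SVL2 by default), the
age class at first capture (sex-specific SVL thresholds), the calendrical
season (wet = July--November) and the year.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidIntervalError, SchemaError

__all__ = [
    "SEXES",
    "WET_MONTHS",
    "AgeClassRule",
    "DEFAULT_AGE_RULES",
    "GrowthInterval",
    "growth_rate",
    "assign_age_class",
    "assign_season",
    "extract_interval",
    "extract_intervals",
    "read_captures",
    "write_captures",
    "read_intervals",
    "write_intervals",
]

SEXES = ("male", "female", "unknown")

#: calendar months of the tropical wet season at the study site
WET_MONTHS = frozenset({7, 8, 9, 10, 11})

#: plausible SVL bounds (mm) used to flag suspect captures
SVL_BOUNDS = (10.0, 80.0)

CAPTURE_COLUMNS = ["id", "sex", "date", "svl_mm", "mass_g"]
INTERVAL_COLUMNS = [
    "id",
    "sex",
    "year",
    "season",
    "age_class",
    "l1_mm",
    "l2_mm",
    "days",
    "gr_mm_per_day",
    "l_ref_mm",
]


@dataclass(frozen=True)
class AgeClassRule:
    """Sex-specific SVL limits separating juveniles from adults.

    ``juvenile_range`` is the nominal juvenile SVL span (mm); ``adult_min``
    is the threshold above which an animal is an adult.  Lengths in the gap
    between the juvenile upper bound and the adult threshold (and below the
    juvenile lower bound, i.e. hatchling-sized animals) classify as juvenile:
    only lengths strictly above ``adult_min`` are adult.
    """

    juvenile_range: tuple[float, float]
    adult_min: float

    def __post_init__(self) -> None:
        if self.juvenile_range[1] > self.adult_min:
            raise ValueError("juvenile upper bound must not exceed adult threshold")

    def classify(self, svl: float) -> str:
        if svl <= 0:
            raise ValueError("svl must be positive")
        return "adult" if svl > self.adult_min else "juvenile"


#: field-standard thresholds: juvenile males 25-31 mm / adults > 32 mm,
#: juvenile females 25-34 mm / adults > 35 mm
DEFAULT_AGE_RULES: dict[str, AgeClassRule] = {
    "male": AgeClassRule((25.0, 31.0), 32.0),
    "female": AgeClassRule((25.0, 34.0), 35.0),
}


@dataclass(frozen=True)
class GrowthInterval:
    """One individual's growth datum between two captures."""

    individual_id: str
    sex: str
    l1: float
    l2: float
    days: int
    gr: float
    l_ref: float
    age_class: str
    season: str
    year: int
    date_first: _dt.date
    date_last: _dt.date

    @property
    def shrinkage(self) -> bool:
        """True when the animal measured smaller at the end of the interval."""
        return self.gr < 0

    @property
    def mid_date(self) -> _dt.date:
        return self.date_first + _dt.timedelta(days=self.days // 2)


def growth_rate(l1: float, l2: float, days: int) -> float:
    """Growth rate ``(l2 - l1)/days`` in mm/day.

    Negative values (apparent shrinkage, normally measurement error) are
    returned as-is; callers flag them via :attr:`GrowthInterval.shrinkage`.
    """
    if days <= 0:
        raise InvalidIntervalError(f"elapsed days must be positive, got {days}")
    if l1 <= 0 or l2 <= 0:
        raise InvalidIntervalError("lengths must be positive")
    return (l2 - l1) / days


def assign_age_class(svl: float, sex: str, rules: dict[str, AgeClassRule] | None = None) -> str:
    """Classify an SVL as juvenile or adult using sex-specific thresholds."""
    rules = DEFAULT_AGE_RULES if rules is None else rules
    if sex not in rules:
        raise ValueError(f"no age-class rule for sex {sex!r}")
    return rules[sex].classify(svl)


def assign_season(date, wet_months: frozenset[int] = WET_MONTHS) -> str:
    """Calendrical wet/dry season of a date (wet = July--November)."""
    month = pd.Timestamp(date).month
    return "wet" if month in wet_months else "dry"


def _interval_from_captures(
    individual_id,
    sex,
    first,
    last,
    window: tuple[int, int],
    l_ref: str,
    rules: dict[str, AgeClassRule] | None,
) -> GrowthInterval | None:
    d1 = pd.Timestamp(first["date"]).date()
    d2 = pd.Timestamp(last["date"]).date()
    days = (d2 - d1).days
    if not (window[0] <= days <= window[1]):
        return None
    l1, l2 = float(first["svl_mm"]), float(last["svl_mm"])
    gr = growth_rate(l1, l2, days)
    if l_ref == "midpoint":
        ref = 0.5 * (l1 + l2)
    elif l_ref == "l1":
        ref = l1
    else:
        raise ValueError(f"unknown l_ref mode {l_ref!r}")
    return GrowthInterval(
        individual_id=str(individual_id),
        sex=str(sex),
        l1=l1,
        l2=l2,
        days=days,
        gr=gr,
        l_ref=ref,
        age_class=assign_age_class(l1, sex, rules),
        season=assign_season(d1),
        year=d1.year,
        date_first=d1,
        date_last=d2,
    )


def extract_interval(
    history: pd.DataFrame,
    window: tuple[int, int] = (30, 100),
    l_ref: str = "midpoint",
    rules: dict[str, AgeClassRule] | None = None,
) -> GrowthInterval | None:
    """Reduce one individual's capture history to a single growth interval.

    The interval spans the first to the last capture; None is returned when
    the individual was captured fewer than twice or the span falls outside
    ``window`` (days).  Age class, season and year are taken at the first
    capture; the reference length is the midpoint of the two SVLs (or the
    first SVL with ``l_ref='l1'``).
    """
    if len(history) == 0:
        raise ValueError("history is empty")
    if history["id"].nunique() > 1:
        raise ValueError("history mixes individuals")
    if len(history) < 2:
        return None
    history = history.sort_values("date", kind="stable")
    first = history.iloc[0]
    last = history.iloc[-1]
    return _interval_from_captures(
        first["id"], first["sex"], first, last, window, l_ref, rules
    )


def extract_intervals(
    captures: pd.DataFrame,
    window: tuple[int, int] = (30, 100),
    l_ref: str = "midpoint",
    per_pair: bool = False,
    drop_shrinkage: bool = False,
    rules: dict[str, AgeClassRule] | None = None,
) -> pd.DataFrame:
    """Extract growth intervals from a capture table (one row per capture).

    Parameters
    ----------
    captures
        Table with columns id, sex, date, svl_mm (mass_g optional).
    window
        Inclusive (min, max) elapsed days an interval may span.
    l_ref
        'midpoint' (default) or 'l1': reference length used as predictor.
    per_pair
        When True, every consecutive capture pair inside the window yields an
        interval; the default is one interval per individual (first to last
        capture).
    drop_shrinkage
        When True, intervals with negative growth are excluded instead of
        flagged.

    Returns
    -------
    DataFrame with one row per interval plus ``shrinkage`` flag and the
    interval's first/mid dates for downstream monthly aggregation.
    """
    _require_columns(captures, ["id", "sex", "date", "svl_mm"], "captures")
    out: list[GrowthInterval] = []
    for _, hist in captures.groupby("id", sort=True):
        hist = hist.sort_values("date", kind="stable")
        sex = hist["sex"].iloc[0]
        if (hist["sex"] != sex).any():
            raise SchemaError(f"individual {hist['id'].iloc[0]!r} has conflicting sex")
        if per_pair:
            rows = list(hist.iterrows())
            for (_, a), (_, b) in zip(rows[:-1], rows[1:]):
                iv = _interval_from_captures(a["id"], sex, a, b, window, l_ref, rules)
                if iv is not None:
                    out.append(iv)
        else:
            if len(hist) < 2:
                continue
            iv = _interval_from_captures(
                hist["id"].iloc[0], sex, hist.iloc[0], hist.iloc[-1], window, l_ref, rules
            )
            if iv is not None:
                out.append(iv)
    if drop_shrinkage:
        out = [iv for iv in out if not iv.shrinkage]
    return intervals_to_frame(out)


def intervals_to_frame(intervals: list[GrowthInterval]) -> pd.DataFrame:
    """Convert GrowthInterval objects to the tabular interval layout."""
    frame = pd.DataFrame(
        [
            {
                "id": iv.individual_id,
                "sex": iv.sex,
                "year": iv.year,
                "season": iv.season,
                "age_class": iv.age_class,
                "l1_mm": iv.l1,
                "l2_mm": iv.l2,
                "days": iv.days,
                "gr_mm_per_day": iv.gr,
                "l_ref_mm": iv.l_ref,
                "shrinkage": iv.shrinkage,
                "date_first": iv.date_first,
                "mid_date": iv.mid_date,
            }
            for iv in intervals
        ]
    )
    if frame.empty:
        frame = pd.DataFrame(
            columns=INTERVAL_COLUMNS + ["shrinkage", "date_first", "mid_date"]
        )
    return frame


def _require_columns(frame: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def read_captures(path, study_window: tuple[str, str] | None = None) -> pd.DataFrame:
    """Read a capture CSV (columns id, sex, date, svl_mm, mass_g).

    Rows with SVL outside plausible bounds, an unknown sex label, or (when a
    study window is given) a date outside it are flagged in a boolean
    ``valid`` column rather than dropped.
    """
    frame = pd.read_csv(path, dtype={"id": str})
    _require_columns(frame, ["id", "sex", "date", "svl_mm"], "captures")
    if "mass_g" not in frame.columns:
        frame["mass_g"] = np.nan
    try:
        frame["date"] = pd.to_datetime(frame["date"], format="ISO8601")
    except ValueError as exc:
        raise SchemaError(f"captures: unparseable date: {exc}") from exc
    if not frame["svl_mm"].map(np.isreal).all():
        raise SchemaError("captures: svl_mm must be numeric")
    valid = frame["svl_mm"].between(*SVL_BOUNDS) & frame["sex"].isin(SEXES)
    if study_window is not None:
        lo, hi = (pd.Timestamp(d) for d in study_window)
        valid &= frame["date"].between(lo, hi)
    frame["valid"] = valid
    return frame


def write_captures(frame: pd.DataFrame, path) -> None:
    out = frame[CAPTURE_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_intervals(frame: pd.DataFrame, path) -> None:
    frame[INTERVAL_COLUMNS].to_csv(path, index=False)


def read_intervals(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"id": str})
    _require_columns(frame, INTERVAL_COLUMNS, "intervals")
    return frame
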
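"""Prey-availability and climate series: aggregation, richness, monthly alignment.

Sweep-net samples are recorded per arthropod order ("prey category"); for
Coleoptera, Hymenoptera and Lepidoptera the larval and adult forms count as
separate categories, all other orders carry an unspecified life stage.  The
package bundles the two-year Chamela prey-availability survey (1989--1990,
wet season July--November) as a reference dataset.

Climate records are one row per year-month (mean temperature degC, total
precipitation mm) and are aligned with monthly prey totals and category
richness for the growth-environment correlation stage.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import AlignmentError, SchemaError
from .records import WET_MONTHS, assign_season

__all__ = [
    "STAGE_SPLIT_ORDERS",
    "load_reference_prey",
    "read_prey",
    "read_climate",
    "aggregate_prey",
    "category_richness",
    "monthly_env_table",
]

#: orders whose larvae and adults are distinct prey categories
STAGE_SPLIT_ORDERS = frozenset({"Coleoptera", "Hymenoptera", "Lepidoptera"})

PREY_COLUMNS = ["year", "season", "category", "life_stage", "count"]
CLIMATE_COLUMNS = ["year", "month", "temp_c", "precip_mm"]


def load_reference_prey() -> pd.DataFrame:
    """The bundled 1989--1990 Chamela prey-availability survey table."""
    ref = resources.files("lizardgrowth.data") / "chamela_prey_1989_1990.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def _validate_prey(samples: pd.DataFrame) -> pd.DataFrame:
    required = ["year", "category", "count"]
    missing = [c for c in required if c not in samples.columns]
    if missing:
        raise SchemaError(f"prey table is missing column(s): {', '.join(missing)}")
    if (samples["count"] < 0).any():
        raise SchemaError("prey counts must be non-negative")
    samples = samples.copy()
    if "life_stage" not in samples.columns:
        samples["life_stage"] = "unspecified"
    if "season" not in samples.columns:
        if "month" not in samples.columns:
            raise SchemaError("prey table needs a season or month column")
        samples["season"] = samples["month"].map(
            lambda m: "wet" if m in WET_MONTHS else "dry"
        )
    return samples


def read_prey(path) -> pd.DataFrame:
    return _validate_prey(pd.read_csv(path))


def read_climate(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in CLIMATE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"climate table is missing column(s): {', '.join(missing)}")
    if (frame["precip_mm"] < 0).any():
        raise SchemaError("precipitation must be non-negative")
    return frame


def _filter(samples: pd.DataFrame, year=None, season=None) -> pd.DataFrame:
    samples = _validate_prey(samples)
    if year is not None:
        samples = samples[samples["year"] == year]
    if season is not None:
        samples = samples[samples["season"] == season]
    return samples


def aggregate_prey(samples: pd.DataFrame, year=None, season=None) -> int:
    """Total prey individuals matching the (year, season) filter; empty -> 0."""
    return int(_filter(samples, year, season)["count"].sum())


def category_richness(samples: pd.DataFrame, year=None, season=None) -> int:
    """Distinct prey categories (order x life stage) with a positive total."""
    sub = _filter(samples, year, season)
    totals = sub.groupby(["category", "life_stage"], observed=True)["count"].sum()
    return int((totals > 0).sum())


def monthly_env_table(prey: pd.DataFrame, climate: pd.DataFrame) -> pd.DataFrame:
    """Align monthly prey totals and richness with climate records.

    ``prey`` must carry a month column (dated sweep samples); the bundled
    season-level survey table cannot be aligned monthly.  Rows missing either
    side are kept and flagged ``complete=False``.  Duplicate climate records
    for one year-month raise.
    """
    prey = _validate_prey(prey)
    if "month" not in prey.columns:
        raise SchemaError("monthly alignment needs dated prey samples (month column)")
    if climate.duplicated(["year", "month"]).any():
        raise SchemaError("duplicate climate record for a year-month")
    prey_m = (
        prey.groupby(["year", "month"])
        .apply(
            lambda g: pd.Series(
                {
                    "prey_count": g["count"].sum(),
                    "prey_categories": (
                        g.groupby(["category", "life_stage"], observed=True)["count"].sum() > 0
                    ).sum(),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    merged = prey_m.merge(climate[CLIMATE_COLUMNS], on=["year", "month"], how="outer")
    if merged.empty:
        raise AlignmentError("prey and climate series share no year-months")
    merged["season"] = merged["month"].map(lambda m: "wet" if m in WET_MONTHS else "dry")
    merged["complete"] = merged[["prey_count", "temp_c", "precip_mm"]].notna().all(axis=1)
    return merged.sort_values(["year", "month"], ignore_index=True)
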
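"""Performance-record ingestion and preparation.

Race records carry one horse's finishing time (or average speed) in one race
plus the race- and horse-level covariates the mixed models condition on.
Times are converted to average speed in yards per second by dividing the
race distance (in yards) by the finishing time; races are grouped into
sprint (5-7 furlongs), middle-distance (8-12 furlongs) and long-distance
(14-20 furlongs) categories, with 220 yards to the furlong.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

YARDS_PER_FURLONG = 220

#: covariates a prepared record must carry (besides speed)
REQUIRED_COLUMNS = [
    "horse", "race_id", "distance", "going", "n_runners", "timing",
    "racecourse", "year", "age", "sex", "trainer",
]


class RecordsError(ValueError):
    """Invalid performance-record input."""


# ---------------------------------------------------------------------------
# speed conversion
# ---------------------------------------------------------------------------


def time_to_speed(finish_time, distance):
    """Average speed (yards/s) from finishing time (s) and distance (yards).

    Accepts scalars or arrays; both inputs must be strictly positive.
    """
    t = np.asarray(finish_time, dtype=float)
    d = np.asarray(distance, dtype=float)
    if np.any(t <= 0) or np.any(d <= 0):
        raise RecordsError("finish_time and distance must be strictly positive")
    out = d / t
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# distance categories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceCategory:
    """A window of race distances, inclusive at both ends, in furlongs."""

    name: str
    min_furlongs: float
    max_furlongs: float

    @property
    def min_yards(self) -> float:
        return self.min_furlongs * YARDS_PER_FURLONG

    @property
    def max_yards(self) -> float:
        return self.max_furlongs * YARDS_PER_FURLONG

    def contains(self, distance_yards) -> np.ndarray:
        d = np.asarray(distance_yards, dtype=float)
        return (d >= self.min_yards) & (d <= self.max_yards)


DEFAULT_CATEGORIES = (
    DistanceCategory("sprint", 5, 7),
    DistanceCategory("middle", 8, 12),
    DistanceCategory("long", 14, 20),
)


def _check_no_overlap(categories) -> None:
    cats = sorted(categories, key=lambda c: c.min_furlongs)
    for a, b in zip(cats, cats[1:]):
        if b.min_furlongs <= a.max_furlongs:
            raise RecordsError(
                f"distance categories {a.name!r} and {b.name!r} overlap"
            )


def assign_category(distance_yards, categories=DEFAULT_CATEGORIES):
    """Name of the category containing a distance, or ``None`` in a gap.

    13-furlong races, for instance, fall between the default middle and
    long windows and map to ``None``.
    """
    _check_no_overlap(categories)
    d = np.asarray(distance_yards, dtype=float)
    if np.any(d <= 0):
        raise RecordsError("distance must be positive")
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    out = np.array([None] * d.size, dtype=object)
    for cat in categories:
        out[cat.contains(d)] = cat.name
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# age factor
# ---------------------------------------------------------------------------

MIN_AGE = 2
AGE_CAP = 11  # ages 11 and above collapse into an open-ended "11+" level


def collapse_age(age):
    """Map age in years to the 10-level factor "2".."10", "11+".

    Few horses race beyond 11, so later ages are pooled.
    """
    a = np.asarray(age)
    if np.any(a < MIN_AGE):
        raise RecordsError(f"racehorse age must be >= {MIN_AGE}")
    scalar = a.ndim == 0
    a = np.atleast_1d(a)
    out = np.where(a >= AGE_CAP, "11+", a.astype(int).astype(str)).astype(object)
    return str(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# table ingestion / preparation
# ---------------------------------------------------------------------------


def read_records(path, sep: str = ",") -> pd.DataFrame:
    """Read a delimited performance-record table.

    Either ``finish_time`` or ``speed`` must be present; speed is derived
    from time and distance when absent.  When both are present their
    consistency (speed * time = distance) is enforced.
    """
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RecordsError(f"records table lacks columns {missing}")
    if "speed" not in df.columns and "finish_time" not in df.columns:
        raise RecordsError("records table needs a finish_time or speed column")
    if "speed" not in df.columns:
        df["speed"] = time_to_speed(df["finish_time"], df["distance"])
    elif "finish_time" in df.columns:
        both = df["finish_time"].notna() & df["speed"].notna()
        err = np.abs(
            df.loc[both, "speed"] * df.loc[both, "finish_time"]
            - df.loc[both, "distance"]
        )
        if np.any(err > 1e-6 * df.loc[both, "distance"]):
            raise RecordsError("speed * finish_time != distance for some records")
    return validate_records(df)


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Type coercion and invariant checks for a record table."""
    df = df.copy()
    for col in ("distance", "going", "speed"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("n_runners", "year", "age"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    for col in ("horse", "race_id", "timing", "racecourse", "sex", "trainer"):
        df[col] = df[col].astype(str)
    bad = (df["speed"] <= 0) | (df["distance"] <= 0) | (df["n_runners"] < 1)
    if bad.any():
        raise RecordsError(
            f"{int(bad.sum())} records violate speed>0 / distance>0 / n_runners>=1"
        )
    if (df["age"] < MIN_AGE).any():
        raise RecordsError(f"records with age < {MIN_AGE} present")
    return df


def prepare_records(
    df: pd.DataFrame,
    category: str | None = None,
    categories=DEFAULT_CATEGORIES,
) -> pd.DataFrame:
    """Subset to one distance category and finalise model covariates.

    Adds the collapsed ``age_class`` factor, drops records with any missing
    required covariate (count logged), and — when ``category`` is given —
    keeps only records inside that category's distance window.
    """
    df = df.copy()
    needed = REQUIRED_COLUMNS + ["speed"]
    n0 = len(df)
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    dropped = n0 - len(df)
    if dropped:
        logger.info("dropped %d records with missing covariates", dropped)
    if category is not None:
        names = [c.name for c in categories]
        if category not in names:
            raise RecordsError(f"unknown distance category {category!r}")
        cat = assign_category(df["distance"].to_numpy(), categories)
        df = df[cat == category]
        if not len(df):
            raise RecordsError(f"no records in distance category {category!r}")
    df["age_class"] = collapse_age(df["age"].to_numpy())
    return df.reset_index(drop=True)
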
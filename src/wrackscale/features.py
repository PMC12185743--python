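"""Regression-ready site-level tables: seasonal means, circular orientation,
wave means."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import CoastGeometry

__all__ = [
    "SEASONS",
    "SEASON_OF_MONTH",
    "season_of_month",
    "season_of_quarter",
    "seasonal_mean_response",
    "orientation_components",
    "build_design_table",
]

logger = logging.getLogger(__name__)

SEASONS = ("winter", "spring", "summer", "fall")

# Jan-Mar winter, Apr-Jun spring, Jul-Sep summer, Oct-Dec fall
SEASON_OF_MONTH = {m: SEASONS[(m - 1) // 3] for m in range(1, 13)}


def season_of_month(month: int) -> str:
    if month not in SEASON_OF_MONTH:
        raise ValueError(f"month must be 1..12, got {month}")
    return SEASON_OF_MONTH[month]


def season_of_quarter(quarter: str) -> str:
    """Season of a calendar-quarter label like ``"2016Q1"`` (Q1 -> winter)."""
    q = int(quarter[-1])
    if quarter[-2] != "Q" or q not in (1, 2, 3, 4):
        raise ValueError(f"malformed quarter label {quarter!r}")
    return SEASONS[q - 1]


def seasonal_mean_response(
    surveys: pd.DataFrame, season: str = "all", value_col: str = "plant_count"
) -> pd.Series:
    """Per-segment arithmetic mean of ``value_col`` over surveys in ``season``.

    ``season="all"`` uses every survey.  Segments with no survey in the
    selected season (or only missing values) are excluded with a logged
    warning; callers drop them from the model.
    """
    if season != "all" and season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    df = surveys
    if season != "all":
        months = pd.to_datetime(df["survey_date"]).dt.month
        df = df[months.map(SEASON_OF_MONTH) == season]
    df = df.dropna(subset=[value_col])
    means = df.groupby("segment_id")[value_col].mean()
    missing = set(surveys["segment_id"].unique()) - set(means.index)
    if missing:
        logger.warning(
            "%d segment(s) have no %r surveys in season %r and are excluded: %s",
            len(missing),
            value_col,
            season,
            sorted(missing)[:10],
        )
    return means.sort_index()


def orientation_components(orientation_deg) -> tuple[np.ndarray, np.ndarray]:
    """(sine, cosine) of a compass bearing in degrees.

    The sine is the east-west component, the cosine the north-south component.
    """
    deg = np.asarray(orientation_deg, dtype=float)
    if not np.all(np.isfinite(deg)):
        raise ValueError("orientation must be finite")
    rad = np.deg2rad(deg)
    return np.sin(rad), np.cos(rad)


def build_design_table(
    surveys: pd.DataFrame,
    geometry: CoastGeometry,
    waves: pd.DataFrame,
    biomass: np.ndarray,
    season: str = "all",
    response_col: str = "plant_count",
) -> pd.DataFrame:
    """One row per segment: response mean, biomass at a radius, drivers, order.

    ``biomass`` is the per-segment buffer sum (aligned with the geometry's
    segment order).  Width is the seasonal (or overall) mean of the surveyed
    dry widths; the wave column is the per-segment mean significant wave
    height (the ``"all"`` window, or a season-named window when present in
    the wave table).  Segments lacking a seasonal response are dropped.
    """
    response = seasonal_mean_response(surveys, season, response_col)
    width = seasonal_mean_response(surveys, season, "dry_width_m")

    wv = waves
    if season != "all" and "window" in waves.columns:
        if (waves["window"] == season).any():
            wv = waves[waves["window"] == season]
        else:
            wv = waves[waves["window"] == "all"]
    hs = wv.set_index("segment_id")["mean_hs_m"]

    sin_o, cos_o = orientation_components(geometry.orientation_deg)
    base = pd.DataFrame(
        {
            "segment_id": geometry.segment_ids,
            "order_index": np.arange(1, geometry.n_segments + 1),
            "biomass": np.asarray(biomass, dtype=float),
            "sin_orientation": sin_o,
            "cos_orientation": cos_o,
        }
    ).set_index("segment_id")
    base["response"] = response
    base["mean_width_m"] = width
    base["mean_hs_m"] = hs
    out = base.dropna(subset=["response", "mean_width_m", "mean_hs_m"]).reset_index()
    cols = [
        "segment_id",
        "order_index",
        "response",
        "biomass",
        "mean_width_m",
        "cos_orientation",
        "sin_orientation",
        "mean_hs_m",
    ]
    return out[cols]
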
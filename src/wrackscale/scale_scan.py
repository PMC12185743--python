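"""Radius scan: fit the response against the biomass column at every candidate
radius and select the scale of effect.

Local design: GLS with ARMA(1,1) alongshore correlation, ranked by the overall
regression F.  Regional design: OLS, ranked by r^2.  A non-significant optimum
is still reported, flagged ``significant=False``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features
from .geo_aggregate import BiomassByRadius, RadiusGrid, aggregate_biomass, temporal_mean_biomass
from .gls_arma import fit_gls
from .types import CanopyRaster, CoastGeometry

__all__ = ["ScanResult", "scan_radii", "select_optimum", "seasonal_scan"]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class ScanResult:
    """Per-radius fit statistics plus the selected optimum.

    ``statistic`` is the overall F in GLS mode and r^2 in OLS mode; NaN marks
    radii whose model was degenerate (constant biomass column) — those are
    excluded from the argmax.
    """

    radii_km: np.ndarray
    statistic: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    optimal_radius_km: float
    optimal_statistic: float
    optimal_p_value: float
    optimal_significant: bool
    method: str
    season: str = "all"
    n: int = 0
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "radius_km": self.radii_km,
                "statistic": self.statistic,
                "p_value": self.p_value,
                "significant": self.significant,
            }
        )

    def summary(self) -> dict:
        return {
            "method": self.method,
            "season": self.season,
            "n": self.n,
            "optimal_radius_km": float(self.optimal_radius_km),
            "optimal_statistic": float(self.optimal_statistic),
            "optimal_p_value": float(self.optimal_p_value),
            "significant": bool(self.optimal_significant),
        }


def select_optimum(radii_km: np.ndarray, statistic: np.ndarray) -> int:
    """Index of the maximal statistic; ties break to the smallest radius.

    NaN statistics (failed radii) are skipped.  Raises on an empty or
    all-failed scan.
    """
    radii_km = np.asarray(radii_km, dtype=float)
    statistic = np.asarray(statistic, dtype=float)
    if len(radii_km) == 0:
        raise ValueError("empty scan: no radii fitted")
    ok = np.isfinite(statistic)
    if not ok.any():
        raise ValueError("scan failed at every radius")
    best = np.nanmax(statistic)
    # first index attaining the max among ascending radii -> smallest radius
    order = np.argsort(radii_km, kind="stable")
    for j in order:
        if ok[j] and statistic[j] == best:
            return int(j)
    raise AssertionError("unreachable")


def scan_radii(
    response: pd.Series | np.ndarray,
    biomass: BiomassByRadius,
    method: str = "gls",
    season: str = "all",
) -> ScanResult:
    """One intercept+biomass model per radius; optimum by max statistic.

    ``response`` must align with ``biomass.segment_ids`` (a pandas Series is
    reindexed by segment id; segments missing a response are dropped from
    every radius model).
    """
    if method not in ("gls", "ols"):
        raise ValueError(f"unknown method {method!r}")
    ids = np.asarray(biomass.segment_ids)
    if isinstance(response, pd.Series):
        y_full = response.reindex(ids).to_numpy(dtype=float)
    else:
        y_full = np.asarray(response, dtype=float)
        if len(y_full) != len(ids):
            raise ValueError("response length does not match biomass segment ids")
    keep = np.isfinite(y_full)
    y = y_full[keep]
    if len(y) < 3:
        raise ValueError("need at least 3 segments with responses")

    radii = biomass.radii_km
    nr = len(radii)
    stat = np.full(nr, np.nan)
    pval = np.full(nr, np.nan)
    for j in range(nr):
        x = biomass.values[keep, j]
        if np.ptp(x) < 1e-12:
            logger.warning(
                "radius %.3g km skipped: constant biomass column (undefined slope)",
                radii[j],
            )
            continue
        X = np.column_stack([np.ones(len(y)), x])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # adjust_se off: the scan ranks by F / r^2, which are RSS-based
            fit = fit_gls(y, X, names=["intercept", "biomass"], mode=method, adjust_se=False)
        if method == "gls":
            stat[j] = fit.f_value
        else:
            stat[j] = fit.r2
        pval[j] = fit.f_p_value

    jopt = select_optimum(radii, stat)
    significant = pval < ALPHA
    return ScanResult(
        radii_km=radii.copy(),
        statistic=stat,
        p_value=pval,
        significant=significant,
        optimal_radius_km=float(radii[jopt]),
        optimal_statistic=float(stat[jopt]),
        optimal_p_value=float(pval[jopt]),
        optimal_significant=bool(pval[jopt] < ALPHA),
        method=method,
        season=season,
        n=len(y),
    )


def seasonal_scan(
    surveys: pd.DataFrame,
    raster: CanopyRaster,
    geometry: CoastGeometry,
    radii: RadiusGrid,
    method: str = "gls",
    response_col: str = "plant_count",
) -> dict[str, ScanResult]:
    """Per-season radius scans with season-matched biomass quarters.

    The response is the per-season segment mean; biomass is re-aggregated
    from the raster quarters whose calendar quarter falls in the season.
    Seasons with no surveys (or no matching quarters) are skipped with a
    warning.
    """
    months = pd.to_datetime(surveys["survey_date"]).dt.month
    present = set(months.map(features.SEASON_OF_MONTH))
    out: dict[str, ScanResult] = {}
    for season in features.SEASONS:
        if season not in present:
            logger.warning("season %r has no surveys; skipped", season)
            continue
        quarters = [q for q in raster.quarters if features.season_of_quarter(q) == season]
        if not quarters:
            logger.warning("season %r has no raster quarters; skipped", season)
            continue
        mean_b = temporal_mean_biomass(raster, quarters)
        bbr = aggregate_biomass(mean_b, raster, geometry, radii)
        response = features.seasonal_mean_response(surveys, season, response_col)
        out[season] = scan_radii(response, bbr, method=method, season=season)
    return out
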
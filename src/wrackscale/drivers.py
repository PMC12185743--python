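"""Multi-predictor driver models at the selected radius, with AIC-based
candidate selection.

Candidates always contain the intercept and the biomass term; the default set
is {full model, full model without the wave-height term}.  Each candidate is
fitted by :func:`wrackscale.gls_arma.fit_gls` and the minimum-AIC candidate is
selected (ties break to the candidate with fewer predictors, then first
listed).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .gls_arma import ArmaParams, GlsFit, fit_gls

__all__ = ["PREDICTORS", "CandidateSet", "DriversFit", "fit_drivers", "direction_of_effect"]

# design-table column -> coefficient label
PREDICTORS = {
    "biomass": "canopy_biomass",
    "mean_width_m": "beach_width",
    "cos_orientation": "cos_orientation",
    "sin_orientation": "sin_orientation",
    "mean_hs_m": "wave_height",
}

FULL = tuple(PREDICTORS)
NO_WAVE = tuple(c for c in FULL if c != "mean_hs_m")


@dataclass(frozen=True)
class CandidateSet:
    """Predictor subsets to compare by AIC; each must include biomass."""

    candidates: tuple[tuple[str, ...], ...] = (FULL, NO_WAVE)

    def __post_init__(self) -> None:
        if len(self.candidates) == 0:
            raise ValueError("candidate set must be nonempty")
        for cand in self.candidates:
            if "biomass" not in cand:
                raise ValueError(f"candidate {cand!r} lacks the biomass predictor")
            unknown = set(cand) - set(PREDICTORS)
            if unknown:
                raise ValueError(f"unknown predictors {sorted(unknown)!r}")

    @classmethod
    def all_subsets(cls) -> "CandidateSet":
        """Every predictor subset that contains biomass (generic option)."""
        others = [c for c in FULL if c != "biomass"]
        cands = []
        for k in range(len(others), -1, -1):
            for combo in combinations(others, k):
                cands.append(tuple(c for c in FULL if c == "biomass" or c in combo))
        return cls(tuple(cands))


@dataclass
class DriversFit:
    """Fitted candidates, their AICs, and the selected model."""

    candidates: tuple[tuple[str, ...], ...]
    aic: np.ndarray
    fits: list[GlsFit]
    selected_index: int
    mode: str
    season: str = "all"

    @property
    def selected(self) -> GlsFit:
        return self.fits[self.selected_index]

    @property
    def selected_predictors(self) -> tuple[str, ...]:
        return self.candidates[self.selected_index]

    def coef_frame(self) -> pd.DataFrame:
        """Selected model's coefficient table (predictor, t-value, p-value)."""
        fit = self.selected
        return pd.DataFrame(
            {
                "predictor": fit.names,
                "estimate": fit.beta,
                "se": fit.se,
                "t_value": fit.t_values,
                "p_value": fit.p_values,
            }
        )

    def aic_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "candidate": [" + ".join(c) for c in self.candidates],
                "n_predictors": [len(c) for c in self.candidates],
                "aic": self.aic,
                "selected": [i == self.selected_index for i in range(len(self.candidates))],
            }
        )


def fit_drivers(
    design: pd.DataFrame,
    mode: str = "gls",
    candidates: CandidateSet | None = None,
    fixed_params: ArmaParams | None = None,
    season: str = "all",
) -> DriversFit:
    """Fit every candidate driver model and select the minimum-AIC one.

    ``design`` is a table from :func:`wrackscale.features.build_design_table`
    (rows already in alongshore order).  Ties in AIC break toward fewer
    predictors, then candidate-list order.
    """
    candidates = candidates or CandidateSet()
    needed = {c for cand in candidates.candidates for c in cand}
    missing = needed - set(design.columns)
    if missing:
        raise ValueError(f"design table lacks columns {sorted(missing)!r}")
    if design[["response", *sorted(needed)]].isna().any().any():
        raise ValueError("design table contains missing values")
    max_k = max(len(c) for c in candidates.candidates) + 1
    if len(design) <= max_k + 3:
        raise ValueError(
            f"need n > {max_k + 3} rows for the largest candidate, got {len(design)}"
        )

    y = design["response"].to_numpy(dtype=float)
    fits: list[GlsFit] = []
    aics = np.empty(len(candidates.candidates))
    for i, cand in enumerate(candidates.candidates):
        X = np.column_stack(
            [np.ones(len(design))] + [design[c].to_numpy(dtype=float) for c in cand]
        )
        names = ["intercept"] + [PREDICTORS[c] for c in cand]
        fit = fit_gls(y, X, names=names, mode=mode, fixed_params=fixed_params)
        fits.append(fit)
        aics[i] = fit.aic

    sizes = np.array([len(c) for c in candidates.candidates])
    order = np.lexsort((np.arange(len(aics)), sizes, np.round(aics, 9)))
    selected = int(order[0])
    return DriversFit(
        candidates=candidates.candidates,
        aic=aics,
        fits=fits,
        selected_index=selected,
        mode=mode,
        season=season,
    )


def direction_of_effect(
    fit: GlsFit | DriversFit,
    directions_deg: tuple[float, ...] = (90.0, 135.0, 180.0, 225.0, 270.0),
) -> dict:
    """Evaluate the fitted orientation surface over candidate facing directions.

    Computes ``b_cos * cos(d) + b_sin * sin(d)`` for each direction and
    returns the directions of minimum and maximum predicted deposition.
    """
    gls = fit.selected if isinstance(fit, DriversFit) else fit
    try:
        b_cos = gls.beta[gls.names.index("cos_orientation")]
        b_sin = gls.beta[gls.names.index("sin_orientation")]
    except ValueError:
        raise ValueError("fit lacks the orientation components") from None
    d = np.asarray(directions_deg, dtype=float)
    rad = np.deg2rad(d)
    surface = b_cos * np.cos(rad) + b_sin * np.sin(rad)
    return {
        "directions_deg": d,
        "effect": surface,
        "min_direction_deg": float(d[int(np.argmin(surface))]),
        "max_direction_deg": float(d[int(np.argmax(surface))]),
    }
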
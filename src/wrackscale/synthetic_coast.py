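"""Seeded synthetic coastal datasets with known ground truth.

Generates the two survey designs the analysis expects:

* a *local* design — a continuous coastline partitioned into equal segments,
  surveyed monthly, and
* a *regional* design — a couple dozen irregularly spaced beach sites with a
  handful of replicate surveys and an additional areal wrack-cover response.

The response is built from a planted linear model: the biomass predictor is
the buffer sum at exactly the true radius ``R*`` (computed with the same
aggregation operator the analysis uses), driver covariates enter with known
coefficients, and the noise is a mean-zero ARMA(1,1) field over the
alongshore segment order plus independent per-survey noise.  Counts are
floored at zero.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .geo_aggregate import RadiusGrid, aggregate_biomass, temporal_mean_biomass
from .gls_arma import ArmaParams
from .types import CanopyRaster, CoastGeometry

__all__ = [
    "RasterSpec",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_arma11",
    "simulate_local_surveys",
    "generate_local_dataset",
    "generate_regional_dataset",
    "local_defaults",
    "regional_defaults",
]


@dataclass(frozen=True)
class RasterSpec:
    """Recipe for the patchy offshore biomass field.

    The field is a sum of fixed-width Gaussian "reef patches" with lognormal
    amplitudes placed in an offshore strip, with per-quarter multiplicative
    amplitude jitter.  ``margin_km`` extends the raster alongshore beyond the
    coastline ends so large buffers near the ends are not artificially empty.
    """

    pixel_km: float = 0.03
    strip_min_km: float = 0.1
    strip_max_km: float = 1.5
    patches_per_km: float = 1.2
    patch_sd_km: float = 0.3
    amp_log_mean: float = np.log(30.0)
    amp_log_sd: float = 0.7
    quarter_jitter_sd: float = 0.3
    margin_km: float = 8.0

    def __post_init__(self) -> None:
        if self.pixel_km <= 0:
            raise ValueError("pixel size must be > 0")
        if self.strip_max_km <= self.strip_min_km:
            raise ValueError("offshore strip must have positive width")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic generator, including the planted truth.

    ``beta`` orders coefficients as (intercept, biomass, width, cos-orientation,
    sin-orientation, wave).  ``noise_sd`` is the innovation standard deviation
    of the ARMA(1,1) alongshore field; ``measurement_sd`` is the independent
    per-survey noise.  Setting both to zero yields a noiseless dataset.
    """

    true_radius_km: float = 2.9
    beta: tuple[float, ...] = (40.0, 1.0e-4, 0.4, -2.0, 1.0, 3.0)
    phi: float = 0.6
    theta: float = 0.2
    noise_sd: float = 8.0
    measurement_sd: float = 12.0
    n_segments: int = 250
    coastline_length_km: float = 25.0
    segment_length_km: float | None = 0.1
    n_surveys: int = 66
    start_year: int = 2015
    start_month: int = 8
    orientation_range: tuple[float, float] = (87.0, 237.0)
    width_winter_mean: float = 1.7
    width_summer_mean: float = 7.7
    width_segment_spread: float = 2.5
    width_survey_sd: float = 2.0
    width_max_m: float = 127.0
    wave_mean: float = 1.0
    wave_sd: float = 0.25
    arma_redraw_per_survey: bool = True
    curvature_amp_km: float = 0.0
    seed: int = 0
    raster: RasterSpec = field(default_factory=RasterSpec)
    # regional-design extras
    n_replicates: int = 3
    wrack_radius_km: float = 2.0
    wrack_beta: tuple[float, ...] = (0.3, 1.2e-5, 0.005, -0.05, -0.25, 0.1)
    wrack_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        ArmaParams(self.phi, self.theta)  # validates |phi| < 1, |theta| < 1
        if self.noise_sd < 0 or self.measurement_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_segments < 3:
            raise ValueError("n_segments must be >= 3")
        if self.n_surveys < 1:
            raise ValueError("n_surveys must be >= 1")
        if self.true_radius_km <= 0 or self.wrack_radius_km <= 0:
            raise ValueError("planted radii must be > 0")
        if len(self.beta) != 6 or len(self.wrack_beta) != 6:
            raise ValueError("beta must have 6 entries (intercept..wave)")

    @property
    def arma(self) -> ArmaParams:
        return ArmaParams(self.phi, self.theta)


def _coerce_overrides(overrides: dict) -> dict:
    """Allow JSON-style overrides: raster as a dict, tuples as lists."""
    o = dict(overrides)
    if isinstance(o.get("raster"), dict):
        o["raster"] = RasterSpec(**o["raster"])
    for key in ("beta", "wrack_beta", "orientation_range"):
        if key in o and not isinstance(o[key], tuple):
            o[key] = tuple(o[key])
    return o


def local_defaults(**overrides) -> SimulationConfig:
    """Local-design defaults: 250 x 100 m segments on 25 km, monthly surveys."""
    return replace(SimulationConfig(), **_coerce_overrides(overrides))


def regional_defaults(**overrides) -> SimulationConfig:
    """Regional-design defaults: 24 irregular sites over ~100 km, 3 surveys."""
    base = SimulationConfig(
        true_radius_km=5.6,
        beta=(25.0, 4.0e-5, 0.1, -2.0, 3.0, 2.0),
        phi=0.0,
        theta=0.0,
        noise_sd=0.0,
        measurement_sd=5.0,
        n_segments=24,
        coastline_length_km=100.0,
        segment_length_km=None,
        n_surveys=3,
        start_year=2017,
        start_month=10,
        orientation_range=(104.0, 241.0),
        width_winter_mean=10.0,
        width_summer_mean=22.0,
        width_segment_spread=6.0,
        width_survey_sd=2.0,
        raster=RasterSpec(patches_per_km=0.8, margin_km=8.0),
    )
    return replace(base, **_coerce_overrides(overrides))


@dataclass
class SyntheticDataset:
    """Bundle of generator outputs plus the planted truth."""

    geometry: CoastGeometry
    raster: CanopyRaster
    surveys: pd.DataFrame
    waves: pd.DataFrame
    truth: dict


def simulate_arma11(
    n: int,
    phi: float,
    theta: float,
    sd: float,
    seed: int | np.random.Generator = 0,
    burn: int = 500,
) -> np.ndarray:
    """Draw a stationary ARMA(1,1) series of length ``n``.

    ``x_t = phi x_{t-1} + eps_t + theta eps_{t-1}`` with N(0, sd^2)
    innovations; the first ``burn`` (>= 500) steps are discarded so the
    returned draw is effectively stationary, with marginal variance
    ``sd^2 (1 + 2 phi theta + theta^2) / (1 - phi^2)``.
    """
    ArmaParams(phi, theta)
    if n < 1:
        raise ValueError("n must be >= 1")
    if burn < 500:
        raise ValueError("burn-in must be >= 500 steps")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sd == 0.0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd, n + burn)
    x = lfilter([1.0, theta], [1.0, -phi], eps)
    return x[burn:]


def _survey_dates(config: SimulationConfig) -> list[date]:
    start = pd.Timestamp(config.start_year, config.start_month, 15)
    if config.n_surveys > 1 and config.segment_length_km is not None:
        freq = "MS"
        stamps = pd.date_range(start.replace(day=1), periods=config.n_surveys, freq=freq)
        return [date(t.year, t.month, 15) for t in stamps]
    # regional replicates: ~bimonthly from the start month
    stamps = pd.date_range(start.replace(day=1), periods=config.n_surveys, freq="2MS")
    return [date(t.year, t.month, 15) for t in stamps]


def quarter_label(d: date) -> str:
    return f"{d.year}Q{(d.month - 1) // 3 + 1}"


def _quarters_covering(dates: list[date]) -> list[str]:
    qs: list[str] = []
    for d in dates:
        q = quarter_label(d)
        if q not in qs:
            qs.append(q)
    return qs


def make_geometry(config: SimulationConfig, rng: np.random.Generator) -> CoastGeometry:
    """Segment/site centers along a (possibly gently curved) coastline."""
    n, length = config.n_segments, config.coastline_length_km
    if config.segment_length_km is not None:
        x = (np.arange(n) + 0.5) * config.segment_length_km
    else:
        spacing = length / n
        x = np.sort((np.arange(n) + 0.5) * spacing + rng.uniform(-0.3, 0.3, n) * spacing)
    y = (
        config.curvature_amp_km * np.sin(2.0 * np.pi * x / length)
        if config.curvature_amp_km
        else np.zeros(n)
    )
    lo, hi = config.orientation_range
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    orientation = mid + half * np.sin(2.0 * np.pi * x / length * 6.0 + 0.7)
    orientation = np.clip(
        orientation + rng.normal(0.0, 0.02 * half, n), lo, min(hi, 360.0 - 1e-9)
    )
    return CoastGeometry(
        segment_ids=np.arange(1, n + 1),
        segment_centers=np.column_stack([x, y]),
        orientation_deg=orientation,
        coastline_length_km=length,
        segment_length_km=config.segment_length_km,
    )


def make_raster(
    config: SimulationConfig, quarters: list[str], rng: np.random.Generator
) -> CanopyRaster:
    """Patchy offshore biomass field: Gaussian reef patches + quarter jitter."""
    spec = config.raster
    x_lo = -spec.margin_km
    x_hi = config.coastline_length_km + spec.margin_km
    px = np.arange(x_lo + spec.pixel_km / 2, x_hi, spec.pixel_km)
    py = np.arange(
        spec.strip_min_km + spec.pixel_km / 2, spec.strip_max_km, spec.pixel_km
    )
    gx, gy = np.meshgrid(px, py, indexing="ij")
    gx, gy = gx.ravel(), gy.ravel()

    n_patches = max(1, int(round(spec.patches_per_km * (x_hi - x_lo))))
    cx = rng.uniform(x_lo, x_hi, n_patches)
    cy = rng.uniform(spec.strip_min_km, spec.strip_max_km, n_patches)
    amp = rng.lognormal(spec.amp_log_mean, spec.amp_log_sd, n_patches)

    s2 = 2.0 * spec.patch_sd_km**2
    basis = np.empty((n_patches, len(gx)))
    for k in range(n_patches):
        basis[k] = np.exp(-((gx - cx[k]) ** 2 + (gy - cy[k]) ** 2) / s2)

    jitter = rng.lognormal(0.0, spec.quarter_jitter_sd, (len(quarters), n_patches))
    biomass = np.atleast_2d((jitter * amp) @ basis)
    return CanopyRaster(
        x_km=gx, y_km=gy, biomass=biomass, quarters=quarters, pixel_km=spec.pixel_km
    )


def biomass_at_radius(
    raster: CanopyRaster,
    geometry: CoastGeometry,
    radius_km: float,
    quarters: list[str] | None = None,
) -> np.ndarray:
    """Buffer sum of temporal-mean biomass at a single radius, per segment."""
    mean_b = temporal_mean_biomass(raster, quarters)
    grid = RadiusGrid(np.array([radius_km]))
    return aggregate_biomass(mean_b, raster, geometry, grid).values[:, 0]


def _widths(
    config: SimulationConfig,
    months: np.ndarray,
    base_offsets: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_surveys, n_segments) dry-beach widths: seasonal cycle + segment level."""
    center = 0.5 * (config.width_winter_mean + config.width_summer_mean)
    amp = 0.5 * (config.width_summer_mean - config.width_winter_mean)
    seasonal = amp * np.cos(2.0 * np.pi * (months - 8) / 12.0)  # summer (Aug) max
    w = (
        center
        + base_offsets[None, :]
        + seasonal[:, None]
        + rng.normal(0.0, config.width_survey_sd, (len(months), len(base_offsets)))
    )
    return np.clip(w, 0.0, config.width_max_m)


def _waves(config: SimulationConfig, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    hs = (
        config.wave_mean
        + 0.3 * np.sin(2.0 * np.pi * x / config.coastline_length_km * 2.0 + 1.0)
        + rng.normal(0.0, config.wave_sd, len(x))
    )
    return np.clip(hs, 0.05, None)


def _noise_field(
    config: SimulationConfig, n_surveys: int, n_segments: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_surveys, n_segments) array: ARMA(1,1) alongshore field + iid noise."""
    eta = np.zeros((n_surveys, n_segments))
    if config.noise_sd > 0:
        if config.arma_redraw_per_survey:
            for m in range(n_surveys):
                eta[m] = simulate_arma11(
                    n_segments, config.phi, config.theta, config.noise_sd, rng
                )
        else:
            eta[:] = simulate_arma11(
                n_segments, config.phi, config.theta, config.noise_sd, rng
            )[None, :]
    if config.measurement_sd > 0:
        eta += rng.normal(0.0, config.measurement_sd, (n_surveys, n_segments))
    return eta


def _design_columns(
    config: SimulationConfig,
    geometry: CoastGeometry,
    raster: CanopyRaster,
    hs: np.ndarray,
    radius_km: float,
) -> dict[str, np.ndarray]:
    rad = np.deg2rad(geometry.orientation_deg)
    return {
        "biomass": biomass_at_radius(raster, geometry, radius_km),
        "cos_orientation": np.cos(rad),
        "sin_orientation": np.sin(rad),
        "wave": hs,
    }


def simulate_local_surveys(
    config: SimulationConfig,
    geometry: CoastGeometry,
    raster: CanopyRaster,
    hs: np.ndarray,
    rng: np.random.Generator,
    biomass: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw one realization of the monthly survey table over fixed terrain.

    Splitting this from :func:`generate_local_dataset` lets replicate studies
    hold geometry/raster/waves fixed and redraw only widths and noise.
    ``biomass`` can pass a precomputed buffer sum at the true radius.
    """
    dates = _survey_dates(config)
    if biomass is None:
        biomass = biomass_at_radius(raster, geometry, config.true_radius_km)
    rad = np.deg2rad(geometry.orientation_deg)
    cols = {
        "biomass": np.asarray(biomass, dtype=float),
        "cos_orientation": np.cos(rad),
        "sin_orientation": np.sin(rad),
        "wave": hs,
    }

    months = np.array([d.month for d in dates])
    base_offsets = rng.uniform(
        -config.width_segment_spread, config.width_segment_spread, config.n_segments
    )
    widths = _widths(config, months, base_offsets, rng)
    noise = _noise_field(config, config.n_surveys, config.n_segments, rng)

    b = np.asarray(config.beta)
    rows = []
    for m, d in enumerate(dates):
        mean = (
            b[0]
            + b[1] * cols["biomass"]
            + b[2] * widths[m]
            + b[3] * cols["cos_orientation"]
            + b[4] * cols["sin_orientation"]
            + b[5] * cols["wave"]
        )
        y = np.maximum(mean + noise[m], 0.0)
        rows.append(
            pd.DataFrame(
                {
                    "segment_id": geometry.segment_ids,
                    "survey_date": d.isoformat(),
                    "plant_count": y,
                    "dry_width_m": widths[m],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_local_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Monthly segment surveys on a regularly partitioned coastline."""
    config = config or local_defaults()
    rng = np.random.default_rng(config.seed)
    geometry = make_geometry(config, rng)
    quarters = _quarters_covering(_survey_dates(config))
    raster = make_raster(config, quarters, rng)
    hs = _waves(config, geometry.alongshore_position_km, rng)
    surveys = simulate_local_surveys(config, geometry, raster, hs, rng)
    waves = pd.DataFrame(
        {"segment_id": geometry.segment_ids, "window": "all", "mean_hs_m": hs}
    )
    truth = {
        "design": "local",
        "true_radius_km": config.true_radius_km,
        "beta": list(config.beta),
        "phi": config.phi,
        "theta": config.theta,
        "noise_sd": config.noise_sd,
        "measurement_sd": config.measurement_sd,
        "seed": config.seed,
    }
    return SyntheticDataset(geometry, raster, surveys, waves, truth)


def generate_regional_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Irregularly spaced beach sites with replicate surveys and wrack cover.

    Plant counts are expressed per km of beach; wrack cover gets its own
    planted radius and coefficient set, and is recorded on the first survey
    only (it is measured once per site).
    """
    config = config or regional_defaults()
    rng = np.random.default_rng(config.seed)
    geometry = make_geometry(config, rng)
    dates = _survey_dates(replace(config, n_surveys=config.n_replicates))
    quarters = _quarters_covering(dates)
    raster = make_raster(config, quarters, rng)
    hs = _waves(config, geometry.alongshore_position_km, rng)
    cols = _design_columns(config, geometry, raster, hs, config.true_radius_km)
    wrack_biomass = biomass_at_radius(raster, geometry, config.wrack_radius_km)

    months = np.array([d.month for d in dates])
    base_offsets = rng.uniform(
        -config.width_segment_spread, config.width_segment_spread, config.n_segments
    )
    widths = _widths(config, months, base_offsets, rng)
    noise = _noise_field(config, len(dates), config.n_segments, rng)

    b = np.asarray(config.beta)
    wb = np.asarray(config.wrack_beta)
    wrack_mean = (
        wb[0]
        + wb[1] * wrack_biomass
        + wb[2] * widths[0]
        + wb[3] * cols["cos_orientation"]
        + wb[4] * cols["sin_orientation"]
        + wb[5] * cols["wave"]
    )
    wrack = np.maximum(
        wrack_mean + rng.normal(0.0, config.wrack_noise_sd, config.n_segments), 0.0
    )

    rows = []
    for m, d in enumerate(dates):
        mean = (
            b[0]
            + b[1] * cols["biomass"]
            + b[2] * widths[m]
            + b[3] * cols["cos_orientation"]
            + b[4] * cols["sin_orientation"]
            + b[5] * cols["wave"]
        )
        y = np.maximum(mean + noise[m], 0.0)
        frame = pd.DataFrame(
            {
                "segment_id": geometry.segment_ids,
                "survey_date": d.isoformat(),
                "plant_count": y,
                "dry_width_m": widths[m],
                "wrack_cover": wrack if m == 0 else np.nan,
            }
        )
        rows.append(frame)
    surveys = pd.concat(rows, ignore_index=True)
    waves = pd.DataFrame(
        {"segment_id": geometry.segment_ids, "window": "all", "mean_hs_m": hs}
    )
    truth = {
        "design": "regional",
        "true_radius_km": config.true_radius_km,
        "beta": list(config.beta),
        "wrack_radius_km": config.wrack_radius_km,
        "wrack_beta": list(config.wrack_beta),
        "phi": config.phi,
        "theta": config.theta,
        "noise_sd": config.noise_sd,
        "measurement_sd": config.measurement_sd,
        "seed": config.seed,
    }
    return SyntheticDataset(geometry, raster, surveys, waves, truth)
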
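"""End-to-end orchestration: simulate -> aggregate -> scan -> drivers,
with a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import features, io
from .drivers import CandidateSet, fit_drivers
from .geo_aggregate import RadiusGrid, aggregate_biomass, temporal_mean_biomass
from .scale_scan import scan_radii, seasonal_scan
from .synthetic_coast import (
    SimulationConfig,
    generate_local_dataset,
    generate_regional_dataset,
    local_defaults,
    regional_defaults,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    design: str = "local"
    rmin: float = 0.1
    rmax: float = 10.0
    rstep: float = 0.1
    seasons: tuple[str, ...] = ()  # () = overall only; or subset of features.SEASONS
    mode: str | None = None  # default: gls for local, ols for regional
    all_subsets: bool = False
    seed: int = 0
    out_dir: str = "wrackscale_out"
    sim_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.design not in ("local", "regional"):
            raise ValueError(f"design must be 'local' or 'regional', got {self.design!r}")
        if self.rstep <= 0:
            raise ValueError(f"rstep must be > 0, got {self.rstep}")
        if self.rmax < self.rmin or self.rmin <= 0:
            raise ValueError("need 0 < rmin <= rmax")
        for s in self.seasons:
            if s not in features.SEASONS:
                raise ValueError(f"unknown season {s!r}")
        if self.mode not in (None, "gls", "ols"):
            raise ValueError(f"mode must be gls or ols, got {self.mode!r}")

    @property
    def model_mode(self) -> str:
        return self.mode or ("gls" if self.design == "local" else "ols")

    def radius_grid(self) -> RadiusGrid:
        return RadiusGrid.from_bounds(self.rmin, self.rmax, self.rstep)

    def simulation_config(self) -> SimulationConfig:
        base = local_defaults if self.design == "local" else regional_defaults
        return base(seed=self.seed, **self.sim_overrides)

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        data.update(overrides)
        if "seasons" in data:
            data["seasons"] = tuple(data["seasons"])
        return cls(**data)


def _checksums(paths: list[Path]) -> dict[str, str]:
    return {p.name: io.sha256_of(p) for p in sorted(paths)}


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> aggregate -> scan -> drivers; write outputs + manifest.

    Returns the manifest dict.  On stage failure, partially written outputs
    are removed before the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stages: list[dict] = []
    t_start = time.time()

    def stage(name: str, **counts) -> None:
        stages.append({"stage": name, "seed": config.seed, **counts})
        logger.info("stage=%s seed=%d %s", name, config.seed, counts)

    try:
        sim = config.simulation_config()
        gen = generate_local_dataset if config.design == "local" else generate_regional_dataset
        data = gen(sim)
        written.append(io.write_segments_csv(data.geometry, out / "segments.csv"))
        written.append(io.write_survey_csv(data.surveys, out / "surveys.csv"))
        written.append(io.write_waves_csv(data.waves, out / "waves.csv"))
        written.append(io.write_raster(data.raster, out / "raster.csv"))
        written.append(io.write_json(data.truth, out / "truth.json"))
        stage(
            "simulate",
            segments=data.geometry.n_segments,
            surveys=int(data.surveys["survey_date"].nunique()),
            pixels=data.raster.n_pixels,
        )

        radii = config.radius_grid()
        mean_b = temporal_mean_biomass(data.raster)
        bbr = aggregate_biomass(mean_b, data.raster, data.geometry, radii)
        written.append(io.write_biomass_by_radius(bbr, out / "biomass_by_radius.csv"))
        stage("aggregate", radii=len(radii), segments=data.geometry.n_segments)

        mode = config.model_mode
        response = features.seasonal_mean_response(data.surveys, "all")
        scan = scan_radii(response, bbr, method=mode)
        scan.to_frame().to_csv(out / f"scan_{config.design}_all.csv", index=False)
        written.append(out / f"scan_{config.design}_all.csv")
        summaries = {"all": scan.summary()}
        season_scans = {}
        if config.seasons:
            season_scans = seasonal_scan(
                data.surveys, data.raster, data.geometry, radii, method=mode
            )
            for season, sres in season_scans.items():
                if season not in config.seasons:
                    continue
                p = out / f"scan_{config.design}_{season}.csv"
                sres.to_frame().to_csv(p, index=False)
                written.append(p)
                summaries[season] = sres.summary()
        written.append(io.write_json(summaries, out / "scan_summary.json"))
        stage("scan", models=len(radii) * (1 + len(config.seasons)))

        cand = CandidateSet.all_subsets() if config.all_subsets else CandidateSet()
        design_tbl = features.build_design_table(
            data.surveys,
            data.geometry,
            data.waves,
            bbr.column(scan.optimal_radius_km),
        )
        design_tbl.to_csv(out / f"design_{config.design}_all.csv", index=False)
        written.append(out / f"design_{config.design}_all.csv")
        dfit = fit_drivers(design_tbl, mode=mode, candidates=cand)
        coef = dfit.coef_frame()
        coef.to_csv(out / f"drivers_{config.design}_all.csv", index=False)
        written.append(out / f"drivers_{config.design}_all.csv")
        written.append(
            io.write_json(
                {
                    "selected_predictors": list(dfit.selected_predictors),
                    "aic": dfit.aic_table().to_dict(orient="records"),
                    "coefficients": dfit.selected.coef_table(),
                    "arma": {"phi": dfit.selected.arma.phi, "theta": dfit.selected.arma.theta},
                    "optimal_radius_km": scan.optimal_radius_km,
                },
                out / "drivers_summary.json",
            )
        )
        stage("drivers", candidates=len(cand.candidates), n=len(design_tbl))
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise

    manifest = {
        "config": {
            **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            }
        },
        "version": __version__,
        "stages": stages,
        "checksums": _checksums(written),
        "elapsed_s": round(time.time() - t_start, 3),
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest
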
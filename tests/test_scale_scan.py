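"""Radius scan and optimum selection."""

import numpy as np
import pandas as pd
import pytest

import wrackscale as w
from wrackscale import features
from wrackscale.geo_aggregate import BiomassByRadius, RadiusGrid, aggregate_biomass, temporal_mean_biomass
from wrackscale.scale_scan import scan_radii, seasonal_scan, select_optimum
from wrackscale.synthetic_coast import biomass_at_radius, local_defaults

from conftest import COARSE

COARSE_SCAN = __import__("wrackscale.synthetic_coast", fromlist=["RasterSpec"]).RasterSpec(pixel_km=0.08, margin_km=6.0)


def make_bbr(radii, values):
    values = np.asarray(values, dtype=float)
    return BiomassByRadius(
        segment_ids=np.arange(1, values.shape[0] + 1),
        radii_km=np.asarray(radii, dtype=float),
        values=values,
    )


class TestSelectOptimum:
    def test_tie_breaks_to_smaller_radius(self):
        j = select_optimum(np.array([1.0, 2.0, 3.0, 4.0]), np.array([1.0, 5.0, 5.0, 2.0]))
        assert j == 1  # radius 2

    def test_single_radius(self):
        assert select_optimum(np.array([3.0]), np.array([0.2])) == 0

    def test_empty_error(self):
        with pytest.raises(ValueError, match="empty"):
            select_optimum(np.array([]), np.array([]))

    def test_all_failed_error(self):
        with pytest.raises(ValueError, match="every radius"):
            select_optimum(np.array([1.0, 2.0]), np.array([np.nan, np.nan]))

    def test_nan_excluded_from_argmax(self):
        j = select_optimum(np.array([1.0, 2.0, 3.0]), np.array([np.nan, 0.5, 0.4]))
        assert j == 1


class TestScanRadii:
    def test_noiseless_planted_optimum(self, rng):
        """y built from the 2.0 km column -> optimum exactly 2.0 km."""
        n = 30
        radii = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
        vals = rng.uniform(0, 100, (n, len(radii))).cumsum(axis=1)  # monotone rows
        bbr = make_bbr(radii, vals)
        y = 2.0 + 3.0 * bbr.column(2.0)
        res = scan_radii(y, bbr, method="ols")
        assert res.optimal_radius_km == 2.0
        assert res.optimal_statistic == pytest.approx(1.0, abs=1e-10)

    def test_identical_columns_tie_to_smaller(self, rng):
        n = 25
        x = rng.uniform(0, 10, n)
        vals = np.column_stack([x, x, x + rng.uniform(0, 1, n)])
        bbr = make_bbr([1.0, 2.0, 3.0], vals)
        y = x + rng.normal(size=n)
        res = scan_radii(y, bbr, method="ols")
        assert res.statistic[0] == res.statistic[1]
        if res.optimal_statistic == res.statistic[0]:
            assert res.optimal_radius_km == 1.0

    def test_degenerate_column_skipped(self, rng):
        n = 20
        vals = np.column_stack([np.full(n, 7.0), rng.uniform(0, 5, n)])
        bbr = make_bbr([1.0, 2.0], vals)
        y = rng.normal(size=n)
        res = scan_radii(y, bbr, method="ols")
        assert np.isnan(res.statistic[0])
        assert res.optimal_radius_km == 2.0

    def test_pure_noise_not_significant_majority(self):
        master = np.random.default_rng(77)
        n = 40
        flags = []
        for _ in range(20):
            vals = np.sort(master.uniform(0, 10, (n, 4)), axis=1)
            bbr = make_bbr([1, 2, 3, 4], vals)
            y = master.normal(size=n)
            flags.append(scan_radii(y, bbr, method="ols").optimal_significant)
        # optimum of 4 noise radii is sometimes significant, but not usually
        assert sum(flags) <= 10

    def test_method_validation_and_alignment(self, rng):
        bbr = make_bbr([1.0], rng.uniform(0, 1, (10, 1)))
        with pytest.raises(ValueError, match="method"):
            scan_radii(np.ones(10), bbr, method="glm")
        with pytest.raises(ValueError, match="length"):
            scan_radii(np.ones(7), bbr)

    def test_series_alignment_drops_missing(self, rng):
        vals = rng.uniform(1, 2, (10, 2)).cumsum(axis=1)
        bbr = make_bbr([1.0, 2.0], vals)
        resp = pd.Series(
            rng.normal(size=8), index=np.arange(1, 9)
        )  # segments 9, 10 missing
        res = scan_radii(resp, bbr, method="ols")
        assert res.n == 8

    def test_gls_statistic_is_f(self, local_small):
        d = local_small
        grid = RadiusGrid(np.array([1.0, 2.0]))
        bbr = aggregate_biomass(
            temporal_mean_biomass(d.raster), d.raster, d.geometry, grid
        )
        resp = features.seasonal_mean_response(d.surveys, "all")
        res = scan_radii(resp, bbr, method="gls")
        assert res.method == "gls"
        assert np.all(res.statistic[np.isfinite(res.statistic)] >= 0)


class TestSeasonalScan:
    def test_single_season_surveys(self, rng):
        cfg = local_defaults(
            seed=6, n_segments=20, coastline_length_km=2.0, n_surveys=2,
            start_month=1, raster=COARSE,
        )
        d = w.generate_local_dataset(cfg)  # Jan+Feb surveys -> winter only
        grid = RadiusGrid(np.array([1.0, 2.0]))
        out = seasonal_scan(d.surveys, d.raster, d.geometry, grid)
        assert set(out) == {"winter"}
        assert out["winter"].season == "winter"

    def test_all_seasons_present(self, local_small):
        grid = RadiusGrid(np.array([1.0, 2.0, 3.0]))
        out = seasonal_scan(
            local_small.surveys, local_small.raster, local_small.geometry, grid
        )
        assert set(out) == set(features.SEASONS)
        for season, res in out.items():
            assert res.optimal_radius_km in grid.radii_km


class TestScanProperties:
    def test_permutation_invariance(self, rng):
        """Per-radius statistics do not depend on scan evaluation order."""
        n = 30
        vals = rng.uniform(0, 10, (n, 5)).cumsum(axis=1)
        radii = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = vals[:, 2] + rng.normal(size=n)
        full = scan_radii(y, make_bbr(radii, vals), method="ols")
        for j in range(5):
            single = scan_radii(y, make_bbr(radii[[j]], vals[:, [j]]), method="ols")
            assert single.statistic[0] == full.statistic[j]
            assert single.p_value[0] == full.p_value[j]

    def test_null_scan_alpha_and_uniform_optima(self):
        """No signal: per-radius significance ~ alpha; optima ~ uniform."""
        master = np.random.default_rng(314)
        n, n_rad, seeds = 40, 10, 200
        radii = np.arange(1.0, n_rad + 1.0)
        sig = 0
        opt_counts = np.zeros(n_rad)
        for _ in range(seeds):
            vals = master.uniform(0, 10, (n, n_rad))  # exchangeable columns
            y = master.normal(size=n)
            res = scan_radii(y, make_bbr(radii, vals), method="ols")
            sig += int(res.significant.sum())
            opt_counts[int(res.optimal_radius_km) - 1] += 1
        rate = sig / (seeds * n_rad)
        assert 0.03 <= rate <= 0.07, rate
        from scipy import stats as st

        chi = st.chisquare(opt_counts)
        assert chi.pvalue > 0.01, opt_counts

    def test_recovery_sharpens_with_more_surveys(self):
        """Median |selected - R*| at 66 surveys <= median at 12 surveys."""
        import warnings

        from wrackscale.geo_aggregate import aggregate_biomass, temporal_mean_biomass
        from wrackscale.synthetic_coast import RasterSpec

        grid = RadiusGrid.from_bounds(1.4, 4.4, 0.2)
        errs = {12: [], 66: []}
        for seed in range(8):
            for n_surveys in (12, 66):
                cfg = local_defaults(
                    seed=seed, n_surveys=n_surveys,
                    raster=RasterSpec(pixel_km=0.08, margin_km=6.0),
                )
                d = w.generate_local_dataset(cfg)
                bbr = aggregate_biomass(
                    temporal_mean_biomass(d.raster), d.raster, d.geometry, grid
                )
                resp = features.seasonal_mean_response(d.surveys, "all")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = scan_radii(resp, bbr, method="gls")
                errs[n_surveys].append(abs(res.optimal_radius_km - 2.9))
        assert np.median(errs[66]) <= np.median(errs[12]), errs

    def test_season_invariant_signal_gives_matching_optima(self):
        """Signal constant across seasons -> the four optima agree closely."""
        import warnings

        cfg = local_defaults(
            seed=21, beta=(40.0, 3.0e-4, 0.4, -2.0, 1.0, 3.0),
            noise_sd=4.0, measurement_sd=6.0, raster=COARSE_SCAN,
        )
        d = w.generate_local_dataset(cfg)
        grid = RadiusGrid.from_bounds(2.0, 3.8, 0.2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = seasonal_scan(d.surveys, d.raster, d.geometry, grid)
        opts = [res.optimal_radius_km for res in out.values()]
        assert len(opts) == 4
        assert max(opts) - min(opts) <= 0.6, opts

    def test_winter_only_signal(self):
        """Signal planted in winter months only: winter beats summer."""
        import warnings

        import pandas as pd

        from wrackscale.synthetic_coast import biomass_at_radius

        wins = 0
        seeds = 12
        grid = RadiusGrid.from_bounds(2.0, 3.8, 0.3)
        for seed in range(seeds):
            cfg = local_defaults(
                seed=seed, beta=(40.0, 0.0, 0.4, -2.0, 1.0, 3.0), raster=COARSE_SCAN
            )
            d = w.generate_local_dataset(cfg)
            B = biomass_at_radius(d.raster, d.geometry, cfg.true_radius_km)
            s = d.surveys.copy()
            months = pd.to_datetime(s["survey_date"]).dt.month
            bmap = dict(zip(d.geometry.segment_ids, 3.0e-4 * B))
            winter = months.isin([1, 2, 3])
            s.loc[winter, "plant_count"] += s.loc[winter, "segment_id"].map(bmap)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = seasonal_scan(s, d.raster, d.geometry, grid)
            if out["winter"].optimal_statistic > out["summer"].optimal_statistic:
                wins += 1
        assert wins >= 0.9 * seeds, wins
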
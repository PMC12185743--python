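# wrackscale

Scale-of-effect analysis of cross-ecosystem kelp subsidies: at what distance
does offshore kelp-canopy biomass best predict kelp deposition on beaches?

The package implements the full analysis pipeline on synthetic coastal data
with known ground truth:

- **`synthetic_coast`** — seeded generators for two survey designs: a *local*
  design (a 25 km coastline partitioned into 250 × 100 m segments, surveyed
  monthly) and a *regional* design (24 irregularly spaced beach sites over
  ~100 km with replicate surveys and an areal wrack-cover response). A known
  connectivity radius R\*, known driver coefficients, and an ARMA(1,1)
  alongshore noise field are planted in every dataset (`truth.json`).
- **`geo_aggregate`** — buffer aggregation: for every segment and candidate
  radius (default 0.1–10.0 km at 0.1 km steps), the sum of temporal-mean
  canopy biomass over all raster pixels whose center lies within the closed
  disk of that radius.
- **`features`** — seasonal segment means (winter = Jan–Mar, …), sine/cosine
  decomposition of shore-normal orientation, wave means, design tables.
- **`gls_arma`** — from-scratch generalized least squares with ARMA(1,1)
  residual correlation over the alongshore segment order: profile Gaussian
  likelihood over (φ, θ) with Cholesky whitening, t/F/AIC inference, residual
  ACF diagnostics, plus a plain OLS mode.
- **`scale_scan`** — one single-predictor model per radius; the optimum is the
  radius maximizing the overall F (GLS, local design) or r² (OLS, regional
  design); non-significant optima are reported and flagged. Seasonal variants
  re-aggregate biomass from season-matched quarters.
- **`drivers`** — multi-predictor models (biomass at the optimal radius +
  beach width + cos/sin orientation + wave height) with AIC-based candidate
  selection (default candidates: full model, full minus wave).
- **`io` / `pipeline` / `cli`** — CSV/TIFF readers and writers with schema
  validation, and an end-to-end `report` command with a checksum manifest.

## CLI

```sh
wrackscale simulate  --design local --seed 1 --out data/
wrackscale aggregate --raster data/raster.csv --segments data/segments.csv \
                     --rmin 0.1 --rmax 10.0 --rstep 0.1 --out data/bbr.csv
wrackscale scan      --surveys data/surveys.csv --biomass data/bbr.csv \
                     --method gls --out data/scan.csv
wrackscale drivers   --surveys data/surveys.csv --segments data/segments.csv \
                     --waves data/waves.csv --biomass data/bbr.csv \
                     --radius 2.9 --out data/drivers.csv
wrackscale report    --design local --seed 1 --out run/   # end-to-end + manifest
```

All stages are deterministic given `--seed`; `report` writes `manifest.json`
with a checksum per output so reruns can be verified bit-for-bit.

## Data formats

CSV (UTF-8, header row, ISO-8601 dates, coordinates in km):
`segments.csv` (segment_id, x_km, y_km, orientation_deg), `surveys.csv`
(segment_id, survey_date, plant_count, dry_width_m[, wrack_cover]),
`waves.csv` (segment_id, window, mean_hs_m), `raster.csv` (x_km, y_km,
quarter, biomass), `biomass_by_radius.csv` (segment_id, radius_km,
biomass_sum). Rasters can also round-trip through multi-page TIFF with
pixel-scale/tiepoint geo tags.
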
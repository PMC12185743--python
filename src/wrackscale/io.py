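"""File formats, validation, and the run manifest.

CSV dialect: comma-separated, UTF-8, mandatory header row, '.' decimal,
ISO-8601 dates.  Coordinates are kilometers everywhere; rasters travel either
as a long-format CSV (x_km, y_km, quarter, biomass) or as a multi-page TIFF
with minimal geo tags (pixel scale + tiepoint), one page per quarter.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CanopyRaster, CoastGeometry

__all__ = [
    "read_segments_csv",
    "write_segments_csv",
    "read_survey_csv",
    "write_survey_csv",
    "read_waves_csv",
    "write_waves_csv",
    "read_raster",
    "write_raster",
    "write_biomass_by_radius",
    "read_biomass_by_radius",
    "sha256_of",
]


class SchemaError(ValueError):
    """A file violated the documented schema; message names file/row/column."""


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------- segments

def write_segments_csv(geometry: CoastGeometry, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "segment_id": geometry.segment_ids,
            "x_km": geometry.segment_centers[:, 0],
            "y_km": geometry.segment_centers[:, 1],
            "orientation_deg": geometry.orientation_deg,
        }
    ).to_csv(path, index=False)
    return path


def read_segments_csv(
    path: str | Path,
    coastline_length_km: float | None = None,
    segment_length_km: float | None = None,
) -> CoastGeometry:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["segment_id", "x_km", "y_km", "orientation_deg"], path)
    if df["segment_id"].duplicated().any():
        row = int(df.index[df["segment_id"].duplicated()][0])
        raise SchemaError(f"{path}: duplicate segment_id at row {row}")
    length = coastline_length_km
    if length is None:
        length = float(df["x_km"].max() - df["x_km"].min())
    return CoastGeometry(
        segment_ids=df["segment_id"].to_numpy(),
        segment_centers=df[["x_km", "y_km"]].to_numpy(dtype=float),
        orientation_deg=df["orientation_deg"].to_numpy(dtype=float),
        coastline_length_km=length,
        segment_length_km=segment_length_km,
    )


# ----------------------------------------------------------------- surveys

def write_survey_csv(surveys: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    surveys.to_csv(path, index=False)
    return path


def read_survey_csv(path: str | Path) -> pd.DataFrame:
    """Load and validate a survey table (long format, one row per
    segment x survey date)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["segment_id", "survey_date", "plant_count", "dry_width_m"], path)
    try:
        parsed = pd.to_datetime(df["survey_date"], format="ISO8601")
    except ValueError as exc:
        raise SchemaError(f"{path}: survey_date not ISO-8601: {exc}") from None
    df["survey_date"] = parsed.dt.date.astype(str)
    dup = df.duplicated(subset=["segment_id", "survey_date"])
    if dup.any():
        row = int(df.index[dup][0])
        raise SchemaError(
            f"{path}: duplicate (segment_id, survey_date) at row {row}: "
            f"{df.loc[row, 'segment_id']!r}, {df.loc[row, 'survey_date']!r}"
        )
    for col in ("plant_count", "dry_width_m"):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise SchemaError(f"{path}: negative {col} at row {int(bad[0])}")
    if "wrack_cover" in df.columns:
        bad = df.index[df["wrack_cover"] < 0]
        if len(bad):
            raise SchemaError(f"{path}: negative wrack_cover at row {int(bad[0])}")
    return df


# ------------------------------------------------------------------- waves

def write_waves_csv(waves: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    waves.to_csv(path, index=False)
    return path


def read_waves_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["segment_id", "window", "mean_hs_m"], path)
    dup = df.duplicated(subset=["segment_id", "window"])
    if dup.any():
        row = int(df.index[dup][0])
        raise SchemaError(f"{path}: duplicate (segment_id, window) at row {row}")
    bad = df.index[~(df["mean_hs_m"] > 0)]
    if len(bad):
        raise SchemaError(f"{path}: non-positive mean_hs_m at row {int(bad[0])}")
    return df


# ------------------------------------------------------------------ raster

def write_raster(raster: CanopyRaster, path: str | Path) -> Path:
    """Write a raster as long CSV or multi-page TIFF, by file extension."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        frames = []
        for qi, q in enumerate(raster.quarters):
            frames.append(
                pd.DataFrame(
                    {
                        "x_km": raster.x_km,
                        "y_km": raster.y_km,
                        "quarter": q,
                        "biomass": raster.biomass[qi],
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        return path
    if path.suffix.lower() in (".tif", ".tiff"):
        _write_raster_tiff(raster, path)
        return path
    raise ValueError(f"unsupported raster format {path.suffix!r} (use .csv or .tif)")


def _grid_axes(raster: CanopyRaster) -> tuple[np.ndarray, np.ndarray]:
    xs = np.unique(np.round(raster.x_km, 9))
    ys = np.unique(np.round(raster.y_km, 9))
    if len(xs) * len(ys) != raster.n_pixels:
        raise ValueError("raster pixels do not form a full regular grid")
    return xs, ys


def _write_raster_tiff(raster: CanopyRaster, path: Path) -> None:
    import tifffile

    xs, ys = _grid_axes(raster)
    nx, ny = len(xs), len(ys)
    ix = np.searchsorted(xs, np.round(raster.x_km, 9))
    iy = np.searchsorted(ys, np.round(raster.y_km, 9))
    pages = np.zeros((raster.n_quarters, ny, nx))
    for qi in range(raster.n_quarters):
        pages[qi, (ny - 1) - iy, ix] = raster.biomass[qi]  # row 0 = northernmost
    # minimal GeoTIFF-style georeferencing: pixel scale + upper-left tiepoint
    sx = xs[1] - xs[0] if nx > 1 else raster.pixel_km
    sy = ys[1] - ys[0] if ny > 1 else raster.pixel_km
    tags = [
        (33550, "d", 3, (float(sx), float(sy), 0.0)),  # ModelPixelScale
        (33922, "d", 6, (0.0, 0.0, 0.0, float(xs[0]), float(ys[-1]), 0.0)),
    ]
    tifffile.imwrite(
        path,
        pages.astype(np.float64),
        extratags=tags,
        metadata={"quarters": list(raster.quarters), "pixel_km": raster.pixel_km},
    )


def read_raster(path: str | Path, pixel_km: float | None = None) -> CanopyRaster:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        _require_columns(df, ["x_km", "y_km", "quarter", "biomass"], path)
        bad = df.index[df["biomass"] < 0]
        if len(bad):
            raise SchemaError(f"{path}: negative biomass at row {int(bad[0])}")
        quarters = list(dict.fromkeys(df["quarter"].astype(str)))
        first = df[df["quarter"].astype(str) == quarters[0]]
        x = first["x_km"].to_numpy(dtype=float)
        y = first["y_km"].to_numpy(dtype=float)
        biomass = np.empty((len(quarters), len(x)))
        for qi, q in enumerate(quarters):
            sub = df[df["quarter"].astype(str) == q]
            if len(sub) != len(x):
                raise SchemaError(f"{path}: quarter {q!r} has a different pixel count")
            biomass[qi] = sub["biomass"].to_numpy(dtype=float)
        if pixel_km is None:
            xs = np.unique(np.round(x, 9))
            pixel_km = float(np.min(np.diff(xs))) if len(xs) > 1 else 0.03
        return CanopyRaster(x_km=x, y_km=y, biomass=biomass, quarters=quarters, pixel_km=pixel_km)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_raster_tiff(path, pixel_km)
    raise ValueError(f"unsupported raster format {path.suffix!r} (use .csv or .tif)")


def _read_raster_tiff(path: Path, pixel_km: float | None) -> CanopyRaster:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        page0 = tif.pages[0]
        scale = page0.tags[33550].value
        tiepoint = page0.tags[33922].value
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if pages.ndim == 2:
        pages = pages[None]
    nq, ny, nx = pages.shape
    sx, sy = float(scale[0]), float(scale[1])
    x0, ytop = float(tiepoint[3]), float(tiepoint[4])
    xs = x0 + sx * np.arange(nx)
    ys = ytop - sy * np.arange(ny)  # row 0 = northernmost
    quarters = list(meta.get("quarters", [f"Q{i + 1}" for i in range(nq)]))
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    biomass = pages.reshape(nq, ny * nx)
    return CanopyRaster(
        x_km=gx.ravel(),
        y_km=gy.ravel(),
        biomass=biomass,
        quarters=quarters,
        pixel_km=pixel_km or float(meta.get("pixel_km", sx)),
    )


# --------------------------------------------------------- biomass-by-radius

def write_biomass_by_radius(bbr, path: str | Path) -> Path:
    path = Path(path)
    nseg, nrad = bbr.values.shape
    df = pd.DataFrame(
        {
            "segment_id": np.repeat(bbr.segment_ids, nrad),
            "radius_km": np.tile(bbr.radii_km, nseg),
            "biomass_sum": bbr.values.ravel(),
        }
    )
    df.to_csv(path, index=False)
    return path


def read_biomass_by_radius(path: str | Path):
    from .geo_aggregate import BiomassByRadius

    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["segment_id", "radius_km", "biomass_sum"], path)
    wide = df.pivot(index="segment_id", columns="radius_km", values="biomass_sum")
    wide = wide.sort_index().sort_index(axis=1)
    return BiomassByRadius(
        segment_ids=wide.index.to_numpy(),
        radii_km=wide.columns.to_numpy(dtype=float),
        values=wide.to_numpy(dtype=float),
        provenance={"source": str(path)},
    )


# ---------------------------------------------------------------- manifest

def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
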
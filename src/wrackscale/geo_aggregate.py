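"""Buffer-based biomass aggregation: donor-side predictors for the radius scan.

For every segment center and every candidate radius, sum the temporal-mean
canopy biomass over all raster pixels whose center lies within the closed
disk of that radius (planar Euclidean distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import CanopyRaster, CoastGeometry

__all__ = ["RadiusGrid", "BiomassByRadius", "temporal_mean_biomass", "aggregate_biomass"]


@dataclass(frozen=True)
class RadiusGrid:
    """Strictly increasing candidate radii in kilometers."""

    radii_km: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.radii_km, dtype=float)
        if r.ndim != 1 or len(r) == 0:
            raise ValueError("radius grid must be a non-empty 1-d sequence")
        if np.any(r <= 0):
            raise ValueError("radii must be positive")
        if np.any(np.diff(r) <= 0):
            raise ValueError("radii must be strictly increasing")
        object.__setattr__(self, "radii_km", r)

    def __len__(self) -> int:
        return len(self.radii_km)

    @classmethod
    def default(cls) -> "RadiusGrid":
        """0.1, 0.2, ..., 10.0 km — 100 radii at 0.1 km increments."""
        return cls.from_bounds(0.1, 10.0, 0.1)

    @classmethod
    def from_bounds(cls, rmin: float, rmax: float, rstep: float) -> "RadiusGrid":
        if rstep <= 0:
            raise ValueError(f"rstep must be > 0, got {rstep}")
        if rmax < rmin:
            raise ValueError("rmax must be >= rmin")
        n = int(round((rmax - rmin) / rstep)) + 1
        return cls(np.round(rmin + rstep * np.arange(n), 9))


@dataclass
class BiomassByRadius:
    """Segments x radii matrix of buffer-summed temporal-mean biomass."""

    segment_ids: np.ndarray
    radii_km: np.ndarray
    values: np.ndarray  # shape (n_segments, n_radii), nonnegative
    provenance: dict = field(default_factory=dict)

    def column(self, radius_km: float) -> np.ndarray:
        """Biomass sums at one radius (must be on the grid)."""
        j = np.flatnonzero(np.isclose(self.radii_km, radius_km))
        if len(j) == 0:
            raise KeyError(f"radius {radius_km} km is not on the aggregation grid")
        return self.values[:, j[0]]


def temporal_mean_biomass(
    raster: CanopyRaster, quarters: list[str] | None = None
) -> np.ndarray:
    """Per-pixel arithmetic mean biomass over the selected quarters.

    ``quarters=None`` averages over all quarters in the raster.  A pixel
    carrying no biomass in some quarter simply contributes its stored value
    (zero) to the mean for that quarter.
    """
    if quarters is None:
        idx = np.arange(len(raster.quarters))
    else:
        if len(quarters) == 0:
            raise ValueError("quarter selection must be nonempty")
        missing = [q for q in quarters if q not in raster.quarters]
        if missing:
            raise ValueError(f"quarters not present in raster: {missing}")
        lookup = {q: i for i, q in enumerate(raster.quarters)}
        idx = np.array([lookup[q] for q in quarters])
    return raster.biomass[idx].mean(axis=0)


def aggregate_biomass(
    mean_biomass: np.ndarray,
    raster: CanopyRaster,
    geometry: CoastGeometry,
    radii: RadiusGrid,
) -> BiomassByRadius:
    """Sum mean biomass within every radius of every segment center.

    Inclusion rule: a pixel counts toward radius ``r`` iff the Euclidean
    distance from the segment center to the pixel *center* is ``<= r``
    (closed disk).  Rows are non-decreasing in radius by construction.

    Implementation: per segment, pixels are sorted by distance and a prefix
    sum is indexed by ``searchsorted`` — O(P log P) per segment instead of
    the O(P * R) double loop, but identical up to float summation order.
    """
    if raster.frame != geometry.frame:
        raise ValueError(
            f"coordinate frame mismatch: raster frame {raster.frame!r} vs "
            f"geometry frame {geometry.frame!r}"
        )
    b = np.asarray(mean_biomass, dtype=float)
    if b.shape != (raster.n_pixels,):
        raise ValueError("mean_biomass length does not match the raster pixel count")
    if np.any(b < 0):
        raise ValueError("biomass must be nonnegative")

    r = radii.radii_km
    out = np.empty((geometry.n_segments, len(r)))
    px, py = raster.x_km, raster.y_km
    for i, (cx, cy) in enumerate(geometry.segment_centers):
        d = np.hypot(px - cx, py - cy)
        order = np.argsort(d, kind="stable")
        csum = np.concatenate([[0.0], np.cumsum(b[order])])
        pos = np.searchsorted(d[order], r, side="right")
        out[i] = csum[pos]
    return BiomassByRadius(
        segment_ids=np.asarray(geometry.segment_ids),
        radii_km=r.copy(),
        values=out,
        provenance={
            "pixel_km": raster.pixel_km,
            "n_pixels": raster.n_pixels,
            "quarters": list(raster.quarters),
        },
    )
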
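"""Core domain containers shared across the pipeline.

Tabular data (surveys, waves, design tables) travels as pandas DataFrames
validated by the functions in :mod:`wrackscale.io`; the spatial containers
below are plain dataclasses in a planar kilometer frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CoastGeometry", "CanopyRaster"]


@dataclass
class CoastGeometry:
    """Segment (or site) centers ordered alongshore, with shore-normal bearings.

    ``segment_length_km`` is set for regularly partitioned coastlines (the
    local design) and ``None`` for irregularly spaced sites (the regional
    design); the spacing invariant is only enforced in the regular case.
    """

    segment_ids: np.ndarray  # int ids, alongshore order
    segment_centers: np.ndarray  # shape (n, 2), km
    orientation_deg: np.ndarray  # shore-normal bearing per segment, [0, 360)
    coastline_length_km: float
    segment_length_km: float | None = None
    frame: str = "planar_km"

    def __post_init__(self) -> None:
        self.segment_ids = np.asarray(self.segment_ids)
        self.segment_centers = np.asarray(self.segment_centers, dtype=float)
        self.orientation_deg = np.asarray(self.orientation_deg, dtype=float)
        n = len(self.segment_ids)
        if self.segment_centers.shape != (n, 2):
            raise ValueError("segment_centers must have shape (n_segments, 2)")
        if len(self.orientation_deg) != n:
            raise ValueError("one orientation per segment required")
        along = self.alongshore_position_km
        if np.any(np.diff(along) <= 0):
            raise ValueError("segment centers must be strictly ordered alongshore")
        if self.segment_length_km is not None and n > 1:
            spacing = np.diff(along)
            if not np.allclose(spacing, self.segment_length_km, atol=1e-9):
                raise ValueError(
                    "consecutive center spacing must equal segment_length_km"
                )
        if np.any((self.orientation_deg < 0) | (self.orientation_deg >= 360)):
            raise ValueError("orientation_deg must lie in [0, 360)")

    @property
    def n_segments(self) -> int:
        return len(self.segment_ids)

    @property
    def alongshore_position_km(self) -> np.ndarray:
        """Arc-length proxy: x coordinate (the synthetic coast runs along x)."""
        return self.segment_centers[:, 0]


@dataclass
class CanopyRaster:
    """Gridded nonnegative canopy biomass per pixel per quarter.

    Pixels are stored flat: ``x_km``/``y_km`` give pixel centers and
    ``biomass`` has shape (n_quarters, n_pixels).
    """

    x_km: np.ndarray
    y_km: np.ndarray
    biomass: np.ndarray
    quarters: list[str] = field(default_factory=list)
    pixel_km: float = 0.03
    frame: str = "planar_km"

    def __post_init__(self) -> None:
        self.x_km = np.asarray(self.x_km, dtype=float)
        self.y_km = np.asarray(self.y_km, dtype=float)
        self.biomass = np.atleast_2d(np.asarray(self.biomass, dtype=float))
        if self.pixel_km <= 0:
            raise ValueError("pixel size must be positive")
        npix = len(self.x_km)
        if len(self.y_km) != npix:
            raise ValueError("x_km and y_km must have equal length")
        if self.biomass.shape != (len(self.quarters), npix):
            raise ValueError(
                "biomass must have shape (n_quarters, n_pixels); got "
                f"{self.biomass.shape} for {len(self.quarters)} quarters, {npix} pixels"
            )
        if np.any(self.biomass < 0):
            raise ValueError("biomass must be nonnegative everywhere")

    @property
    def n_pixels(self) -> int:
        return len(self.x_km)

    @property
    def n_quarters(self) -> int:
        return len(self.quarters)
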
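"""Shared fixtures: small, fast synthetic datasets (coarse raster)."""

from __future__ import annotations

import numpy as np
import pytest

import wrackscale as w
from wrackscale.synthetic_coast import RasterSpec


COARSE = RasterSpec(pixel_km=0.1, patches_per_km=1.0, margin_km=4.0)


@pytest.fixture(scope="session")
def local_small():
    """40 segments, 12 monthly surveys, coarse raster — structural tests."""
    cfg = w.local_defaults(
        seed=42, n_segments=40, coastline_length_km=4.0, n_surveys=12, raster=COARSE
    )
    return w.generate_local_dataset(cfg)


@pytest.fixture(scope="session")
def regional_small():
    """Default regional design but with a coarse raster."""
    cfg = w.regional_defaults(seed=42, raster=RasterSpec(pixel_km=0.1, patches_per_km=0.6, margin_km=4.0))
    return w.generate_regional_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
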
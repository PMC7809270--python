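"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter

from cellstream.tracks import TrackSet


def smooth_texture(seed: int, shape=(160, 160), grain: float = 2.0) -> np.ndarray:
    """Band-limited random texture for correlation-based matching tests."""
    rng = np.random.default_rng(seed)
    return gaussian_filter(rng.standard_normal(shape), grain)


def make_trackset(points: dict, wound_axis=(1.0, 0.0)) -> TrackSet:
    """TrackSet from {track_id: [(t_h, x, y), ...]}."""
    rows = []
    for tid, pts in points.items():
        for t, x, y in pts:
            rows.append({"track_id": tid, "t_h": t, "x_um": x, "y_um": y})
    return pd.DataFrame(rows).pipe(
        lambda df: TrackSet(df, wound_axis=np.asarray(wound_axis, float))
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic open-field simulation shared across tests."""
    from cellstream.synthetic import SimConfig, simulate_cells

    cfg = SimConfig(
        arena_width_um=500.0,
        arena_height_um=500.0,
        density_per_mm2=200.0,
        speed_um_per_h=4.0,
        rot_diffusion_per_h=0.5,
        n_frames=13,
        seed=42,
    )
    return cfg, simulate_cells(cfg)
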
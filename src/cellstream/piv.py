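"""Particle image velocimetry for cell monolayers.

Consecutive frame pairs are divided into interrogation windows (default
50 µm, 50% overlap) and each window of the first frame is matched against the
second frame by normalized cross-correlation within a bounded search range.
The correlation peak gives an integer displacement, refined to subpixel
precision by a three-point parabolic fit per axis, and converted to µm/h.
A second pass at half the window size, seeded with the first-pass
displacement, recovers finer spatial structure (the classic coarse-to-fine
schedule); a single pass is available via ``passes=1``.

Windows with too little texture (below a local-std floor) or a weak
correlation peak are flagged invalid and skipped by downstream averages —
no interpolation is used, so no motion is fabricated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import match_template

from .confluency import TimeLapse

__all__ = ["VelocityField", "piv_frame_pair", "piv_sequence", "mean_speed"]


@dataclass
class VelocityField:
    """Per-frame-pair grid of 2D velocities in µm/h.

    ``grid_x_um``/``grid_y_um`` are 1D window-center coordinates; ``vx``,
    ``vy`` and ``valid`` have shape (n_pairs, ny, nx).  x runs along image
    columns, y along rows.
    """

    times_h: np.ndarray
    grid_x_um: np.ndarray
    grid_y_um: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    valid: np.ndarray
    pixel_size_um: float = 1.0

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table (t_h, x_um, y_um, vx, vy, valid)."""
        gx, gy = np.meshgrid(self.grid_x_um, self.grid_y_um)
        rows = []
        for i, t in enumerate(self.times_h):
            rows.append(
                pd.DataFrame(
                    {
                        "t_h": t,
                        "x_um": gx.ravel(),
                        "y_um": gy.ravel(),
                        "vx": self.vx[i].ravel(),
                        "vy": self.vy[i].ravel(),
                        "valid": self.valid[i].ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _parabolic_offset(cm1: float, c0: float, cp1: float) -> float:
    denom = cm1 - 2.0 * c0 + cp1
    if denom >= 0:  # not a local maximum; keep integer peak
        return 0.0
    off = 0.5 * (cm1 - cp1) / denom
    return float(np.clip(off, -1.0, 1.0))


def _match_pass(
    frameA: np.ndarray,
    frameB: np.ndarray,
    win: int,
    stride: int,
    search: int,
    offsets,
    peak_min: float,
    min_std: float,
    subpixel: bool,
):
    """One block-matching pass; ``offsets`` pre-shifts each search window."""
    H, W = frameA.shape
    y0s = np.arange(0, H - win + 1, stride)
    x0s = np.arange(0, W - win + 1, stride)
    ny, nx = len(y0s), len(x0s)
    dy = np.zeros((ny, nx))
    dx = np.zeros((ny, nx))
    valid = np.zeros((ny, nx), dtype=bool)
    for iy, y0 in enumerate(y0s):
        for ix, x0 in enumerate(x0s):
            oy, ox = (0, 0) if offsets is None else offsets[iy, ix]
            template = frameA[y0 : y0 + win, x0 : x0 + win]
            if template.std() <= min_std:
                continue
            ry0 = max(0, y0 + oy - search)
            rx0 = max(0, x0 + ox - search)
            ry1 = min(H, y0 + oy + win + search)
            rx1 = min(W, x0 + ox + win + search)
            region = frameB[ry0:ry1, rx0:rx1]
            if region.shape[0] < win or region.shape[1] < win:
                continue
            if region.std() == 0:
                continue
            corr = match_template(region, template)
            py, px = np.unravel_index(np.argmax(corr), corr.shape)
            peak = float(corr[py, px])
            if peak < peak_min:
                continue
            fy = fx = 0.0
            # a perfect match needs no refinement (and the parabola vertex
            # would be pulled off-center by texture asymmetry)
            if subpixel and peak < 1.0 - 1e-9:
                if 0 < py < corr.shape[0] - 1:
                    fy = _parabolic_offset(
                        corr[py - 1, px], corr[py, px], corr[py + 1, px]
                    )
                if 0 < px < corr.shape[1] - 1:
                    fx = _parabolic_offset(
                        corr[py, px - 1], corr[py, px], corr[py, px + 1]
                    )
            dy[iy, ix] = (ry0 + py) - y0 + fy
            dx[iy, ix] = (rx0 + px) - x0 + fx
            valid[iy, ix] = True
    centers_y = y0s + (win - 1) / 2.0
    centers_x = x0s + (win - 1) / 2.0
    return centers_y, centers_x, dy, dx, valid


def piv_frame_pair(
    frameA: np.ndarray,
    frameB: np.ndarray,
    window_um: float = 50.0,
    search_um: float = 20.0,
    pixel_size_um: float = 1.0,
    dt_min: float = 10.0,
    passes: int = 2,
    peak_min: float = 0.3,
    min_std: float = 0.0,
    subpixel: bool = True,
    time_h: float = 0.0,
) -> VelocityField:
    """Velocity field between two frames by windowed block matching.

    ``min_std`` gates windows on texture (e.g. the confluency threshold);
    windows whose correlation peak is below ``peak_min`` are invalid.
    """
    frameA = np.asarray(frameA, dtype=float)
    frameB = np.asarray(frameB, dtype=float)
    if frameA.shape != frameB.shape or frameA.ndim != 2:
        raise ValueError("frames must be two same-shape 2D images")
    if dt_min <= 0:
        raise ValueError("frame interval must be positive")
    win = int(round(window_um / pixel_size_um))
    search = max(1, int(round(search_um / pixel_size_um)))
    if win < 8:
        raise ValueError("interrogation window below 8 px; increase window_um")
    if win > min(frameA.shape):
        raise ValueError("interrogation window larger than the frame")
    if passes not in (1, 2):
        raise ValueError("passes must be 1 or 2")

    stride = max(1, win // 2)
    cy, cx, dy, dx, valid = _match_pass(
        frameA,
        frameB,
        win,
        stride,
        search,
        None,
        peak_min,
        min_std,
        subpixel and passes == 1,
    )
    if passes == 2 and win // 2 >= 8:
        win2 = win // 2
        stride2 = max(1, win2 // 2)
        # seed each fine window with the displacement of the nearest coarse node
        H, W = frameA.shape
        y0s2 = np.arange(0, H - win2 + 1, stride2)
        x0s2 = np.arange(0, W - win2 + 1, stride2)
        c2y = y0s2 + (win2 - 1) / 2.0
        c2x = x0s2 + (win2 - 1) / 2.0
        iy_near = np.array([int(np.argmin(np.abs(cy - c))) for c in c2y])
        ix_near = np.array([int(np.argmin(np.abs(cx - c))) for c in c2x])
        offsets = np.zeros((len(y0s2), len(x0s2), 2), dtype=int)
        for a, ia in enumerate(iy_near):
            for b, ib in enumerate(ix_near):
                if valid[ia, ib]:
                    offsets[a, b] = (
                        int(round(dy[ia, ib])),
                        int(round(dx[ia, ib])),
                    )
        search2 = max(3, search // 4)
        cy, cx, dy, dx, valid = _match_pass(
            frameA, frameB, win2, stride2, search2, offsets, peak_min, min_std, subpixel
        )

    scale = pixel_size_um / (dt_min / 60.0)  # px/frame -> µm/h
    return VelocityField(
        times_h=np.array([time_h]),
        grid_x_um=cx * pixel_size_um,
        grid_y_um=cy * pixel_size_um,
        vx=(dx * scale)[None],
        vy=(dy * scale)[None],
        valid=valid[None],
        pixel_size_um=pixel_size_um,
    )


def piv_sequence(movie: TimeLapse, **params) -> VelocityField:
    """Run PIV on every consecutive frame pair of a time-lapse.

    The node layout is constant across time; times are pair midpoints.
    """
    fields = []
    times = movie.times_h
    for i in range(movie.n_frames - 1):
        fields.append(
            piv_frame_pair(
                movie.frames[i],
                movie.frames[i + 1],
                pixel_size_um=movie.pixel_size_um,
                dt_min=movie.dt_min,
                time_h=float(0.5 * (times[i] + times[i + 1])),
                **params,
            )
        )
    first = fields[0]
    return VelocityField(
        times_h=np.array([f.times_h[0] for f in fields]),
        grid_x_um=first.grid_x_um,
        grid_y_um=first.grid_y_um,
        vx=np.concatenate([f.vx for f in fields]),
        vy=np.concatenate([f.vy for f in fields]),
        valid=np.concatenate([f.valid for f in fields]),
        pixel_size_um=first.pixel_size_um,
    )


def mean_speed(
    field: VelocityField,
    occupancy: np.ndarray | None = None,
    interval_h: tuple | None = None,
):
    """Spatially averaged speed per frame pair, and its time average.

    ``occupancy`` is an optional per-frame boolean mask stack (one mask per
    frame pair, image-shaped); only valid nodes whose centers fall inside the
    occupied area contribute.  Frame pairs with no valid node are flagged
    missing (NaN) and excluded from the scalar with a warning.

    Returns ``(trace, scalar)`` where trace is a DataFrame (t_h,
    mean_speed_um_per_h, n_nodes).
    """
    n_pairs = len(field.times_h)
    if occupancy is not None and len(occupancy) < n_pairs:
        raise ValueError("need one occupancy mask per frame pair")
    speed = field.speed
    node_r = None
    node_c = None
    if occupancy is not None:
        node_c = np.rint(field.grid_x_um / field.pixel_size_um).astype(int)
        node_r = np.rint(field.grid_y_um / field.pixel_size_um).astype(int)
    means = np.full(n_pairs, np.nan)
    counts = np.zeros(n_pairs, dtype=int)
    for i in range(n_pairs):
        sel = field.valid[i].copy()
        if occupancy is not None:
            mask = occupancy[i]
            rr = np.clip(node_r, 0, mask.shape[0] - 1)
            cc = np.clip(node_c, 0, mask.shape[1] - 1)
            sel &= mask[np.ix_(rr, cc)]
        counts[i] = int(sel.sum())
        if counts[i]:
            means[i] = float(speed[i][sel].mean())
    trace = pd.DataFrame(
        {"t_h": field.times_h, "mean_speed_um_per_h": means, "n_nodes": counts}
    )
    sel_t = np.ones(n_pairs, dtype=bool)
    if interval_h is not None:
        sel_t = (field.times_h >= interval_h[0]) & (field.times_h <= interval_h[1])
    usable = sel_t & np.isfinite(means)
    if np.any(sel_t & ~np.isfinite(means)):
        warnings.warn("frame pairs without valid PIV nodes excluded from average")
    if not usable.any():
        raise ValueError("no frame pair with valid PIV nodes in the interval")
    scalar = float(means[usable].mean())
    return trace, scalar
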
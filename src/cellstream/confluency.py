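"""Confluency and wound-front speed from phase-contrast time-lapse imaging.

Cell-occupied area is detected from image texture: cells carry fine
brightness fluctuations while the cell-free substrate is flat, so a global
threshold on the local standard deviation of brightness separates the two.
The confluency trace A(t) — occupied area normalised to the field of view —
turns into a wound-front speed via V = (w/2)·(dA/dt), where w is the field
width and the factor 1/2 accounts for the two fronts advancing into the gap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import uniform_filter
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, remove_small_holes

__all__ = [
    "TimeLapse",
    "ConfluencyTrace",
    "WoundSpeedResult",
    "local_std_map",
    "segment_confluency",
    "wound_front_speed",
]


@dataclass
class TimeLapse:
    """Ordered grayscale frame stack with physical calibration."""

    frames: np.ndarray            # (n_frames, H, W)
    pixel_size_um: float
    dt_min: float
    t0_offset_min: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("need a (n_frames, H, W) stack with ≥2 frames")
        if self.pixel_size_um <= 0 or self.dt_min <= 0:
            raise ValueError("pixel_size_um and dt_min must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_h(self) -> np.ndarray:
        return (self.t0_offset_min + np.arange(self.n_frames) * self.dt_min) / 60.0

    @property
    def field_width_um(self) -> float:
        return self.frames.shape[2] * self.pixel_size_um

    def save(self, path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.frames)
        meta = {
            "pixel_size_um": self.pixel_size_um,
            "dt_min": self.dt_min,
            "t0_offset_min": self.t0_offset_min,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "TimeLapse":
        """Read a TIFF stack plus its JSON sidecar (pixel size, frame interval)."""
        path = Path(path)
        frames = tifffile.imread(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(frames=frames, **meta)


@dataclass
class ConfluencyTrace:
    """Occupied-area fraction per frame."""

    t_h: np.ndarray
    A: np.ndarray
    masks: np.ndarray | None = None   # optional (n_frames, H, W) booleans
    threshold: float = float("nan")

    def __post_init__(self) -> None:
        self.t_h = np.asarray(self.t_h, float)
        self.A = np.asarray(self.A, float)
        if len(self.t_h) != len(self.A):
            raise ValueError("t_h and A lengths differ")
        if np.any((self.A < 0) | (self.A > 1)):
            raise ValueError("confluency must lie in [0, 1]")

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_h": self.t_h, "A": self.A}).to_csv(path, index=False)


@dataclass
class WoundSpeedResult:
    V_um_per_h: float
    dA_dt_per_h: float
    w_um: float
    fit_interval_h: tuple
    r_squared: float
    n_points: int = 0

    def to_dict(self) -> dict:
        return {
            "V_um_per_h": self.V_um_per_h,
            "dA_dt_per_h": self.dA_dt_per_h,
            "w_um": self.w_um,
            "fit_interval_h": list(self.fit_interval_h),
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


def local_std_map(frame: np.ndarray, radius_px: int = 5) -> np.ndarray:
    """Local standard deviation of brightness in a (2r+1)² neighborhood.

    Edges use reflected padding.  Computed as sqrt(E[x²] − E[x]²) with
    box-filter means, clipped at zero against round-off.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be ≥ 1")
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    size = 2 * radius_px + 1
    if frame.shape[0] < size or frame.shape[1] < size:
        raise ValueError("frame smaller than the smoothing window")
    mean = uniform_filter(frame, size=size, mode="reflect")
    mean_sq = uniform_filter(frame * frame, size=size, mode="reflect")
    var = np.clip(mean_sq - mean * mean, 0.0, None)
    return np.sqrt(var)


def _occupancy_mask(
    std_map: np.ndarray, threshold: float, cleanup: bool
) -> np.ndarray:
    mask = std_map > threshold
    if cleanup:
        mask = closing(mask, disk(2))
        mask = remove_small_holes(mask, max_size=64)
    return mask


def segment_confluency(
    movie: TimeLapse,
    radius_px: int = 5,
    cleanup: bool = True,
    keep_masks: bool = False,
    min_contrast: float = 2.0,
) -> ConfluencyTrace:
    """Texture-threshold every frame into occupied/free and report A(t).

    A single global threshold — Otsu's criterion on the first frame's local
    standard deviation map — is held fixed for the whole sequence so that
    dA/dt is not contaminated by threshold drift.  Isolated speckle is
    suppressed by morphological closing and hole filling (switchable off).

    The first frame must contain genuinely bimodal texture: the mean
    local-std above the Otsu threshold must exceed ``min_contrast`` times
    the mean below it, otherwise the frame is all background (or all cells
    and noise-free gaps are absent) and the global threshold would be
    splitting noise.
    """
    first = local_std_map(movie.frames[0], radius_px)
    if float(np.ptp(first)) < 1e-9:
        raise ValueError(
            "first frame has uniform texture; cannot choose a global Otsu "
            "threshold on its local-std map"
        )
    # Otsu on the log of the std map: texture amplitudes are long-tailed and
    # a linear Otsu drifts into the textured mode, eroding the occupied area
    threshold = float(np.exp(threshold_otsu(np.log(first + 1e-6))) - 1e-6)
    hi = first[first > threshold]
    lo = first[first <= threshold]
    if hi.size == 0 or lo.size == 0 or hi.mean() < min_contrast * max(
        lo.mean(), 1e-12
    ):
        raise ValueError(
            "no bimodal texture in the first frame: Otsu threshold on the "
            "local-std map does not separate textured cells from background "
            f"(contrast < {min_contrast}×)"
        )
    A = np.empty(movie.n_frames)
    masks = np.empty(movie.frames.shape, dtype=bool) if keep_masks else None
    for i in range(movie.n_frames):
        std_map = first if i == 0 else local_std_map(movie.frames[i], radius_px)
        mask = _occupancy_mask(std_map, threshold, cleanup)
        A[i] = mask.mean()
        if keep_masks:
            masks[i] = mask
    return ConfluencyTrace(t_h=movie.times_h, A=A, masks=masks, threshold=threshold)


def wound_front_speed(
    trace: ConfluencyTrace,
    w_um: float,
    fit_interval_h: tuple = (1.0, 15.0),
) -> WoundSpeedResult:
    """Wound-front speed V = (w/2)·(dA/dt) from a least-squares fit of A(t).

    dA/dt is the OLS slope of confluency against time over the fit interval
    (interval-average front speed; frame-to-frame differencing would be noise
    dominated).  A closing wound has rising A, hence V > 0.
    """
    if w_um <= 0:
        raise ValueError("field width must be positive")
    t0, t1 = fit_interval_h
    if t0 >= t1:
        raise ValueError("empty fit interval")
    if t0 > trace.t_h[-1] or t1 < trace.t_h[0]:
        raise ValueError(
            f"fit interval {fit_interval_h} outside trace span "
            f"[{trace.t_h[0]}, {trace.t_h[-1]}] h"
        )
    sel = (trace.t_h >= t0) & (trace.t_h <= t1)
    if int(sel.sum()) < 3:
        raise ValueError("need ≥3 confluency samples inside the fit interval")
    t = trace.t_h[sel]
    a = trace.A[sel]
    if np.ptp(a) == 0.0:
        warnings.warn("constant confluency in fit interval; V = 0")
        slope, r2 = 0.0, 1.0
    else:
        slope, intercept = np.polyfit(t, a, 1)
        resid = a - (slope * t + intercept)
        ss_tot = float(np.sum((a - a.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return WoundSpeedResult(
        V_um_per_h=float(w_um / 2.0 * slope),
        dA_dt_per_h=float(slope),
        w_um=float(w_um),
        fit_interval_h=(float(t0), float(t1)),
        r_squared=r2,
        n_points=int(sel.sum()),
    )
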
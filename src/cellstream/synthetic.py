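"""Ground-truthed synthetic data for every stage of the pipeline.

Three generators emulate the raw material of a collective-migration study:

* :func:`simulate_cells` — overdamped self-propelled particles with
  Vicsek-style neighbor alignment, rotational noise, soft-core repulsion and
  an optional wound-directed bias.  This is the minimal motion model with a
  tunable velocity correlation length (alignment strength) and tunable
  guidance efficiency (wound bias), so every trajectory statistic downstream
  can be tested by parameter recovery.
* :func:`render_timelapse` — draws each cell as a cell-fixed speckle blob
  over a uniform background with additive noise, producing phase-contrast-like
  texture that confluency thresholding and PIV block matching can work on.
* :func:`render_nuclei` — fields of non-overlapping bright ellipses whose
  orientations follow a von Mises distribution on the doubled angle, with the
  concentration chosen so the expected nematic order matches a target.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, shift as nd_shift
from scipy.optimize import brentq
from scipy.special import ive
from skimage.draw import ellipse as draw_ellipse

from .confluency import TimeLapse
from .nematic import order_parameter as nematic_order
from .tracks import TRACK_COLUMNS, TrackSet

__all__ = [
    "SimConfig",
    "ImagingConfig",
    "NucleiFieldConfig",
    "simulate_cells",
    "render_timelapse",
    "render_nuclei",
    "kappa_for_order",
    "nematic_order",
]


@dataclass
class SimConfig:
    """Self-propelled-particle simulation parameters.

    Defaults mirror the study conditions the generator stands in for:
    10-min frame cadence, cell speeds of a few µm/h, and plating densities
    given per mm².  ``wound_bias`` ∈ [0, 1] mixes the persistent heading with
    a deterministic pull along the wound axis (+x, or toward the gap center
    when a gap is present); 0 is free migration, 1 is perfectly guided.
    """

    arena_width_um: float = 1000.0
    arena_height_um: float = 1000.0
    density_per_mm2: float = 300.0
    speed_um_per_h: float = 4.0
    rot_diffusion_per_h: float = 0.5
    align_strength: float = 0.0
    align_radius_um: float = 100.0
    wound_bias: float = 0.0
    gap_width_um: float = 0.0
    dt_min: float = 10.0
    n_frames: int = 30
    seed: int = 0
    cell_radius_um: float = 10.0   # soft-core repulsion range = 1 diameter

    def __post_init__(self) -> None:
        for name in (
            "arena_width_um",
            "arena_height_um",
            "density_per_mm2",
            "speed_um_per_h",
            "rot_diffusion_per_h",
            "align_strength",
            "align_radius_um",
            "wound_bias",
            "gap_width_um",
            "dt_min",
        ):
            value = float(getattr(self, name))
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite")
        if self.density_per_mm2 <= 0:
            raise ValueError("density_per_mm2 must be positive")
        if not 0.0 <= self.wound_bias <= 1.0:
            raise ValueError("wound_bias must lie in [0, 1]")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.gap_width_um >= self.arena_width_um:
            raise ValueError("gap wider than the arena")

    @property
    def n_cells(self) -> int:
        area_mm2 = self.arena_width_um * self.arena_height_um / 1e6
        return int(round(self.density_per_mm2 * area_mm2))


@dataclass
class ImagingConfig:
    """Rendering parameters for phase-contrast-like frames (8-bit gray)."""

    pixel_size_um: float = 1.0
    background_level: float = 20.0
    cell_contrast: float = 40.0
    noise_sd: float = 2.0
    cell_radius_um: float = 12.0
    texture_grain_px: float = 2.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")


def _bias_direction(x: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Unit bias vectors: +x without a gap, toward the gap center with one."""
    b = np.zeros((len(x), 2))
    if cfg.gap_width_um > 0:
        center = cfg.arena_width_um / 2.0
        b[:, 0] = np.where(x <= center, 1.0, -1.0)
    else:
        b[:, 0] = 1.0
    return b


def _soft_core_repulsion(pos: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Linear soft-core repulsion velocity within one cell diameter."""
    d0 = 2.0 * cfg.cell_radius_um
    dx = pos[:, 0][:, None] - pos[:, 0][None, :]
    dy = pos[:, 1][:, None] - pos[:, 1][None, :]
    H = cfg.arena_height_um
    dy = (dy + H / 2.0) % H - H / 2.0  # minimum image in the periodic axis
    dist = np.hypot(dx, dy)
    np.fill_diagonal(dist, np.inf)
    overlap = dist < d0
    if not overlap.any():
        return np.zeros_like(pos)
    with np.errstate(invalid="ignore", divide="ignore"):
        mag = np.where(overlap, (1.0 - dist / d0) / np.maximum(dist, 1e-9), 0.0)
    force = np.empty_like(pos)
    force[:, 0] = (mag * dx).sum(axis=1)
    force[:, 1] = (mag * dy).sum(axis=1)
    return cfg.speed_um_per_h * force


def simulate_cells(config: SimConfig) -> TrackSet:
    """Simulate one trajectory per cell over ``n_frames`` frames.

    Per step the persistent heading turns toward the mean heading of
    neighbors within ``align_radius_um`` (weight ``align_strength``) and
    accumulates rotational noise of intensity ``rot_diffusion_per_h``; the
    movement direction mixes that heading with the wound bias; positions
    advance at ``speed_um_per_h`` plus soft-core repulsion.  Boundaries are
    periodic in y and reflecting in x, so density is conserved while the
    wound axis stays well defined.  When ``gap_width_um`` > 0 a cell-free
    strip is left at the arena center at t = 0.
    """
    n = config.n_cells
    if n < 1:
        raise ValueError("density too low for the arena: zero cells")
    rng = np.random.default_rng(config.seed)
    W, H = config.arena_width_um, config.arena_height_um
    if config.gap_width_um > 0:
        half = config.gap_width_um / 2.0
        center = W / 2.0
        free = W - config.gap_width_um
        u = rng.uniform(0.0, free, size=n)
        x = np.where(u < center - half, u, u + config.gap_width_um)
    else:
        x = rng.uniform(0.0, W, size=n)
    y = rng.uniform(0.0, H, size=n)
    pos = np.column_stack([x, y])
    theta = rng.uniform(-np.pi, np.pi, size=n)

    dt_h = config.dt_min / 60.0
    noise_scale = math.sqrt(2.0 * config.rot_diffusion_per_h * dt_h)
    history = np.empty((config.n_frames, n, 2))
    history[0] = pos
    for step in range(1, config.n_frames):
        heading = np.column_stack([np.cos(theta), np.sin(theta)])
        if config.align_strength > 0:
            dx = pos[:, 0][:, None] - pos[:, 0][None, :]
            dy = pos[:, 1][:, None] - pos[:, 1][None, :]
            dy = (dy + H / 2.0) % H - H / 2.0
            nbr = np.hypot(dx, dy) <= config.align_radius_um  # includes self
            mean_head = nbr.astype(float) @ heading / nbr.sum(axis=1)[:, None]
            desired = heading + config.align_strength * mean_head
        else:
            desired = heading
        theta = np.arctan2(desired[:, 1], desired[:, 0])
        theta = theta + noise_scale * rng.standard_normal(n)
        heading = np.column_stack([np.cos(theta), np.sin(theta)])

        wb = config.wound_bias
        move = (1.0 - wb) * heading + wb * _bias_direction(pos[:, 0], config)
        norms = np.linalg.norm(move, axis=1)
        degenerate = norms < 1e-12
        move[degenerate] = heading[degenerate]
        norms[degenerate] = 1.0
        move /= norms[:, None]

        vel = config.speed_um_per_h * move + _soft_core_repulsion(pos, config)
        pos = pos + vel * dt_h
        # reflecting in x (position and heading, billiard-style), periodic in y
        out = (pos[:, 0] < 0) | (pos[:, 0] > W)
        theta = np.where(out, np.pi - theta, theta)
        pos[:, 0] = np.abs(pos[:, 0])
        pos[:, 0] = W - np.abs(W - pos[:, 0])
        pos[:, 1] %= H
        history[step] = pos

    t_h = np.arange(config.n_frames) * dt_h
    frames_idx = np.repeat(np.arange(config.n_frames), n)
    data = pd.DataFrame(
        {
            "track_id": np.tile(np.arange(n), config.n_frames),
            "t_h": t_h[frames_idx],
            "x_um": history.reshape(-1, 2)[:, 0],
            "y_um": history.reshape(-1, 2)[:, 1],
        }
    )
    axis = np.array([1.0, 0.0])
    return TrackSet(data=data[TRACK_COLUMNS], wound_axis=axis)


def _speckle_patch(rng: np.random.Generator, radius_px: int, cfg: ImagingConfig):
    """Cell-fixed texture: smoothed noise under a soft radial window."""
    P = 2 * radius_px + 3
    noise = rng.standard_normal((P, P))
    if cfg.texture_grain_px > 0:
        noise = gaussian_filter(noise, cfg.texture_grain_px, mode="wrap")
    sd = noise.std()
    if sd > 0:
        noise /= sd
    yy, xx = np.mgrid[0:P, 0:P] - (P - 1) / 2.0
    r2 = (yy**2 + xx**2) / radius_px**2
    window = np.clip(1.0 - r2**3, 0.0, 1.0)  # flat core, soft rim
    texture = cfg.cell_contrast * np.clip(0.5 + 0.3 * noise, 0.0, None)
    return texture * window


def render_timelapse(
    tracks: TrackSet,
    imaging: ImagingConfig | None = None,
    field_origin_um: tuple = (0.0, 0.0),
    field_size_um: tuple | None = None,
    seed: int = 0,
) -> TimeLapse:
    """Render a trajectory set into a textured grayscale time-lapse.

    Every cell carries a fixed speckle pattern that translates (with
    subpixel bilinear interpolation) along its trajectory, so image texture
    moves exactly as the ground-truth tracks do.  ``field_origin_um`` /
    ``field_size_um`` select the imaged window within the arena, defaulting
    to the bounding box of the tracks.
    """
    if imaging is None:
        imaging = ImagingConfig()
    px = imaging.pixel_size_um
    radius_px = int(round(imaging.cell_radius_um / px))
    if radius_px < 2:
        raise ValueError("cell radius below 2 px; decrease pixel size")
    df = tracks.data
    times = np.unique(df["t_h"].to_numpy(float))
    if field_size_um is None:
        if df.empty:
            raise ValueError("cannot infer field size from an empty track set")
        field_size_um = (
            float(df["x_um"].max()) - field_origin_um[0],
            float(df["y_um"].max()) - field_origin_um[1],
        )
    Wpx = int(round(field_size_um[0] / px))
    Hpx = int(round(field_size_um[1] / px))
    if Wpx < 2 * radius_px + 3 or Hpx < 2 * radius_px + 3:
        raise ValueError("imaged field smaller than one cell blob")

    rng = np.random.default_rng(seed)
    ids = tracks.track_ids
    patches = {tid: _speckle_patch(rng, radius_px, imaging) for tid in ids}
    P = 2 * radius_px + 3
    half = (P - 1) // 2

    by_time = {t: g for t, g in df.groupby("t_h", sort=True)}
    frames = np.empty((len(times), Hpx, Wpx), dtype=np.uint8)
    for i, t in enumerate(times):
        canvas = np.zeros((Hpx, Wpx))
        g = by_time[t]
        cx = (g["x_um"].to_numpy(float) - field_origin_um[0]) / px
        cy = (g["y_um"].to_numpy(float) - field_origin_um[1]) / px
        for tid, xc, yc in zip(g["track_id"], cx, cy):
            bx, by_ = int(np.floor(xc)), int(np.floor(yc))
            fx, fy = xc - bx, yc - by_
            patch = patches[tid]
            if fx or fy:
                patch = nd_shift(patch, (fy, fx), order=1, mode="constant")
            r0, c0 = by_ - half, bx - half
            rr0, cc0 = max(r0, 0), max(c0, 0)
            rr1, cc1 = min(r0 + P, Hpx), min(c0 + P, Wpx)
            if rr1 <= rr0 or cc1 <= cc0:
                continue
            canvas[rr0:rr1, cc0:cc1] += patch[
                rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0
            ]
        canvas += imaging.background_level
        if imaging.noise_sd > 0:
            canvas += imaging.noise_sd * rng.standard_normal(canvas.shape)
        frames[i] = np.clip(canvas, 0, 255).astype(np.uint8)

    if len(times) >= 2:
        dt_min = float(np.diff(times).mean() * 60.0)
    else:
        dt_min = 10.0
    return TimeLapse(
        frames=frames,
        pixel_size_um=px,
        dt_min=dt_min,
        t0_offset_min=float(times[0] * 60.0),
    )


def kappa_for_order(S_target: float) -> float:
    """Von Mises concentration κ whose mean resultant length equals S.

    The expected resultant length of angles 2θ drawn from VM(µ, κ) is the
    modified Bessel ratio R(κ) = I₁(κ)/I₀(κ), strictly increasing in κ;
    this inverts it numerically.
    """
    if not 0.0 <= S_target < 1.0:
        raise ValueError("order target must lie in [0, 1); S = 1 needs κ = ∞")
    if S_target == 0.0:
        return 0.0

    def resultant(kappa: float) -> float:
        return float(ive(1, kappa) / ive(0, kappa))

    hi = 1.0
    while resultant(hi) < S_target:
        hi *= 2.0
        if hi > 1e8:
            raise RuntimeError("failed to bracket κ")
    return float(brentq(lambda k: resultant(k) - S_target, 0.0, hi, xtol=1e-12))




@dataclass
class NucleiFieldConfig:
    """Synthetic nuclei-field parameters.

    Orientations θ are drawn so the doubled angles 2θ follow a von Mises
    distribution whose concentration reproduces ``order_target`` in
    expectation; ``order_target=1`` makes every nucleus exactly parallel to
    ``mean_direction_deg``.  Nuclei are placed by rejection sampling with
    non-overlap enforced through bounding circles.
    """

    n_nuclei: int = 400
    order_target: float = 0.5
    mean_direction_deg: float = 0.0
    axis_ratio: float = 0.5         # minor/major
    region_polygons: dict = field(default_factory=dict)
    seed: int = 0
    width_um: float = 700.0
    height_um: float = 700.0
    pixel_size_um: float = 1.0
    major_axis_um: float = 16.0
    background_level: float = 10.0
    nucleus_level: float = 200.0
    noise_sd: float = 2.0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.order_target <= 1.0:
            raise ValueError("order_target must lie in [0, 1]")
        if not 0.0 < self.axis_ratio < 1.0:
            raise ValueError("axis_ratio must lie in (0, 1)")
        if self.n_nuclei < 1:
            raise ValueError("need at least one nucleus")


def render_nuclei(config: NucleiFieldConfig):
    """Render a nuclei field and return ``(image, ground_truth)``.

    The ground truth table has one row per nucleus (x_um, y_um, theta_deg,
    major_um, minor_um).  Placement is uniform over the field (or over the
    union of ``region_polygons`` when given), rejecting positions whose
    bounding circles would overlap an existing nucleus; after
    ``max_retries`` failures per nucleus an error is raised.
    """
    rng = np.random.default_rng(config.seed)
    major = config.major_axis_um
    minor = config.axis_ratio * major
    margin = 3.0
    min_dist = major + margin

    polygons = None
    if config.region_polygons:
        from shapely.geometry import Point, Polygon

        polygons = [Polygon(p) for p in config.region_polygons.values()]

    border = major / 2.0 + 1.0
    centers = np.empty((config.n_nuclei, 2))
    for i in range(config.n_nuclei):
        for _ in range(config.max_retries):
            cx = rng.uniform(border, config.width_um - border)
            cy = rng.uniform(border, config.height_um - border)
            if polygons is not None and not any(
                poly.contains(Point(cx, cy)) for poly in polygons
            ):
                continue
            if i and np.min(np.hypot(*(centers[:i] - (cx, cy)).T)) < min_dist:
                continue
            centers[i] = (cx, cy)
            break
        else:
            raise RuntimeError(
                f"could not place nucleus {i + 1}/{config.n_nuclei} without "
                f"overlap after {config.max_retries} retries"
            )

    if config.order_target >= 1.0:
        theta_deg = np.full(config.n_nuclei, config.mean_direction_deg % 180.0)
    else:
        kappa = kappa_for_order(config.order_target)
        if kappa == 0.0:
            theta_deg = rng.uniform(0.0, 180.0, size=config.n_nuclei)
        else:
            two_theta = rng.vonmises(0.0, kappa, size=config.n_nuclei)
            theta_deg = (config.mean_direction_deg + np.rad2deg(two_theta) / 2.0) % 180.0

    px = config.pixel_size_um
    Hpx = int(round(config.height_um / px))
    Wpx = int(round(config.width_um / px))
    image = np.full((Hpx, Wpx), float(config.background_level))
    for (cx, cy), th in zip(centers, theta_deg):
        # negated rotation makes draw_ellipse agree with the moment-analysis
        # convention used downstream (θ CCW from +x with y along rows)
        rr, cc = draw_ellipse(
            cy / px,
            cx / px,
            (minor / 2.0) / px,
            (major / 2.0) / px,
            shape=image.shape,
            rotation=np.deg2rad(-th),
        )
        image[rr, cc] = config.nucleus_level
    if config.noise_sd > 0:
        image += config.noise_sd * rng.standard_normal(image.shape)
    image = np.clip(image, 0, 255).astype(np.uint8)

    truth = pd.DataFrame(
        {
            "x_um": centers[:, 0],
            "y_um": centers[:, 1],
            "theta_deg": theta_deg,
            "major_um": major,
            "minor_um": minor,
        }
    )
    return image, truth
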
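"""Co-movement flow fields and velocity correlation lengths.

Collective motion is quantified by the average flow field U(x) around moving
cells: a reference frame is aligned with each sufficiently fast velocity
vector ("front" = its direction of motion, "left" = the 90° CCW normal), all
same-frame neighbor velocities are rotated into that frame, and their relative
positions are accumulated into Cartesian bins.  Averaging random vectors
cancels to zero, so a nonzero mean U flags spatially correlated motion.

Profiles of the co-moving (front) speed along the front–rear and left–right
axes are fitted with U(x) = a·exp(−x/x0) + U0; the fitted x0 is the
correlation length — the distance over which velocity–velocity correlations
decay.  Parallel and perpendicular correlation lengths come from the
front–rear and left–right profiles respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .piv import VelocityField
from .tracks import TrackSet

__all__ = [
    "CoMovementMap",
    "CorrelationFit",
    "frame_velocities",
    "comovement_map",
    "axis_profiles",
    "fit_correlation_length",
    "correlation_lengths",
]


@dataclass
class CoMovementMap:
    """Binned average neighbor velocities in the cell-aligned frame.

    ``U_front``/``U_left`` are per-bin mean velocity components (µm/h);
    empty bins hold NaN and a zero count — they are flagged, never averaged
    as zeros.  The grid is symmetric about the reference cell at the origin.
    """

    bin_centers_um: np.ndarray      # 1D, shared by both axes
    U_front: np.ndarray             # (n_bins, n_bins), row = front axis
    U_left: np.ndarray
    n_samples: np.ndarray
    bin_um: float
    moving_min_um_per_h: float

    @property
    def front_coords(self) -> np.ndarray:
        return self.bin_centers_um

    def to_dataframe(self) -> pd.DataFrame:
        f, l = np.meshgrid(self.bin_centers_um, self.bin_centers_um, indexing="ij")
        return pd.DataFrame(
            {
                "front_um": f.ravel(),
                "left_um": l.ravel(),
                "U_front": self.U_front.ravel(),
                "U_left": self.U_left.ravel(),
                "n": self.n_samples.ravel(),
            }
        )


@dataclass
class CorrelationFit:
    a: float
    x0_um: float
    U0: float
    rss: float
    converged: bool
    resid_sd: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "x0_um": self.x0_um,
            "U0": self.U0,
            "rss": self.rss,
            "converged": self.converged,
            "resid_sd": self.resid_sd,
        }


def frame_velocities(source) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-frame ``(positions, velocities)`` samples from tracks or PIV.

    Track velocities are forward finite differences assigned to the earlier
    position; PIV fields contribute their valid nodes per frame pair.
    """
    if isinstance(source, TrackSet):
        by_time: dict[float, tuple[list, list]] = {}
        for tid in source.track_ids:
            t, xy = source.track(tid)
            if len(t) < 2:
                continue
            vel = np.diff(xy, axis=0) / np.diff(t)[:, None]
            for k in range(len(t) - 1):
                key = round(float(t[k]), 9)
                pos_list, vel_list = by_time.setdefault(key, ([], []))
                pos_list.append(xy[k])
                vel_list.append(vel[k])
        return [
            (np.asarray(p, float), np.asarray(v, float))
            for _, (p, v) in sorted(by_time.items())
        ]
    if isinstance(source, VelocityField):
        gx, gy = np.meshgrid(source.grid_x_um, source.grid_y_um)
        pos_all = np.column_stack([gx.ravel(), gy.ravel()])
        out = []
        for i in range(len(source.times_h)):
            sel = source.valid[i].ravel()
            vel = np.column_stack([source.vx[i].ravel(), source.vy[i].ravel()])
            out.append((pos_all[sel], vel[sel]))
        return out
    raise TypeError("source must be a TrackSet or VelocityField")


def comovement_map(
    source,
    moving_min_um_per_h: float | None = None,
    bin_um: float = 25.0,
    extent_um: float = 500.0,
    subtract_frame_mean: bool = False,
) -> CoMovementMap:
    """Average flow field around moving reference cells.

    Every velocity vector faster than ``moving_min_um_per_h`` (default: the
    25th percentile of the speed distribution of the recording) serves as a
    reference; all other same-frame vectors are rotated into its aligned
    frame and binned by relative position.  Self-pairs are excluded; each
    ordered pair is counted once per reference, so the map is symmetric by
    construction.

    ``subtract_frame_mean`` removes the per-frame mean velocity before
    binning.  In small fields with few cells the random net flow (rigid
    drift) of a frame shows up as a spurious distance-independent
    correlation; subtracting it isolates the relative co-movement.  The
    reference/moving selection still uses the raw speeds.
    """
    frames = frame_velocities(source)
    if not frames:
        raise ValueError("no velocity samples")
    if moving_min_um_per_h is None:
        speeds = np.concatenate(
            [np.linalg.norm(v, axis=1) for _, v in frames if len(v)]
        )
        moving_min_um_per_h = float(np.percentile(speeds, 25.0))

    n_bins = 2 * int(np.ceil(extent_um / bin_um))
    edges = (np.arange(n_bins + 1) - n_bins / 2) * bin_um
    centers = 0.5 * (edges[:-1] + edges[1:])
    sum_front = np.zeros((n_bins, n_bins))
    sum_left = np.zeros((n_bins, n_bins))
    counts = np.zeros((n_bins, n_bins), dtype=np.int64)

    n_refs = 0
    for pos, vel in frames:
        n = len(pos)
        speed = np.linalg.norm(vel, axis=1)
        refs = np.flatnonzero(speed > moving_min_um_per_h)
        if refs.size == 0:
            continue
        n_refs += refs.size
        if n < 2:
            continue  # a lone reference has no neighbors to register
        raw_vel = vel
        if subtract_frame_mean:
            vel = vel - vel.mean(axis=0)
        c = raw_vel[refs, 0] / speed[refs]
        s = raw_vel[refs, 1] / speed[refs]
        rel = pos[None, :, :] - pos[refs, None, :]          # (R, N, 2)
        # rotate by -phi: front = c*dx + s*dy, left = -s*dx + c*dy
        front = c[:, None] * rel[:, :, 0] + s[:, None] * rel[:, :, 1]
        left = -s[:, None] * rel[:, :, 0] + c[:, None] * rel[:, :, 1]
        v_front = c[:, None] * vel[None, :, 0] + s[:, None] * vel[None, :, 1]
        v_left = -s[:, None] * vel[None, :, 0] + c[:, None] * vel[None, :, 1]
        keep = (
            (np.abs(front) < extent_um)
            & (np.abs(left) < extent_um)
        )
        keep[np.arange(refs.size), refs] = False            # self-pairs out
        fi = np.floor((front[keep] + extent_um) / bin_um).astype(int)
        li = np.floor((left[keep] + extent_um) / bin_um).astype(int)
        flat = fi * n_bins + li
        np.add.at(counts.ravel(), flat, 1)
        np.add.at(sum_front.ravel(), flat, np.broadcast_to(v_front, keep.shape)[keep])
        np.add.at(sum_left.ravel(), flat, np.broadcast_to(v_left, keep.shape)[keep])

    if n_refs == 0:
        raise ValueError(
            f"no reference vector moves faster than {moving_min_um_per_h} µm/h"
        )
    with np.errstate(invalid="ignore"):
        U_front = np.where(counts > 0, sum_front / np.maximum(counts, 1), np.nan)
        U_left = np.where(counts > 0, sum_left / np.maximum(counts, 1), np.nan)
    return CoMovementMap(
        bin_centers_um=centers,
        U_front=U_front,
        U_left=U_left,
        n_samples=counts,
        bin_um=bin_um,
        moving_min_um_per_h=float(moving_min_um_per_h),
    )


def axis_profiles(
    cmap: CoMovementMap, strip_halfwidth_um: float = 37.5
) -> dict[str, pd.DataFrame]:
    """Sample the co-moving (front) speed along the two principal axes.

    Returns two distance profiles: ``front_rear`` keeps the forward and
    backward sides separate (columns ``U_front_side``/``U_rear_side``) plus
    their count-weighted mean ``U``; ``left_right`` averages the two lateral
    sides by symmetry.  Empty strips yield missing rows, not zeros.
    """
    centers = cmap.bin_centers_um
    half = strip_halfwidth_um
    in_strip_left = np.abs(centers) <= half      # lateral coordinate filter
    dist = np.unique(np.abs(centers))

    def _weighted(u: np.ndarray, n: np.ndarray) -> float:
        total = n.sum()
        if total == 0:
            return float("nan")
        ok = n > 0
        return float(np.sum(u[ok] * n[ok]) / total)

    rows_fr = []
    for d in dist:
        fwd = np.isclose(centers, d)
        bwd = np.isclose(centers, -d)
        n_f = cmap.n_samples[fwd][:, in_strip_left]
        n_b = cmap.n_samples[bwd][:, in_strip_left]
        u_f = np.nan_to_num(cmap.U_front[fwd][:, in_strip_left])
        u_b = np.nan_to_num(cmap.U_front[bwd][:, in_strip_left])
        n_all = int(n_f.sum() + n_b.sum())
        if n_all == 0:
            continue
        rows_fr.append(
            {
                "distance_um": float(d),
                "U_front_side": _weighted(u_f, n_f),
                "U_rear_side": _weighted(u_b, n_b),
                "U": float(
                    (np.sum(u_f * n_f) + np.sum(u_b * n_b)) / n_all
                ),
                "n": n_all,
            }
        )

    in_strip_front = np.abs(centers) <= half     # front coordinate filter
    rows_lr = []
    for d in dist:
        lft = np.isclose(centers, d)
        rgt = np.isclose(centers, -d)
        n_l = cmap.n_samples[in_strip_front][:, lft]
        n_r = cmap.n_samples[in_strip_front][:, rgt]
        u_l = np.nan_to_num(cmap.U_front[in_strip_front][:, lft])
        u_r = np.nan_to_num(cmap.U_front[in_strip_front][:, rgt])
        n_all = int(n_l.sum() + n_r.sum())
        if n_all == 0:
            continue
        rows_lr.append(
            {
                "distance_um": float(d),
                "U": float((np.sum(u_l * n_l) + np.sum(u_r * n_r)) / n_all),
                "n": n_all,
            }
        )
    if not rows_fr or not rows_lr:
        raise ValueError("co-movement map empty along a principal axis")
    return {
        "front_rear": pd.DataFrame(rows_fr),
        "left_right": pd.DataFrame(rows_lr),
    }


def _exp_decay(x, a, x0, U0):
    return a * np.exp(-x / x0) + U0


def fit_correlation_length(
    distance_um,
    values,
    counts=None,
    flat_tol: float = 1e-3,
    x0_max_factor: float = 1.0,
    noise_factor: float = 3.0,
) -> CorrelationFit:
    """Fit U(x) = a·exp(−x/x0) + U0 with a ≥ 0, x0 > 0.

    Initial guesses: U0 from the tail mean, a from head − tail, x0 from the
    distance at which the excess over U0 first halves.  A profile whose head
    and tail are indistinguishable (relative to its overall scale) has no
    identifiable correlation length and is reported unconverged.

    ``counts`` optionally weights each point by its per-bin sample count
    (σ ∝ 1/√n).  The correlation length is capped at ``x0_max_factor`` times
    the largest sampled distance: beyond that the decay is outside the
    observed range and x0 degenerates against the offset U0.  A fit whose
    amplitude is below ``noise_factor`` times the residual scatter is
    chasing bin noise rather than a real decay and is reported unconverged
    (the profile of uncorrelated motion is flat noise, and noise-trend fits
    would otherwise produce arbitrary correlation lengths).
    """
    x = np.asarray(distance_um, float)
    y = np.asarray(values, float)
    w = None if counts is None else np.asarray(counts, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if w is not None:
        ok &= w > 0
        w = w[ok]
    x, y = x[ok], y[ok]
    if len(x) < 4 or len(np.unique(x)) < 2:
        raise ValueError("need ≥4 profile points at ≥2 distinct distances")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if w is not None:
        w = w[order]

    tail = float(np.mean(y[-max(2, len(y) // 4):]))
    head = float(y[0])
    scale = max(float(np.max(np.abs(y))), 1e-12)
    if abs(head - tail) <= flat_tol * scale:
        return CorrelationFit(
            a=0.0, x0_um=float("nan"), U0=tail, rss=float(np.sum((y - tail) ** 2)),
            converged=False,
        )

    a0 = head - tail
    half_level = tail + a0 / 2.0
    below = np.flatnonzero(y < half_level) if a0 > 0 else np.flatnonzero(y > half_level)
    x_half = x[below[0]] if below.size else x[len(x) // 2]
    x0_guess = max(x_half / math.log(2.0), 1e-3) if x_half > 0 else max(x[1], 1.0)
    x0_cap = x0_max_factor * float(x.max())
    # decay shorter than the first sampled distance cannot be resolved and
    # only feeds a degenerate single-point spike mode
    x0_floor = max(float(x[x > 0].min()) if np.any(x > 0) else 1e-9, 1e-9)
    x0_guess = float(np.clip(x0_guess, x0_floor, x0_cap))
    sigma = None if w is None else 1.0 / np.sqrt(w)

    # the RSS landscape is multi-modal (a spike mode with tiny x0, a flat
    # mode with x0 at the cap); a small multi-start sweep picks the best basin
    span = float(x.max() - x.min())
    starts = {x0_guess, span / 10.0, span / 3.0, span}
    best = None
    for s0 in sorted(starts):
        try:
            popt, _ = curve_fit(
                _exp_decay,
                x,
                y,
                p0=[max(a0, 1e-6), float(np.clip(s0, x0_floor, x0_cap)), tail],
                sigma=sigma,
                bounds=([0.0, x0_floor, -np.inf], [np.inf, x0_cap, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        resid = y - _exp_decay(x, *popt)
        rss = float(np.sum(resid**2) if w is None else np.sum(w * resid**2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return CorrelationFit(
            a=float("nan"), x0_um=float("nan"), U0=float("nan"),
            rss=float("nan"), converged=False,
        )
    popt, rss = best
    resid = y - _exp_decay(x, *popt)
    resid_sd = float(np.std(resid, ddof=1))
    significant = popt[0] >= noise_factor * resid_sd
    return CorrelationFit(
        a=float(popt[0]),
        x0_um=float(popt[1]) if significant else float("nan"),
        U0=float(popt[2]),
        rss=rss,
        converged=bool(significant),
        resid_sd=resid_sd,
    )


def correlation_lengths(
    source,
    bin_um: float = 25.0,
    extent_um: float = 500.0,
    strip_halfwidth_um: float = 37.5,
    **map_kwargs,
) -> dict[str, CorrelationFit]:
    """Parallel and perpendicular correlation lengths of one recording.

    Convenience wrapper: builds the co-movement map, samples the front–rear
    and left–right profiles and fits each with the exponential decay.
    Returns ``{"parallel": fit, "perpendicular": fit}``.
    """
    cmap = comovement_map(source, bin_um=bin_um, extent_um=extent_um, **map_kwargs)
    profiles = axis_profiles(cmap, strip_halfwidth_um=strip_halfwidth_um)
    return {
        "parallel": fit_correlation_length(
            profiles["front_rear"]["distance_um"],
            profiles["front_rear"]["U"],
            counts=profiles["front_rear"]["n"],
        ),
        "perpendicular": fit_correlation_length(
            profiles["left_right"]["distance_um"],
            profiles["left_right"]["U"],
            counts=profiles["left_right"]["n"],
        ),
    }
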
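"""Single-cell trajectory statistics.

Given manually (or synthetically) tracked cell positions ``P(i, t)`` and a
wound axis — the direction perpendicular to the wound edge — each trajectory
is summarised by three numbers evaluated at a time point ``t``:

* total path length ``T(i, t)``: the cumulative Euclidean distance travelled,
* net displacement into the wound ``D(i, t) = |X(i, t) - X(i, 0)|`` where
  ``X`` is the position projected onto the wound axis,
* guidance efficiency ``D/T`` in [0, 1]: 1 for a cell marching straight into
  the wound, 0 for a cell with no net wound-directed progress.

Cultures are characterised by the population mean ± SEM of these single-cell
measures at a fixed evaluation time (default 10 h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrackSet",
    "TrajectoryStats",
    "read_tracks",
    "path_length",
    "net_displacement",
    "guidance_efficiency",
    "population_summary",
]

TRACK_COLUMNS = ["track_id", "t_h", "x_um", "y_um"]


@dataclass
class TrackSet:
    """A set of cell trajectories with a declared wound axis.

    ``data`` holds one row per (cell, time point) with columns
    ``track_id, t_h, x_um, y_um``, sorted by track and time.  The wound axis
    is the unit vector perpendicular to the wound edge (default +x).
    """

    data: pd.DataFrame
    wound_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    origin_time_h: float = 0.0

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"track table missing columns {missing}")
        self.wound_axis = _unit_axis(self.wound_axis)
        df = self.data.sort_values(["track_id", "t_h"], kind="stable")
        self.data = df.reset_index(drop=True)
        values = df[["t_h", "x_um", "y_um"]].to_numpy(float)
        if not np.all(np.isfinite(values)):
            raise ValueError("track coordinates/times must be finite")
        for tid, grp in df.groupby("track_id", sort=False):
            t = grp["t_h"].to_numpy(float)
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"track {tid!r}: times not strictly increasing")

    @property
    def track_ids(self) -> list:
        return list(dict.fromkeys(self.data["track_id"]))

    def __len__(self) -> int:
        return len(self.track_ids)

    def track(self, track_id) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(t_h, xy_um)`` arrays for one track."""
        grp = self.data[self.data["track_id"] == track_id]
        if grp.empty:
            raise KeyError(track_id)
        return grp["t_h"].to_numpy(float), grp[["x_um", "y_um"]].to_numpy(float)

    def to_csv(self, path, dt_min: float | None = None) -> None:
        """Write ``track_id, frame, x_um, y_um, t_h`` rows.

        Frames are recovered from times if a frame interval is given,
        otherwise numbered within each track.
        """
        df = self.data.copy()
        if dt_min is not None:
            df["frame"] = np.rint(
                (df["t_h"] - self.origin_time_h) * 60.0 / dt_min
            ).astype(int)
        else:
            df["frame"] = df.groupby("track_id", sort=False).cumcount()
        df[["track_id", "frame", "x_um", "y_um", "t_h"]].to_csv(path, index=False)


def _unit_axis(axis) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    norm = float(np.linalg.norm(axis))
    if not math.isfinite(norm) or norm == 0.0:
        raise ValueError("wound_axis must be a nonzero finite vector")
    return axis / norm


def read_tracks(
    path,
    dt_min: float | None = None,
    wound_axis=(1.0, 0.0),
) -> TrackSet:
    """Load a track table from CSV.

    Requires columns ``track_id, frame, x_um, y_um``; times come from an
    optional ``t_h`` column or from ``frame × dt_min``.  Rows are grouped by
    track id and sorted by frame; duplicated (id, frame) pairs are an error.
    Frame gaps are allowed (each later contributes a single chord step).
    """
    df = pd.read_csv(path)
    required = ["track_id", "frame", "x_um", "y_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("frame", "x_um", "y_um"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if df.duplicated(subset=["track_id", "frame"]).any():
        dupes = df[df.duplicated(subset=["track_id", "frame"])]["track_id"].unique()
        raise ValueError(f"duplicate (track_id, frame) rows for tracks {list(dupes)}")
    if "t_h" in df.columns:
        df["t_h"] = pd.to_numeric(df["t_h"], errors="raise")
    elif dt_min is not None:
        df["t_h"] = df["frame"] * dt_min / 60.0
    else:
        raise ValueError("need a t_h column or an explicit frame interval dt_min")
    return TrackSet(df[TRACK_COLUMNS], wound_axis=np.asarray(wound_axis, float))


def _clip_track(t_h: np.ndarray, xy: np.ndarray, t_eval_h: float):
    if t_eval_h < t_h[0]:
        raise ValueError(
            f"evaluation time {t_eval_h} h precedes track start {t_h[0]} h"
        )
    last = int(np.searchsorted(t_h, t_eval_h, side="right"))
    return xy[:last]


def path_length(t_h, xy, t_eval_h: float) -> float:
    """Total path length T: sum of step lengths up to the last sample ≤ t."""
    t_h = np.asarray(t_h, float)
    xy = np.asarray(xy, float)
    pts = _clip_track(t_h, xy, t_eval_h)
    if len(pts) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def net_displacement(t_h, xy, t_eval_h: float, wound_axis=(1.0, 0.0)) -> float:
    """Net displacement into the wound D = |X(t) − X(0)| along the wound axis."""
    axis = _unit_axis(wound_axis)
    t_h = np.asarray(t_h, float)
    xy = np.asarray(xy, float)
    pts = _clip_track(t_h, xy, t_eval_h)
    return float(abs((pts[-1] - pts[0]) @ axis))


def guidance_efficiency(
    t_h, xy, t_eval_h: float, wound_axis=(1.0, 0.0)
) -> float:
    """Guidance efficiency D/T; NaN (undefined) for a cell that never moved."""
    T = path_length(t_h, xy, t_eval_h)
    if T == 0.0:
        return float("nan")
    return net_displacement(t_h, xy, t_eval_h, wound_axis) / T


@dataclass
class TrajectoryStats:
    """Per-cell (T, D, D/T) table at an evaluation time plus population summary."""

    per_cell: pd.DataFrame          # track_id, T_um, D_um, ratio
    t_eval_h: float
    population: dict                # metric -> {"mean": .., "sem": .., "n": ..}
    n_excluded_short: int = 0       # tracks ending before t_eval
    n_undefined_ratio: int = 0      # tracks with T == 0


def population_summary(tracks: TrackSet, t_eval_h: float = 10.0) -> TrajectoryStats:
    """Evaluate (T, D, D/T) for every track reaching ``t_eval_h``.

    Tracks that end before the evaluation time are excluded (their count is
    reported); tracks with zero path length have an undefined ratio and are
    excluded from the ratio mean only.
    """
    rows = []
    n_short = 0
    for tid in tracks.track_ids:
        t_h, xy = tracks.track(tid)
        if t_h[-1] < t_eval_h or t_h[0] > t_eval_h:
            n_short += 1
            continue
        T = path_length(t_h, xy, t_eval_h)
        D = net_displacement(t_h, xy, t_eval_h, tracks.wound_axis)
        ratio = D / T if T > 0 else float("nan")
        rows.append({"track_id": tid, "T_um": T, "D_um": D, "ratio": ratio})
    if not rows:
        raise ValueError(f"no track reaches evaluation time {t_eval_h} h")
    per_cell = pd.DataFrame(rows)
    population = {}
    for metric in ("T_um", "D_um", "ratio"):
        vals = per_cell[metric].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        n = len(vals)
        sem = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        population[metric] = {"mean": float(np.mean(vals)), "sem": sem, "n": n}
    return TrajectoryStats(
        per_cell=per_cell,
        t_eval_h=t_eval_h,
        population=population,
        n_excluded_short=n_short,
        n_undefined_ratio=int(per_cell["ratio"].isna().sum()),
    )
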
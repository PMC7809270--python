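"""Nematic order of nuclear orientations in section images.

Elongated (spindle-shaped) cells orient their nuclei along the cell body, so
the nucleus long axis is a proxy for local cell orientation.  The pipeline:
segment nuclei by global thresholding, split touching nuclei by watershed,
fit an ellipse to each region from its second central moments, keep only
nuclei with an unambiguous axis (minor/major < 0.8), and quantify local
ordering on a spatial grid (default 50 µm) with the scalar 2D nematic order
parameter

    S² = ⟨cos 2θ⟩² + ⟨sin 2θ⟩²,

where θ is the long-axis angle against a reference direction.  S = 1 means
perfectly parallel nuclei, S = 0 a completely random set; the doubled angles
make the measure independent of axis polarity (θ and θ+180° are the same
orientation).  A Monte-Carlo null (uniform random orientations) provides the
significance threshold for finite samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops
from skimage.segmentation import watershed

__all__ = [
    "NucleusEllipse",
    "OrderGrid",
    "segment_nuclei",
    "fit_ellipses",
    "order_parameter",
    "order_grid",
    "pooled_region_order",
    "null_order_ci",
]


@dataclass
class NucleusEllipse:
    """Moment-equivalent ellipse of one segmented nucleus."""

    centroid_um: tuple
    major_um: float
    minor_um: float
    theta_deg: float        # long-axis angle vs +x, in [0°, 180°)
    area_px: int


@dataclass
class OrderGrid:
    """Per-grid-cell nematic order.

    ``S`` and ``direction_deg`` are NaN where fewer than ``n_min`` nuclei
    fell into the cell (a single nucleus is degenerately ordered).
    """

    cell_size_um: float
    x_edges_um: np.ndarray
    y_edges_um: np.ndarray
    S: np.ndarray
    direction_deg: np.ndarray
    n_nuclei: np.ndarray
    n_min: int

    def to_dataframe(self) -> pd.DataFrame:
        xc = 0.5 * (self.x_edges_um[:-1] + self.x_edges_um[1:])
        yc = 0.5 * (self.y_edges_um[:-1] + self.y_edges_um[1:])
        gx, gy = np.meshgrid(xc, yc, indexing="ij")
        return pd.DataFrame(
            {
                "x_um": gx.ravel(),
                "y_um": gy.ravel(),
                "S": self.S.ravel(),
                "direction_deg": self.direction_deg.ravel(),
                "n": self.n_nuclei.ravel(),
            }
        )


def segment_nuclei(
    image: np.ndarray,
    min_area_px: int = 10,
    min_peak_separation_px: int = 5,
) -> np.ndarray:
    """Label nuclei: global Otsu threshold + distance-transform watershed.

    Touching nuclei are split by a watershed on the negated distance
    transform seeded at its local maxima (minimum separation 5 px).  Regions
    with area ≤ ``min_area_px`` are discarded.  An image with no foreground
    yields an empty labeling with a warning rather than an error.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if np.ptp(image) == 0:
        warnings.warn("uniform image: no nuclei segmented")
        return np.zeros(image.shape, dtype=np.int32)
    binary = image > threshold_otsu(image)
    if not binary.any():
        warnings.warn("empty segmentation: no pixels above threshold")
        return np.zeros(image.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(binary)
    smooth = ndi.gaussian_filter(distance, sigma=1.0)  # suppress ridge plateaus
    peaks = peak_local_max(
        smooth,
        min_distance=min_peak_separation_px,
        labels=sk_label(binary),
        exclude_border=False,
    )
    markers = np.zeros(image.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-smooth, markers, mask=binary)
    # drop small clusters, relabel compactly
    sizes = np.bincount(labels.ravel())
    too_small = np.flatnonzero(sizes <= min_area_px)
    labels[np.isin(labels, too_small)] = 0
    return sk_label(labels > 0) if labels.max() == 0 else _relabel(labels)


def _relabel(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


def fit_ellipses(
    labels: np.ndarray,
    pixel_size_um: float = 1.0,
    aspect_max: float = 0.8,
) -> list[NucleusEllipse]:
    """Moment ellipses of labeled regions, keeping unambiguous orientations.

    Regions whose minor/major axis ratio is ≥ ``aspect_max`` are too round
    to define an axis and are dropped, as are degenerate (zero-minor-axis)
    regions; the dropped count is reported via a warning when nonzero.
    """
    ellipses: list[NucleusEllipse] = []
    n_round = n_degenerate = 0
    for region in regionprops(labels):
        major = region.axis_major_length
        minor = region.axis_minor_length
        if major == 0 or minor == 0:
            n_degenerate += 1
            continue
        if minor / major >= aspect_max:
            n_round += 1
            continue
        # regionprops orientation: angle of the major axis against the row
        # (0th) axis, CCW in (row, col) space; convert to angle vs +x columns
        theta = (90.0 - math.degrees(region.orientation)) % 180.0
        cy, cx = region.centroid
        ellipses.append(
            NucleusEllipse(
                centroid_um=(cx * pixel_size_um, cy * pixel_size_um),
                major_um=major * pixel_size_um,
                minor_um=minor * pixel_size_um,
                theta_deg=theta,
                area_px=int(region.area),
            )
        )
    if n_degenerate:
        warnings.warn(f"dropped {n_degenerate} degenerate 1-px-wide regions")
    return ellipses


def order_parameter(theta_deg) -> tuple[float, float]:
    """(S, prevailing direction in [0°, 180°)) of a set of axis angles."""
    theta = np.deg2rad(np.asarray(theta_deg, float))
    c = float(np.mean(np.cos(2.0 * theta)))
    s = float(np.mean(np.sin(2.0 * theta)))
    S = math.hypot(c, s)
    direction = math.degrees(0.5 * math.atan2(s, c)) % 180.0
    return S, direction


def ellipse_table(ellipses: list[NucleusEllipse]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_um": [e.centroid_um[0] for e in ellipses],
            "y_um": [e.centroid_um[1] for e in ellipses],
            "theta_deg": [e.theta_deg for e in ellipses],
            "major_um": [e.major_um for e in ellipses],
            "minor_um": [e.minor_um for e in ellipses],
            "area_px": [e.area_px for e in ellipses],
        }
    )


def order_grid(
    ellipses: list[NucleusEllipse],
    cell_size_um: float = 50.0,
    n_min: int = 3,
) -> OrderGrid:
    """Nematic order on a spatial grid (default pitch 50 µm).

    Grid cells with fewer than ``n_min`` member nuclei are reported empty
    (NaN) — the order of one or two nuclei is degenerately high.
    """
    if not ellipses:
        raise ValueError("no ellipses to grid")
    xs = np.array([e.centroid_um[0] for e in ellipses])
    ys = np.array([e.centroid_um[1] for e in ellipses])
    thetas = np.array([e.theta_deg for e in ellipses])
    nx = max(1, int(np.ceil(xs.max() / cell_size_um)))
    ny = max(1, int(np.ceil(ys.max() / cell_size_um)))
    x_edges = np.arange(nx + 1) * cell_size_um
    y_edges = np.arange(ny + 1) * cell_size_um
    S = np.full((nx, ny), np.nan)
    direction = np.full((nx, ny), np.nan)
    counts = np.zeros((nx, ny), dtype=int)
    ix = np.clip((xs // cell_size_um).astype(int), 0, nx - 1)
    iy = np.clip((ys // cell_size_um).astype(int), 0, ny - 1)
    for i in range(nx):
        for j in range(ny):
            members = thetas[(ix == i) & (iy == j)]
            counts[i, j] = len(members)
            if len(members) >= n_min:
                S[i, j], direction[i, j] = order_parameter(members)
    return OrderGrid(
        cell_size_um=cell_size_um,
        x_edges_um=x_edges,
        y_edges_um=y_edges,
        S=S,
        direction_deg=direction,
        n_nuclei=counts,
        n_min=n_min,
    )


def pooled_region_order(
    ellipses: list[NucleusEllipse],
    region_polygons: dict,
) -> dict[str, dict]:
    """Pooled nematic order per named region (polygons in µm).

    Nuclei are assigned by centroid; pooling nuclei from several specimens is
    done by concatenating their ellipse lists before the call.  Nuclei
    outside every polygon are excluded (their count is reported under
    ``"_unassigned"``); empty regions are flagged with S = None.
    """
    from shapely.geometry import Point, Polygon

    polys = {name: Polygon(coords) for name, coords in region_polygons.items()}
    assigned: dict[str, list] = {name: [] for name in polys}
    n_outside = 0
    for e in ellipses:
        point = Point(*e.centroid_um)
        for name, poly in polys.items():
            if poly.contains(point):
                assigned[name].append(e.theta_deg)
                break
        else:
            n_outside += 1
    result: dict[str, dict] = {}
    for name, thetas in assigned.items():
        if thetas:
            S, direction = order_parameter(thetas)
            result[name] = {"S": S, "direction_deg": direction, "n": len(thetas)}
        else:
            result[name] = {"S": None, "direction_deg": None, "n": 0, "empty": True}
    result["_unassigned"] = {"n": n_outside}
    return result


def null_order_ci(
    n: int,
    reps: int = 10000,
    level: float = 0.99,
    seed: int | None = None,
) -> float:
    """Monte-Carlo null threshold for S under uniform random orientations.

    Returns the ``level`` percentile of S over ``reps`` draws of ``n``
    independent uniform axis angles; a measured S above it rejects the
    random-orientation null.  For large n the threshold approaches the 2D
    random-walk closed form sqrt(ln(1/(1−level))/n).
    """
    if n < 1:
        raise ValueError("need at least one nucleus")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if reps < 100:
        raise ValueError("reps < 100 gives an unstable percentile")
    rng = np.random.default_rng(seed)
    two_theta = rng.uniform(0.0, 2.0 * np.pi, size=(reps, n))
    S = np.hypot(
        np.mean(np.cos(two_theta), axis=1), np.mean(np.sin(two_theta), axis=1)
    )
    return float(np.percentile(S, 100.0 * level))
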
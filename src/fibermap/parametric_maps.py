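"""Dense parametric maps computed from fiber graphs.

Two maps are produced:

* **Fiber length map** -- each chord of the simplified graph is
  rasterized (integer line drawing) and its Euclidean length written
  onto the chord's pixels (overlaps keep the maximum, preserving the
  detectability of long fibers); values are then extrapolated to every
  pixel by nearest assigned pixel and smoothed with a Gaussian kernel.

* **Pore directionality map** -- pores are the enclosed background
  components of the fiber mask; an ellipse is fitted to each pore by
  second-order central moments and its major-axis angle theta_i (degrees
  against the horizontal axis, in [0, 180)) is compared with the circular
  median orientation of all pores (subtracting the median removes global
  image rotation).  The pore's pixels receive the score
  1 / (eps + delta_i), where delta_i is the orientation difference folded
  into [0, 90] degrees and eps (default 1 degree) regularizes the
  otherwise infinite score at delta = 0.  High values mark regions whose
  pores align with the dominant orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

from .fiber_graph import FiberGraph
from .grf import ParametricMap

__all__ = [
    "PoreRecord",
    "fiber_length_map",
    "pore_directionality_map",
    "pore_detect",
    "circular_median_orientation",
    "fold_orientation_difference",
]

DEFAULT_SMOOTH_SIGMA = 5.0
DEFAULT_EPSILON_DEG = 1.0
_MIN_AXIS_RATIO = 1.05


@dataclass
class PoreRecord:
    """An enclosed background component with its fitted ellipse."""

    label: int
    pixels: np.ndarray            # (n, 2) (row, col) coordinates
    centroid: tuple[float, float]
    major_axis: float             # full axis lengths, pixels
    minor_axis: float
    theta: float                  # degrees vs horizontal axis, [0, 180)
    area: int
    orientation_reliable: bool = True
    delta: float | None = None    # folded deviation from median, degrees
    score: float | None = None


# ---------------------------------------------------------------------------
# Fiber length map
# ---------------------------------------------------------------------------

def rasterize_fiber_lengths(graph: FiberGraph, shape: tuple[int, int]) -> np.ndarray:
    """Write each chord's length onto its line pixels (max on overlap).

    Unassigned pixels are NaN.
    """
    if graph.n_edges == 0:
        raise ValueError("cannot rasterize an empty graph")
    out = np.full(shape, np.nan)
    pos = graph.node_positions()
    for u, v, d in graph.graph.edges(data=True):
        r0, c0 = (int(round(x)) for x in pos[u])
        r1, c1 = (int(round(x)) for x in pos[v])
        h, w = shape
        r0, r1 = np.clip([r0, r1], 0, h - 1)
        c0, c1 = np.clip([c0, c1], 0, w - 1)
        rr, cc = draw_line(r0, c0, r1, c1)
        cur = out[rr, cc]
        out[rr, cc] = np.where(np.isnan(cur), d["length"], np.maximum(cur, d["length"]))
    return out


def extrapolate_nearest(sparse: np.ndarray) -> np.ndarray:
    """Fill NaN pixels with the value of the nearest assigned pixel."""
    missing = np.isnan(sparse)
    if not missing.any():
        return sparse.copy()
    if missing.all():
        raise ValueError("no assigned pixels to extrapolate from")
    idx = ndimage.distance_transform_edt(missing, return_distances=False, return_indices=True)
    return sparse[tuple(idx)]


def fiber_length_map(
    graph: FiberGraph,
    shape: tuple[int, int],
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
    pixel_size: float | None = None,
) -> ParametricMap:
    """Dense fiber length map from a simplified fiber graph.

    ``smooth_sigma`` is the Gaussian smoothing width in pixels
    (0 disables smoothing; useful for inspecting the raw assignment).
    """
    if graph.variant != "simplified":
        raise ValueError("fiber_length_map expects the simplified graph variant")
    sparse = rasterize_fiber_lengths(graph, shape)
    dense = extrapolate_nearest(sparse)
    if smooth_sigma > 0:
        dense = ndimage.gaussian_filter(dense, smooth_sigma)
    return ParametricMap(dense, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Pore detection and directionality
# ---------------------------------------------------------------------------

def _ellipse_from_coords(coords: np.ndarray):
    """Moments-based ellipse fit; angle vs the horizontal axis in [0, 180).

    Works in a right-handed frame (x = col, y = -row) so that angles are
    measured counterclockwise from +x when the image is viewed with the
    row axis pointing down.
    """
    x = coords[:, 1].astype(float)
    y = -coords[:, 0].astype(float)
    x -= x.mean()
    y -= y.mean()
    mxx = np.mean(x * x)
    myy = np.mean(y * y)
    mxy = np.mean(x * y)
    theta = 0.5 * np.degrees(np.arctan2(2.0 * mxy, mxx - myy))
    theta %= 180.0
    common = np.sqrt(max((mxx - myy) ** 2 + 4 * mxy**2, 0.0))
    l1 = (mxx + myy + common) / 2.0
    l2 = (mxx + myy - common) / 2.0
    major = 4.0 * np.sqrt(max(l1, 0.0))
    minor = 4.0 * np.sqrt(max(l2, 0.0))
    return theta, major, minor


def pore_detect(fiber_mask: np.ndarray) -> list[PoreRecord]:
    """Enclosed background components of a binary fiber mask.

    Background is labeled with 4-connectivity (the complement convention
    for 8-connected foreground); components touching the image border
    are excluded.  Near-circular pores (axis ratio below 1.05) keep
    their fitted angle but are flagged orientation-unreliable.
    """
    fiber_mask = np.asarray(fiber_mask).astype(bool)
    bg = ~fiber_mask
    labels, n = ndimage.label(bg, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    border = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    border = set(border.tolist()) - {0}
    records = []
    for lab in range(1, n + 1):
        if lab in border:
            continue
        coords = np.column_stack(np.nonzero(labels == lab))
        theta, major, minor = _ellipse_from_coords(coords)
        ratio = major / minor if minor > 0 else np.inf
        records.append(
            PoreRecord(
                label=lab,
                pixels=coords,
                centroid=(float(coords[:, 0].mean()), float(coords[:, 1].mean())),
                major_axis=float(major),
                minor_axis=float(minor),
                theta=float(theta),
                area=len(coords),
                orientation_reliable=bool(ratio >= _MIN_AXIS_RATIO),
            )
        )
    return records


def fold_orientation_difference(a: float, b: float) -> float:
    """Circular difference of two undirected orientations, in [0, 90] deg."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def circular_median_orientation(thetas) -> float:
    """Orientation minimizing the summed folded deviations (ties: lower angle)."""
    thetas = sorted(float(t) % 180.0 for t in thetas)
    if not thetas:
        raise ValueError("no orientations given")
    best, best_cost = None, np.inf
    for cand in thetas:
        cost = sum(fold_orientation_difference(t, cand) for t in thetas)
        if cost < best_cost - 1e-12 or (abs(cost - best_cost) <= 1e-12 and cand < best):
            best, best_cost = cand, cost
    return best


def pore_directionality_map(
    fiber_mask: np.ndarray,
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
    epsilon: float = DEFAULT_EPSILON_DEG,
    pixel_size: float | None = None,
) -> tuple[ParametricMap, list[PoreRecord]]:
    """Pore directionality map plus the per-pore records used to build it.

    Each enclosed pore's pixels receive ``1 / (epsilon + delta)`` where
    ``delta`` is the pore orientation's folded deviation (degrees, in
    [0, 90]) from the circular median orientation of all pores.  The
    median subtraction makes the map invariant to global image rotation.
    Pixels outside any pore stay 0.  The result is Gaussian smoothed.
    """
    pores = pore_detect(fiber_mask)
    if not pores:
        raise ValueError("fiber mask contains no enclosed pores")
    median = circular_median_orientation([p.theta for p in pores])
    out = np.zeros(np.asarray(fiber_mask).shape, dtype=float)
    for p in pores:
        p.delta = fold_orientation_difference(p.theta, median)
        p.score = 1.0 / (epsilon + p.delta)
        out[p.pixels[:, 0], p.pixels[:, 1]] = p.score
    if smooth_sigma > 0:
        out = ndimage.gaussian_filter(out, smooth_sigma)
    return ParametricMap(out, pixel_size=pixel_size), pores
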
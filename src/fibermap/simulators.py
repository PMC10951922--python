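"""Synthetic scene generators and ground-truth scoring.

Three generators cover the study conditions used throughout the test
suite and the two end-to-end anomaly-detection experiments:

* :func:`simulate_grf` -- a zero-mean stationary Gaussian random field
  (white noise smoothed by an isotropic Gaussian kernel, rescaled to a
  target standard deviation).
* :func:`inject_ellipses` -- adds disjoint elliptical "foreign objects"
  of varied area and added intensity to a scene (larger ellipses get the
  lower added intensities, so detectability is spread across both the
  extent and the peak criterion).
* :func:`simulate_fiber_network` -- a jittered offset (triangular-like)
  lattice whose Delaunay edges are the fibers; inside an optional defect
  mask the lattice spacing is larger, producing locally more elongated
  fibers.  The generating graph is returned as ground truth.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .fiber_graph import FiberGraph

__all__ = [
    "SyntheticScene",
    "simulate_grf",
    "inject_ellipses",
    "simulate_fiber_network",
    "three_ellipse_defect_mask",
    "score_detections",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class SyntheticScene:
    """Generated image (or map) with its ground-truth anomaly mask."""

    image: np.ndarray
    truth_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.truth_mask = np.asarray(self.truth_mask).astype(bool)
        if self.truth_mask.shape != self.image.shape:
            raise ValueError("truth mask and image shapes differ")


def simulate_grf(
    shape: tuple[int, int] = (512, 512),
    kernel_width: float = 3.0,
    sigma: float = 1.0,
    seed: int = 0,
) -> SyntheticScene:
    """Zero-mean stationary GRF: smoothed white noise, rescaled.

    ``kernel_width`` is the standard deviation (pixels) of the isotropic
    Gaussian smoothing kernel; periodic boundary handling keeps the
    field stationary up to the image edge.  The sample mean is removed
    and the sample standard deviation set exactly to ``sigma``.
    """
    if kernel_width < 1.0:
        raise ValueError("kernel_width must be at least 1 px")
    rng = np.random.default_rng(seed)
    f = ndimage.gaussian_filter(rng.standard_normal(shape), kernel_width, mode="wrap")
    f -= f.mean()
    f *= sigma / f.std()
    return SyntheticScene(
        image=f,
        truth_mask=np.zeros(shape, dtype=bool),
        provenance={
            "generator": "simulate_grf",
            "shape": list(shape),
            "kernel_width": kernel_width,
            "sigma": sigma,
            "seed": int(seed),
        },
    )


def inject_ellipses(
    scene: SyntheticScene,
    n_ellipses: int = 6,
    semi_major_range: tuple[float, float] = (8.0, 18.0),
    semi_minor_range: tuple[float, float] = (5.0, 10.0),
    intensity_range: tuple[float, float] = (4.0, 8.0),
    seed: int = 0,
    max_tries: int = 2000,
) -> SyntheticScene:
    """Add disjoint elliptical foreign objects to a scene.

    Semi-axes are drawn uniformly from the given ranges and each ellipse
    gets a random orientation.  Added intensities are ``intensity_range``
    multiples of the scene's standard deviation, evenly spaced and paired
    with the ellipses sorted by decreasing area (largest area, lowest
    added intensity).  Placement retries until the ellipses are mutually
    disjoint with a 3-px separation and stay off the border; failure to
    place after ``max_tries`` raises.
    """
    if n_ellipses == 0:
        return SyntheticScene(scene.image.copy(), scene.truth_mask.copy(),
                              dict(scene.provenance, ellipses=0))
    rng = np.random.default_rng(seed)
    shape = scene.image.shape
    field_sd = scene.image.std()

    params = []
    for _ in range(n_ellipses):
        a = rng.uniform(*semi_major_range)
        b = rng.uniform(*semi_minor_range)
        params.append((a, b, rng.uniform(0.0, np.pi)))
    params.sort(key=lambda p: p[0] * p[1], reverse=True)
    intensities = np.linspace(*intensity_range, n_ellipses) * field_sd

    occupied = np.zeros(shape, dtype=bool)
    truth = np.zeros(shape, dtype=bool)
    image = scene.image.copy()
    margin = int(np.ceil(max(semi_major_range)) + 2)
    placed_meta = []
    for (a, b, rot), level in zip(params, intensities):
        for attempt in range(max_tries):
            r = rng.integers(margin, shape[0] - margin)
            c = rng.integers(margin, shape[1] - margin)
            rr, cc = draw_ellipse(r, c, b, a, shape=shape, rotation=rot)
            cand = np.zeros(shape, dtype=bool)
            cand[rr, cc] = True
            # 3-px separation so truth components stay disjoint
            grown = ndimage.binary_dilation(cand, iterations=3)
            if not (grown & occupied).any():
                break
        else:
            raise RuntimeError("could not place ellipses without overlap")
        occupied |= ndimage.binary_dilation(cand, iterations=3)
        truth |= cand
        image[rr, cc] += level
        placed_meta.append(
            {"center": [int(r), int(c)], "semi_axes": [float(a), float(b)],
             "rotation": float(rot), "added_intensity": float(level)}
        )
    prov = dict(scene.provenance)
    prov.update({"generator": "inject_ellipses", "seed": int(seed),
                 "ellipses": placed_meta})
    return SyntheticScene(image=image, truth_mask=truth, provenance=prov)


# ---------------------------------------------------------------------------
# Jittered-lattice Delaunay fiber networks
# ---------------------------------------------------------------------------

def _offset_lattice(shape, d, margin):
    """Offset (triangular-like) lattice: odd rows shifted by d/2."""
    h, w = shape
    row_step = d * np.sqrt(3.0) / 2.0
    rows = np.arange(-margin, h + margin, row_step)
    pts = []
    for i, y in enumerate(rows):
        off = d / 2.0 if i % 2 == 1 else 0.0
        xs = np.arange(-margin + off, w + margin, d)
        pts.append(np.column_stack([np.full_like(xs, y), xs]))
    return np.concatenate(pts, axis=0)


def simulate_fiber_network(
    shape: tuple[int, int] = (1024, 1024),
    d_normal: float = 16.0,
    d_defect: float = 28.0,
    mask: np.ndarray | None = None,
    jitter_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[SyntheticScene, FiberGraph]:
    """Jittered-lattice Delaunay fiber scene with optional defect regions.

    Two offset lattices are built: spacing ``d_normal`` outside the
    binary ``mask`` and ``d_defect`` (must be larger: defect fibers are
    more elongated) inside it.  Every point is jittered by independent
    uniform offsets of amplitude ``jitter_fraction * d``.  Fibers are the
    Delaunay edges of the combined point set, rendered as 1-px lines into
    a binary image.  A margin of lattice beyond the frame avoids
    artificial long border edges; edges with an endpoint in the margin
    are dropped.  Returns the rendered scene and the generating graph
    (simplified variant: straight chords with Euclidean lengths).
    """
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != tuple(shape):
            raise ValueError("mask shape must match the image shape")
        if not d_defect > d_normal > 0:
            raise ValueError("require d_defect > d_normal > 0")
    elif not d_normal > 0:
        raise ValueError("d_normal must be positive")

    rng = np.random.default_rng(seed)
    margin = 2.0 * max(d_normal, d_defect)

    def jitter(points, d):
        return points + rng.uniform(-jitter_fraction * d, jitter_fraction * d,
                                    size=points.shape)

    def inside_mask(points):
        if mask is None:
            return np.zeros(len(points), dtype=bool)
        r = np.clip(np.round(points[:, 0]).astype(int), 0, shape[0] - 1)
        c = np.clip(np.round(points[:, 1]).astype(int), 0, shape[1] - 1)
        out = (points[:, 0] < 0) | (points[:, 0] >= shape[0]) | \
              (points[:, 1] < 0) | (points[:, 1] >= shape[1])
        res = mask[r, c]
        res[out] = False
        return res

    normal_pts = jitter(_offset_lattice(shape, d_normal, margin), d_normal)
    pts = normal_pts[~inside_mask(normal_pts)]
    if mask is not None and mask.any():
        defect_pts = jitter(_offset_lattice(shape, d_defect, margin), d_defect)
        pts = np.concatenate([pts, defect_pts[inside_mask(defect_pts)]], axis=0)

    tri = Delaunay(pts[:, ::-1])  # Delaunay in (x, y) = (col, row)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            u, v = sorted((simplex[i], simplex[(i + 1) % 3]))
            edges.add((u, v))

    in_frame = (
        (pts[:, 0] >= 0) & (pts[:, 0] < shape[0])
        & (pts[:, 1] >= 0) & (pts[:, 1] < shape[1])
    )
    g = nx.MultiGraph()
    image = np.zeros(shape, dtype=bool)
    for u, v in sorted(edges):
        if not (in_frame[u] and in_frame[v]):
            continue
        pu, pv = pts[u], pts[v]
        if u not in g:
            g.add_node(int(u), pos=(float(pu[0]), float(pu[1])), role="crosslink")
        if v not in g:
            g.add_node(int(v), pos=(float(pv[0]), float(pv[1])), role="crosslink")
        length = float(np.hypot(*(pu - pv)))
        g.add_edge(int(u), int(v), length=length)
        r0 = int(np.clip(round(pu[0]), 0, shape[0] - 1))
        c0 = int(np.clip(round(pu[1]), 0, shape[1] - 1))
        r1 = int(np.clip(round(pv[0]), 0, shape[0] - 1))
        c1 = int(np.clip(round(pv[1]), 0, shape[1] - 1))
        rr, cc = draw_line(r0, c0, r1, c1)
        image[rr, cc] = True

    truth = mask.copy() if mask is not None else np.zeros(shape, dtype=bool)
    scene = SyntheticScene(
        image=image.astype(float),
        truth_mask=truth,
        provenance={
            "generator": "simulate_fiber_network",
            "shape": list(shape),
            "d_normal": d_normal,
            "d_defect": d_defect if mask is not None else None,
            "jitter_fraction": jitter_fraction,
            "seed": int(seed),
        },
    )
    return scene, FiberGraph(g, "simplified")


def three_ellipse_defect_mask(shape: tuple[int, int] = (1024, 1024)) -> np.ndarray:
    """Canonical defect layout: three disjoint ellipses, scaled to ``shape``."""
    h, w = shape
    scale = min(h, w) / 1024.0
    layout = [
        ((0.28, 0.28), (90, 60), np.deg2rad(30)),
        ((0.72, 0.40), (75, 50), np.deg2rad(120)),
        ((0.45, 0.75), (60, 42), np.deg2rad(75)),
    ]
    mask = np.zeros(shape, dtype=bool)
    for (fr, fc), (a, b), rot in layout:
        rr, cc = draw_ellipse(fr * h, fc * w, b * scale, a * scale,
                              shape=shape, rotation=rot)
        mask[rr, cc] = True
    return mask


def score_detections(
    selected_regions: np.ndarray, truth_mask: np.ndarray
) -> tuple[int, int, int]:
    """(true_positives, false_positives, missed) by component intersection.

    TP = truth components intersected by at least one selected region;
    FP = selected components intersecting no truth component;
    missed = truth components with no intersection.  A single detection
    straddling two truth components counts both as found.
    """
    selected_regions = np.asarray(selected_regions).astype(bool)
    truth_mask = np.asarray(truth_mask).astype(bool)
    if selected_regions.shape != truth_mask.shape:
        raise ValueError("selected regions and truth mask shapes differ")
    truth_labels, n_truth = ndimage.label(truth_mask, structure=_EIGHT)
    sel_labels, n_sel = ndimage.label(selected_regions, structure=_EIGHT)
    hit_truth = np.unique(truth_labels[selected_regions])
    tp = int(np.count_nonzero(hit_truth))
    sel_hitting = np.unique(sel_labels[truth_mask])
    fp = int(n_sel - np.count_nonzero(sel_hitting))
    return tp, fp, n_truth - tp
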
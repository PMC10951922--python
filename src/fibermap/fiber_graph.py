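"""Fiber enhancement and graph extraction from 2D fiber-network images.

Pipeline: a bank of Gabor filters spanning several orientations and
wavelengths enhances curvilinear structures; the enhanced image is
binarized (Otsu by default) and thinned to a one-pixel morphological
skeleton; skeleton pixels with one neighbor become *endpoint* nodes and
pixels with three or more become *crosslink* nodes (true junctions and
junctions created by the 2D projection are not distinguished); edges are
the geodesic pixel paths between nodes, with axial steps counted as 1
and diagonal steps as sqrt(2).  Short spurs are pruned.  A *simplified*
variant of the graph replaces each skeleton edge by the straight chord
between its two nodes; "fiber length" then means chord length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage, signal
from skimage.filters import gabor_kernel, threshold_otsu
from skimage.morphology import skeletonize

__all__ = [
    "FiberImage",
    "FiberGraph",
    "gabor_enhance",
    "extract_skeleton_graph",
    "simplify_graph",
]

SQRT2 = float(np.sqrt(2.0))


@dataclass
class FiberImage:
    """A 2D grayscale image of a fibrillar network."""

    values: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("fiber image must be 2D")
        if np.any(self.values < 0):
            raise ValueError("fiber image intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class FiberGraph:
    """Skeleton- or simplified-variant fiber graph.

    Wraps a :class:`networkx.MultiGraph`.  Node attributes: ``pos``
    (row, col) and ``role`` ("endpoint" or "crosslink").  Edge
    attributes: ``length`` (pixels) and, for the skeleton variant,
    ``path`` (the (n, 2) array of skeleton pixels the fiber traverses).
    """

    graph: nx.MultiGraph
    variant: str = "skeleton"  # or "simplified"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_lengths(self) -> np.ndarray:
        return np.array([d["length"] for *_, d in self.graph.edges(data=True)])

    def node_positions(self) -> dict:
        return nx.get_node_attributes(self.graph, "pos")


# ---------------------------------------------------------------------------
# Gabor filter bank
# ---------------------------------------------------------------------------

def gabor_enhance(
    image: FiberImage,
    orientations: int | list[float] = 8,
    wavelengths: tuple[float, ...] = (4.0, 8.0, 16.0),
    return_orientation: bool = False,
):
    """Per-pixel maximum Gabor response magnitude over a filter bank.

    Parameters
    ----------
    orientations : int or list of float
        Number of evenly spaced orientations on [0, pi), or explicit
        angles in radians (at least two).
    wavelengths : tuple of float
        Carrier wavelengths in pixels; each must be >= 2 px (Nyquist).
    return_orientation : bool
        Also return the per-pixel argmax orientation (radians).
    """
    if isinstance(orientations, int):
        thetas = [np.pi * k / orientations for k in range(orientations)]
    else:
        thetas = list(orientations)
    if len(thetas) < 2:
        raise ValueError("Gabor bank requires at least 2 orientations")
    if any(w < 2.0 for w in wavelengths):
        raise ValueError("wavelengths below 2 px alias; use >= 2 px")

    v = image.values - image.values.mean()
    best = np.zeros(v.shape, dtype=float)
    best_theta = np.zeros(v.shape, dtype=float)
    for theta in thetas:
        for lam in wavelengths:
            # bank angles are fiber directions CCW from +x with y up; the
            # kernel's carrier must run normal to the fiber, and the
            # kernel grid has the row axis pointing down: theta_k = pi/2 - a
            k = gabor_kernel(frequency=1.0 / lam, theta=np.pi / 2 - theta)
            resp = np.abs(signal.fftconvolve(v, k, mode="same"))
            better = resp > best
            best[better] = resp[better]
            best_theta[better] = theta % np.pi
    enhanced = FiberImage(best, pixel_size=image.pixel_size)
    if return_orientation:
        return enhanced, best_theta
    return enhanced


# ---------------------------------------------------------------------------
# Skeleton graph extraction
# ---------------------------------------------------------------------------

_NBR = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _step(a: tuple[int, int], b: tuple[int, int]) -> float:
    return SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0


def _deletable(patch: np.ndarray) -> bool:
    """Center pixel of a 3x3 foreground patch is simple (safe to delete)."""
    nbrs = patch.copy()
    nbrs[1, 1] = False
    if nbrs.sum() < 3:
        return False  # would create/extend an endpoint
    labeled, n = ndimage.label(nbrs, structure=np.ones((3, 3), int))
    return n == 1


def _remove_blocks(skel: np.ndarray) -> np.ndarray:
    """Delete simple pixels until no 2x2 foreground block remains.

    Thinning occasionally leaves 2x2 staircase blocks; removing one
    simple pixel per block restores a strictly 1-px-wide skeleton
    without changing connectivity.
    """
    skel = skel.copy()
    for _ in range(8):  # blocks are sparse; a few sweeps suffice
        blocks = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
        if not blocks.any():
            break
        progress = False
        for r, c in zip(*np.nonzero(blocks)):
            if not (skel[r, c] and skel[r + 1, c] and skel[r, c + 1] and skel[r + 1, c + 1]):
                continue  # already resolved by an earlier deletion
            for pr, pc in ((r, c), (r + 1, c + 1), (r, c + 1), (r + 1, c)):
                if 1 <= pr < skel.shape[0] - 1 and 1 <= pc < skel.shape[1] - 1:
                    patch = skel[pr - 1:pr + 2, pc - 1:pc + 2]
                    if _deletable(patch):
                        skel[pr, pc] = False
                        progress = True
                        break
        if not progress:
            break
    return skel


def extract_skeleton_graph(
    enhanced: FiberImage,
    threshold: float | None = None,
    min_spur: float = 5.0,
    merge_radius: float = 3.0,
) -> FiberGraph:
    """Binarize, thin to a 1-px skeleton, and trace the fiber graph.

    Parameters
    ----------
    threshold : float, optional
        Absolute binarization threshold; Otsu's threshold when omitted.
    min_spur : float
        Skeleton spurs (edges ending in an endpoint) shorter than this
        are pruned once -- a minimal stand-in for heavier fiber
        post-processing.
    merge_radius : float
        Crosslink nodes joined by a path shorter than this are merged
        into one junction (rasterized junctions often split into nearby
        skeleton branch points).

    An empty skeleton yields an empty graph (not an error).
    """
    v = enhanced.values
    if threshold is None:
        if np.ptp(v) == 0:
            return FiberGraph(nx.MultiGraph(), "skeleton")
        threshold = threshold_otsu(v)
    binary = v > threshold
    skel = _remove_blocks(skeletonize(binary))
    if not skel.any():
        return FiberGraph(nx.MultiGraph(), "skeleton")

    nbr_count = ndimage.convolve(
        skel.astype(np.uint8), np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]]),
        mode="constant",
    )
    nbr_count[~skel] = 0
    node_mask = skel & (nbr_count != 2)
    # drop isolated single pixels (degree 0): no fiber attached
    iso = skel & (nbr_count == 0)
    node_mask &= ~iso
    skel_work = skel & ~iso

    node_labels, n_node_comp = ndimage.label(node_mask, structure=np.ones((3, 3), int))

    g = nx.MultiGraph()
    if n_node_comp == 0:
        return FiberGraph(g, "skeleton")  # pure cycles only; ignored

    centroids = ndimage.center_of_mass(node_mask, node_labels, np.arange(1, n_node_comp + 1))
    max_nbrs = ndimage.maximum(nbr_count, node_labels, np.arange(1, n_node_comp + 1))
    for nid in range(1, n_node_comp + 1):
        r, c = centroids[nid - 1]
        role = "crosslink" if max_nbrs[nid - 1] >= 3 else "endpoint"
        g.add_node(nid, pos=(float(r), float(c)), role=role)

    skel_set = set(zip(*np.nonzero(skel_work)))
    node_of = {}
    for r, c in zip(*np.nonzero(node_mask)):
        node_of[(r, c)] = int(node_labels[r, c])

    def _end_offset(nid, pixel):
        # junction clusters are represented by their centroid: include the
        # centroid-to-path-end distance so edge lengths stay consistent
        pr, pc = g.nodes[nid]["pos"]
        return float(np.hypot(pr - pixel[0], pc - pixel[1]))

    visited_chain: set[tuple[int, int]] = set()
    seen_direct = set()

    def neighbors(p):
        return [
            (p[0] + dr, p[1] + dc)
            for dr, dc in _NBR
            if (p[0] + dr, p[1] + dc) in skel_set
        ]

    for start in sorted(node_of):
        sid = node_of[start]
        for nb in neighbors(start):
            if nb in node_of:
                # direct node-pixel adjacency between different junctions
                tid = node_of[nb]
                if tid != sid:
                    key = (min(start, nb), max(start, nb))
                    if key not in seen_direct:
                        seen_direct.add(key)
                        length = (_step(start, nb) + _end_offset(sid, start)
                                  + _end_offset(tid, nb))
                        g.add_edge(sid, tid, length=length,
                                   path=np.array([start, nb]))
                continue
            if nb in visited_chain:
                continue
            # walk the degree-2 chain until another node pixel is reached
            path = [start, nb]
            length = _step(start, nb)
            prev, cur = start, nb
            while cur not in node_of:
                visited_chain.add(cur)
                cands = [q for q in neighbors(cur) if q != prev and q not in visited_chain]
                if not cands:
                    break  # dangling chain end (no node pixel); drop
                # prefer ending on a different junction over stepping back
                # onto the starting one through a tight corner
                node_c = [q for q in cands if q in node_of and node_of[q] != sid]
                chain_c = [q for q in cands if q not in node_of]
                nxt = node_c[0] if node_c else (chain_c[0] if chain_c else cands[0])
                length += _step(cur, nxt)
                path.append(nxt)
                prev, cur = cur, nxt
            if cur in node_of:
                tid = node_of[cur]
                if tid == sid:
                    continue  # self-loop (skeleton cycle back to one node): drop
                length += _end_offset(sid, start) + _end_offset(tid, cur)
                g.add_edge(sid, tid, length=float(length), path=np.array(path))

    _prune_spurs(g, min_spur)
    _merge_close_crosslinks(g, merge_radius)
    # node merging moves centroids; restore length >= chord for every edge
    for u, v, key, d in g.edges(keys=True, data=True):
        pu, pv = g.nodes[u]["pos"], g.nodes[v]["pos"]
        chord = float(np.hypot(pu[0] - pv[0], pu[1] - pv[1]))
        if d["length"] < chord:
            d["length"] = chord
    return FiberGraph(g, "skeleton")


def _prune_spurs(g: nx.MultiGraph, min_spur: float) -> None:
    """Remove endpoint-terminated edges shorter than ``min_spur``."""
    to_drop = []
    for u, v, key, d in g.edges(keys=True, data=True):
        if d["length"] >= min_spur:
            continue
        if (g.degree(u) == 1 and g.nodes[u]["role"] == "endpoint") or (
            g.degree(v) == 1 and g.nodes[v]["role"] == "endpoint"
        ):
            to_drop.append((u, v, key))
    g.remove_edges_from(to_drop)
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])


def _merge_close_crosslinks(g: nx.MultiGraph, radius: float) -> None:
    """Contract crosslink-crosslink edges shorter than ``radius``."""
    changed = True
    while changed:
        changed = False
        for u, v, key, d in list(g.edges(keys=True, data=True)):
            if u == v or d["length"] >= radius:
                continue
            if g.nodes[u]["role"] == "crosslink" and g.nodes[v]["role"] == "crosslink":
                pu, pv = g.nodes[u]["pos"], g.nodes[v]["pos"]
                g.nodes[u]["pos"] = ((pu[0] + pv[0]) / 2, (pu[1] + pv[1]) / 2)
                nx.contracted_nodes(g, u, v, self_loops=False, copy=False)
                changed = True
                break


def simplify_graph(skeleton_graph: FiberGraph) -> FiberGraph:
    """Replace each skeleton edge by the straight chord between its nodes.

    Keeps the full node set; edge length becomes the Euclidean distance
    between the node coordinates (always <= the geodesic length).
    Parallel skeleton fibers between the same node pair collapse onto
    the same chord.
    """
    if skeleton_graph.variant != "skeleton":
        raise ValueError("simplify_graph expects a skeleton-variant graph")
    src = skeleton_graph.graph
    out = nx.MultiGraph()
    for n, d in src.nodes(data=True):
        out.add_node(n, **d)
    seen = set()
    for u, v in src.edges():
        if u == v or (min(u, v), max(u, v)) in seen:
            continue
        seen.add((min(u, v), max(u, v)))
        pu, pv = src.nodes[u]["pos"], src.nodes[v]["pos"]
        chord = float(np.hypot(pu[0] - pv[0], pu[1] - pv[1]))
        out.add_edge(u, v, length=chord)
    return FiberGraph(out, "simplified")
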
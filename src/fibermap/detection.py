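"""Multi-threshold cluster extraction and anomaly testing against a GRF model.

A test map (gaussianized) is binarized at each configured threshold;
8-connected components of the excursion set are the *clusters*.  Each
cluster is assigned two null probabilities under the learned reference
GRF model -- one from its intensity peak, one from its spatial extent --
and flagged significant when a probability falls at or below the
per-cluster p-value (0.05 by default).  Three selection criteria are
supported:

* ``intensity`` -- clusters whose peak probability is significant,
* ``surface``   -- clusters whose extent probability is significant,
* ``joint``     -- surface-significant clusters (at one threshold) that
  share at least one pixel with an intensity-significant cluster (at a
  second, typically higher, threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grf import GRFModel, ParametricMap, p_intensity, p_surface

__all__ = [
    "ClusterRecord",
    "DetectionConfig",
    "DetectionResult",
    "find_clusters",
    "test_clusters",
    "detect",
    "summarize",
    "format_summary",
]

_EIGHT = np.ones((3, 3), dtype=int)

CRITERIA = ("intensity", "surface", "joint")


@dataclass
class ClusterRecord:
    """A connected suprathreshold component and its GRF membership test."""

    label: int
    pixels: np.ndarray          # (n, 2) array of (row, col) coordinates
    extent_s: int               # pixel count |pixels|
    peak_x: float               # maximum intensity inside the cluster
    threshold_t: float          # threshold the cluster was formed at
    p_intensity: float | None = None
    p_surface: float | None = None
    intensity_sig: bool = False
    surface_sig: bool = False

    def __post_init__(self) -> None:
        if self.extent_s < 1:
            raise ValueError("a cluster has at least one pixel")
        if self.peak_x < self.threshold_t:
            raise ValueError("cluster peak cannot lie below its threshold")


@dataclass
class DetectionConfig:
    """Thresholds, significance level and selection rule for detection.

    ``thresholds`` are in map units (after gaussianization, map units are
    those of the reference model's sigma) and must be strictly
    increasing.  For the joint criterion, ``joint_surface_threshold`` /
    ``joint_intensity_threshold`` name the two thresholds to pair; they
    default to the lowest and highest configured threshold.
    """

    thresholds: tuple[float, ...]
    pval: float = 0.05
    criterion: str = "joint"
    joint_surface_threshold: float | None = None
    joint_intensity_threshold: float | None = None

    def __post_init__(self) -> None:
        self.thresholds = tuple(float(t) for t in self.thresholds)
        if len(self.thresholds) == 0:
            raise ValueError("at least one threshold is required")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if not 0.0 < self.pval < 1.0:
            raise ValueError("pval must lie strictly between 0 and 1")
        if self.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")
        if self.criterion == "joint":
            if self.joint_surface_threshold is None:
                self.joint_surface_threshold = self.thresholds[0]
            if self.joint_intensity_threshold is None:
                self.joint_intensity_threshold = self.thresholds[-1]
            for t in (self.joint_surface_threshold, self.joint_intensity_threshold):
                if t not in self.thresholds:
                    raise ValueError(
                        "joint thresholds must be among the configured thresholds"
                    )


@dataclass
class DetectionResult:
    """Per-threshold cluster records plus the final selected-region mask."""

    clusters: dict[float, list[ClusterRecord]]
    selected_regions: np.ndarray    # bool mask of significant selections
    criterion: str
    pval: float
    summary: dict = field(default_factory=dict)

    def significant(self, t: float, criterion: str | None = None) -> list[ClusterRecord]:
        crit = criterion or self.criterion
        recs = self.clusters[t]
        if crit == "intensity":
            return [c for c in recs if c.intensity_sig]
        if crit == "surface":
            return [c for c in recs if c.surface_sig]
        raise ValueError("per-threshold significance is intensity or surface")


def find_clusters(pmap: ParametricMap, t: float) -> list[ClusterRecord]:
    """8-connected components of ``{pixel : value >= t}``.

    Single-pixel components are kept.  Returns an empty list when no
    pixel reaches the threshold.
    """
    v = pmap.values
    mask = v >= t
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return []
    flat = labels.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_labels = flat[order]
    # positions of each label run in the sorted flat index array
    boundaries = np.searchsorted(sorted_labels, np.arange(1, n + 2))
    peaks = ndimage.maximum(v, labels=labels, index=np.arange(1, n + 1))
    h, w = v.shape
    records = []
    for lab in range(1, n + 1):
        idx = order[boundaries[lab - 1]:boundaries[lab]]
        coords = np.column_stack(np.unravel_index(idx, (h, w)))
        records.append(
            ClusterRecord(
                label=lab,
                pixels=coords,
                extent_s=len(idx),
                peak_x=float(peaks[lab - 1]),
                threshold_t=float(t),
            )
        )
    return records


def test_clusters(
    clusters: list[ClusterRecord],
    model: GRFModel,
    t: float,
    pval: float = 0.05,
) -> list[ClusterRecord]:
    """Attach both GRF membership probabilities and significance flags.

    The null hypothesis is that a cluster belongs to a realization of
    the reference GRF; it is rejected for a cluster when either
    probability is at or below ``pval``.
    """
    if not isinstance(model, GRFModel):
        raise TypeError("a learned GRFModel is required")
    for c in clusters:
        c.p_intensity = p_intensity(model, t, max(c.peak_x, t))
        c.p_surface = p_surface(model, t, c.extent_s)
        c.intensity_sig = c.p_intensity <= pval
        c.surface_sig = c.p_surface <= pval
    return clusters


def _union_mask(shape: tuple[int, int], records: list[ClusterRecord]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for c in records:
        mask[c.pixels[:, 0], c.pixels[:, 1]] = True
    return mask


def detect(pmap: ParametricMap, model: GRFModel, config: DetectionConfig) -> DetectionResult:
    """Run cluster extraction + GRF tests at every configured threshold.

    Thresholds below the model sigma are outside the large-threshold
    regime of the cluster-count formula; they are dropped with a warning.
    For the joint criterion the selected regions are the
    surface-significant clusters at ``joint_surface_threshold`` having a
    non-null (>= 1 pixel) intersection with intensity-significant
    clusters at ``joint_intensity_threshold``.
    """
    usable = []
    for t in config.thresholds:
        if t < model.sigma:
            warnings.warn(
                f"threshold {t} below model sigma {model.sigma:.4g} rejected "
                "(outside the large-threshold regime)",
                stacklevel=2,
            )
        else:
            usable.append(t)
    if not usable:
        raise ValueError("no usable threshold at or above the model sigma")
    if config.criterion == "joint":
        for t in (config.joint_surface_threshold, config.joint_intensity_threshold):
            if t not in usable:
                raise ValueError("joint thresholds were rejected (below model sigma)")

    clusters: dict[float, list[ClusterRecord]] = {}
    for t in usable:
        clusters[t] = test_clusters(find_clusters(pmap, t), model, t, config.pval)

    shape = pmap.shape
    if config.criterion == "intensity":
        selected = _union_mask(shape, [c for t in usable for c in clusters[t] if c.intensity_sig])
    elif config.criterion == "surface":
        selected = _union_mask(shape, [c for t in usable for c in clusters[t] if c.surface_sig])
    else:
        ts = config.joint_surface_threshold
        ti = config.joint_intensity_threshold
        int_mask = _union_mask(shape, [c for c in clusters[ti] if c.intensity_sig])
        keep = [
            c
            for c in clusters[ts]
            if c.surface_sig and int_mask[c.pixels[:, 0], c.pixels[:, 1]].any()
        ]
        selected = _union_mask(shape, keep)

    n_sig = {
        t: sum(c.intensity_sig or c.surface_sig for c in clusters[t]) for t in usable
    }
    result = DetectionResult(
        clusters=clusters,
        selected_regions=selected,
        criterion=config.criterion,
        pval=config.pval,
        summary={"n_significant": n_sig},
    )
    return result


def summarize(results: list[DetectionResult]) -> pd.DataFrame:
    """Per-threshold, per-criterion group summary over a set of images.

    Reports the mean number of significant clusters per image and the
    mean significant-cluster area per image.  The area is NaN when no
    significant detection is present in the whole group (rendered as an
    em-dash by :func:`format_summary`).
    """
    if len(results) == 0:
        raise ValueError("summarize requires at least one detection result")
    thresholds = sorted({t for r in results for t in r.clusters})
    rows = []
    for t in thresholds:
        for crit in ("intensity", "surface"):
            counts, areas = [], []
            for r in results:
                sig = r.significant(t, crit) if t in r.clusters else []
                counts.append(len(sig))
                areas.extend(c.extent_s for c in sig)
            rows.append(
                {
                    "threshold": t,
                    "criterion": crit,
                    "mean_clusters_per_image": float(np.mean(counts)),
                    "mean_cluster_area": float(np.mean(areas)) if areas else np.nan,
                    "n_images": len(results),
                }
            )
    return pd.DataFrame(rows)


def format_summary(table: pd.DataFrame) -> str:
    """Render a summary table, writing an em-dash where no detection exists."""
    shown = table.copy()
    shown["mean_cluster_area"] = [
        "—" if np.isnan(a) else f"{a:.1f}" for a in shown["mean_cluster_area"]
    ]
    return shown.to_string(index=False)
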
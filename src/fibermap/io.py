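"""Readers and writers for maps, models, graphs and cluster tables.

Maps travel as 32-bit float TIFF (lossless) or as 16-bit PNG with a JSON
sidecar recording the linear scale; models and provenance as JSON;
graphs and cluster records as CSV tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .detection import ClusterRecord
from .fiber_graph import FiberGraph
from .grf import GRFModel, ParametricMap

__all__ = [
    "write_map_tiff",
    "read_map_tiff",
    "write_map_png16",
    "read_map_png16",
    "write_mask_png",
    "read_mask_png",
    "save_model",
    "load_model",
    "clusters_to_csv",
    "graph_to_csvs",
    "write_overlay_png",
]


def write_map_tiff(pmap: ParametricMap, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, pmap.values.astype(np.float32))
    meta = {"pixel_size_um": pmap.pixel_size}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_map_tiff(path: str | Path) -> ParametricMap:
    path = Path(path)
    values = tifffile.imread(path).astype(float)
    pixel_size = None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        pixel_size = json.loads(sidecar.read_text()).get("pixel_size_um")
    return ParametricMap(values, pixel_size=pixel_size)


def write_map_png16(pmap: ParametricMap, path: str | Path) -> None:
    """16-bit PNG with a JSON sidecar holding the affine intensity scale."""
    path = Path(path)
    v = pmap.values
    lo, hi = float(v.min()), float(v.max())
    span = hi - lo if hi > lo else 1.0
    q = np.round((v - lo) / span * 65535.0).astype(np.uint16)
    Image.fromarray(q).save(path)
    meta = {"offset": lo, "scale": span / 65535.0, "pixel_size_um": pmap.pixel_size}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_map_png16(path: str | Path) -> ParametricMap:
    path = Path(path)
    q = np.asarray(Image.open(path), dtype=float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ParametricMap(q * meta["scale"] + meta["offset"],
                         pixel_size=meta.get("pixel_size_um"))


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray((np.asarray(mask).astype(np.uint8)) * 255, mode="L").save(path)


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path)) > 127


def save_model(model: GRFModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "lambda_det": model.lambda_det,
        "sigma": model.sigma,
        "n_pixels": model.n_pixels,
        "n_training_maps": model.n_training_maps,
    }, indent=2))


def load_model(path: str | Path) -> GRFModel:
    d = json.loads(Path(path).read_text())
    return GRFModel(**d)


def clusters_to_csv(clusters_by_threshold: dict, path: str | Path) -> pd.DataFrame:
    """Flatten per-threshold ClusterRecords into one CSV table."""
    rows = []
    for t, records in sorted(clusters_by_threshold.items()):
        for c in records:
            rows.append({
                "threshold": t,
                "label": c.label,
                "extent_s": c.extent_s,
                "peak_x": c.peak_x,
                "p_intensity": c.p_intensity,
                "p_surface": c.p_surface,
                "intensity_sig": c.intensity_sig,
                "surface_sig": c.surface_sig,
            })
    df = pd.DataFrame(rows, columns=["threshold", "label", "extent_s", "peak_x",
                                     "p_intensity", "p_surface",
                                     "intensity_sig", "surface_sig"])
    df.to_csv(path, index=False)
    return df


def graph_to_csvs(graph: FiberGraph, node_path: str | Path, edge_path: str | Path) -> None:
    nodes = [
        {"node": n, "row": d["pos"][0], "col": d["pos"][1], "role": d["role"]}
        for n, d in graph.graph.nodes(data=True)
    ]
    edges = [
        {"u": u, "v": v, "length": d["length"], "variant": graph.variant}
        for u, v, d in graph.graph.edges(data=True)
    ]
    pd.DataFrame(nodes, columns=["node", "row", "col", "role"]).to_csv(node_path, index=False)
    pd.DataFrame(edges, columns=["u", "v", "length", "variant"]).to_csv(edge_path, index=False)


def write_overlay_png(base: np.ndarray, mask: np.ndarray, path: str | Path) -> None:
    """Grayscale base with selected regions painted red, for visual QC."""
    b = np.asarray(base, dtype=float)
    span = np.ptp(b) or 1.0
    g = ((b - b.min()) / span * 255).astype(np.uint8)
    rgb = np.stack([g, g, g], axis=-1)
    rgb[np.asarray(mask, dtype=bool)] = (255, 40, 40)
    Image.fromarray(rgb, mode="RGB").save(path)
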
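"""File I/O: TIFF heatmaps with JSON sidecars, RLE mask JSON, ASCII PLY
meshes, and CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import trimesh

from .heatmap import HeatMap, SamplingBox

__all__ = [
    "write_heatmap", "read_heatmap",
    "write_mask_rle", "read_mask_rle",
    "write_mesh_ply", "read_mesh_ply",
]


def write_heatmap(path, heatmap: HeatMap, box_id: str = "",
                  sidecar: dict | None = None) -> None:
    """Write a heatmap as float32 single-channel TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, heatmap.values.astype(np.float32))
    meta = {"pixel_size_um": heatmap.pixel_size_um,
            "class": heatmap.inclusion_class, "box_id": box_id}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_heatmap(path) -> tuple[HeatMap, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    values = tifffile.imread(path).astype(float)
    return HeatMap(values=values, pixel_size_um=meta["pixel_size_um"],
                   inclusion_class=meta["class"]), meta


def write_mask_rle(path, box: SamplingBox) -> None:
    """Run-length-encoded sampling-box mask as JSON (row-major runs)."""
    flat = box.mask.ravel().astype(np.int8)
    change = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [flat.size]]))
    Path(path).write_text(json.dumps({
        "box_id": box.box_id, "slide_id": box.slide_id,
        "anatomical_label": box.anatomical_label,
        "pixel_size_um": box.pixel_size_um,
        "shape": list(box.mask.shape),
        "first_value": int(flat[0]),
        "run_lengths": [int(x) for x in lengths],
    }))


def read_mask_rle(path) -> SamplingBox:
    meta = json.loads(Path(path).read_text())
    vals, val = [], bool(meta["first_value"])
    for run in meta["run_lengths"]:
        vals.append(np.full(run, val, dtype=bool))
        val = not val
    mask = np.concatenate(vals).reshape(meta["shape"])
    return SamplingBox(box_id=meta["box_id"], slide_id=meta["slide_id"],
                       anatomical_label=meta["anatomical_label"], mask=mask,
                       pixel_size_um=meta["pixel_size_um"])


def write_mesh_ply(path, vertices: np.ndarray, triangles: np.ndarray,
                   vertex_scalars: dict | None = None) -> None:
    """ASCII PLY mesh, with optional per-vertex scalar attributes."""
    mesh = trimesh.Trimesh(vertices=vertices, faces=triangles, process=False)
    if vertex_scalars:
        for name, values in vertex_scalars.items():
            mesh.vertex_attributes[name] = np.asarray(values, dtype=float)
    Path(path).write_bytes(trimesh.exchange.ply.export_ply(
        mesh, encoding="ascii", include_attributes=True))


def read_mesh_ply(path) -> tuple[np.ndarray, np.ndarray]:
    mesh = trimesh.load(Path(path), file_type="ply", process=False)
    return np.asarray(mesh.vertices), np.asarray(mesh.faces)
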
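"""Image/table/checkpoint plumbing shared by the CLI and the library."""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

import endoseg

__all__ = [
    "read_gray_image",
    "write_gray_image",
    "read_probability_map",
    "write_probability_map",
    "write_label_image",
    "write_overlay",
    "save_checkpoint",
    "load_checkpoint",
    "write_provenance",
    "biomarker_row",
]


def read_gray_image(path) -> np.ndarray:
    """8-bit grayscale image -> float array in [0, 1]."""
    arr = np.asarray(Image.open(path).convert("L"), dtype=float)
    return arr / 255.0


def write_gray_image(img: np.ndarray, path) -> None:
    arr = np.clip(np.asarray(img, dtype=float), 0, 1)
    Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(path)


def read_probability_map(path) -> np.ndarray:
    """Probability map from float TIFF or 8-bit PNG (value/255)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path).astype(float)
        return np.clip(arr, 0.0, 1.0)
    return read_gray_image(path)


def write_probability_map(prob: np.ndarray, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(prob, np.float32))
    else:
        write_gray_image(prob, path)


def write_label_image(labels: np.ndarray, path) -> None:
    """16-bit label PNG (0 = ridge)."""
    Image.fromarray(np.asarray(labels, np.uint16)).save(path)


def write_overlay(image: np.ndarray, graph, path) -> None:
    """RGB overlay: edges red, vertices yellow, selected cells green tint,
    unselected/non-ROI blue tint."""
    base = np.clip(np.asarray(image, dtype=float), 0, 1)
    rgb = np.stack([base, base, base], axis=-1)
    labels = graph.labels
    if graph.regions is not None:
        sel = np.zeros(int(labels.max()) + 1, bool)
        sel[graph.regions.index[graph.regions["selected"]]] = True
        green = sel[labels] & (labels > 0)
        blue = ~sel[labels] & (labels > 0)
        rgb[green] = 0.6 * rgb[green] + 0.4 * np.array([0.0, 1.0, 0.0])
        rgb[blue] = 0.7 * rgb[blue] + 0.3 * np.array([0.0, 0.3, 1.0])
    ridge = labels == 0
    rgb[ridge] = [1.0, 0.0, 0.0]
    for pix in graph.vertex_pixels.values():
        rgb[pix[:, 0], pix[:, 1]] = [1.0, 1.0, 0.0]
    Image.fromarray(np.round(rgb * 255).astype(np.uint8), mode="RGB").save(path)


def save_checkpoint(net, config, path) -> None:
    """Network weights + its NetworkConfig in one .npz file."""
    arrays = net.state_arrays()
    arrays["__config__"] = np.frombuffer(config.to_json().encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path):
    from endoseg.nn import Network, NetworkConfig, build_network

    data = np.load(path)
    cfg = NetworkConfig.from_json(bytes(data["__config__"]).decode())
    net = Network(build_network(cfg), seed=0)
    for full in data.files:
        if full == "__config__":
            continue
        arr = data[full]
        if "::stat::" in full:
            name, key = full.split("::stat::")
            net.stats[name][key] = arr
        else:
            name, key = full.split("::")
            net.params[name][key] = arr.astype(np.float32)
    return net, cfg


def write_provenance(path, command: str, config: dict, seeds: dict) -> None:
    record = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "versions": {
            "endoseg": endoseg.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str))


def biomarker_row(image_id: str, bm, cfg) -> dict:
    """One CSV row of biomarker estimates (absent values stay empty)."""
    return {
        "image": image_id,
        "n_cells": bm.n_cells,
        "ecd_cells_per_mm2": "" if bm.ecd is None else round(bm.ecd, 2),
        "cv_pct": "" if bm.cv is None else round(bm.cv, 2),
        "hex_pct": "" if bm.hex is None else round(bm.hex, 2),
        "hex_method": bm.hex_method,
        "edge_threshold": cfg.edge_threshold,
        "body_threshold": cfg.body_threshold,
    }
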
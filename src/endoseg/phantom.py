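"""Synthetic endothelium phantoms with known ground truth.

A phantom emulates a specular-microscopy view of the corneal endothelium: a
cell tessellation (bright cell bodies separated by dark 1-px edge curves),
optional guttae (near-black discs occluding cells), a spatially varying
blur, and additive noise.  Each phantom carries its generating tessellation,
so the true biomarkers (cell count, ECD, CV, HEX) are known exactly and any
segmentation pipeline can be scored against them.

Geometry model: cell nuclei sit on a hexagonal lattice whose positions are
jittered by ``1 - regularity``; cell areas follow a lognormal law whose
sigma controls the coefficient of variation (for a lognormal, CV^2 =
exp(sigma^2) - 1).  The tessellation is the power diagram (additively
weighted Voronoi) of the nuclei, with weights calibrated by a capacity
iteration so that realized cell areas track the lognormal draws.  Guttae
are discs; a gutta larger than the mean cell diameter occludes the
tessellation irrecoverably and is marked as discard area in the annotation,
while smaller guttae keep their edges annotated (as a human annotator would
infer them from the surroundings).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.segmentation import watershed

from endoseg.annotations import Annotation, ComplexityGrade, grade_complexity
from endoseg.biomarkers import DEFAULT_PIXEL_SIZE_MM, BiomarkerSet, CellRecord, estimate_biomarkers

__all__ = ["PhantomConfig", "PhantomSample", "generate_phantom", "generate_dataset"]


@dataclass(frozen=True)
class PhantomConfig:
    """Generator knobs; defaults model a typical specular image."""

    shape: tuple = (240, 528)
    mean_cell_diameter: float = 22.0   # px; ~380 px^2 cells, ECD ~ 2400 cells/mm^2
    area_sigma: float = 0.25           # lognormal sigma of cell areas (CV ~ 25%)
    regularity: float = 0.3            # 0 = fully jittered nuclei, 1 = hexagonal lattice
    guttae_count: int = 0
    guttae_radius_mean: float = 10.0   # px
    guttae_radius_sigma: float = 0.35  # lognormal sigma of radii
    guttae_confluence: float = 0.3     # probability a gutta attaches to an existing one
    blur_strength: float = 0.0         # 0..1 mixing weight of the blurred image
    blur_max_sigma: float = 3.0        # px
    noise_sd: float = 0.0
    edge_intensity: float = 0.20
    gutta_intensity: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_cell_diameter < 3:
            raise ValueError("cells smaller than 3 px are not resolvable")
        for name in ("area_sigma", "guttae_radius_mean", "blur_strength", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.regularity <= 1):
            raise ValueError("regularity must be in [0, 1]")


@dataclass
class PhantomSample:
    """One phantom: image, annotation, and the generating ground truth."""

    image: np.ndarray                  # float in [0, 1]
    annotation: Annotation
    label_image: np.ndarray            # generating tessellation (0 = edge lines)
    cells: list                        # CellRecord of the countable (truth) cells
    biomarkers: BiomarkerSet           # truth biomarkers of those cells
    guttae_score: int = 1
    blur_score: int = 1
    config: PhantomConfig | None = None

    @property
    def grade(self) -> ComplexityGrade:
        return grade_complexity(self.guttae_score, self.blur_score)

    def truth_json(self) -> str:
        return json.dumps(
            {
                "n_cells": self.biomarkers.n_cells,
                "ecd": self.biomarkers.ecd,
                "cv": self.biomarkers.cv,
                "hex": self.biomarkers.hex,
                "guttae_score": self.guttae_score,
                "blur_score": self.blur_score,
                "cells": [
                    {"id": c.id, "area_px": c.area_px, "vertex_count": c.vertex_count,
                     "neighbor_count": c.neighbor_count, "is_inner": c.is_inner}
                    for c in self.cells
                ],
            },
            indent=1,
        )


def _lattice_constant(cfg: PhantomConfig) -> float:
    mean_area = np.pi * (cfg.mean_cell_diameter / 2.0) ** 2
    return float(np.sqrt(2.0 * mean_area / np.sqrt(3.0)))


def _hex_seeds(cfg: PhantomConfig, rng) -> np.ndarray:
    """Jittered hexagonal nuclei covering the image with one-cell margin."""
    h, w = cfg.shape
    a = _lattice_constant(cfg)
    dy = a * np.sqrt(3.0) / 2.0
    rows = np.arange(-a, h + a, dy)
    pts = []
    for i, y in enumerate(rows):
        xs = np.arange(-a + (a / 2.0 if i % 2 else 0.0), w + a, a)
        pts.append(np.stack([np.full_like(xs, y), xs], axis=1))
    seeds = np.concatenate(pts)
    jitter_sd = (1.0 - cfg.regularity) * 0.18 * a
    if jitter_sd > 0:
        seeds = seeds + rng.normal(0.0, jitter_sd, seeds.shape)
    return seeds


def _pad_width(cfg: PhantomConfig) -> int:
    """Canvas padding so that every margin nucleus lies inside the canvas."""
    return int(np.ceil(_lattice_constant(cfg))) + 2


def _power_labels(cfg: PhantomConfig, seeds: np.ndarray, rng) -> np.ndarray:
    """Per-pixel nucleus assignment from a capacity-calibrated power diagram.

    Additive weights are iterated so that each interior cell's pixel area
    tracks its lognormal target (a discrete capacity-constrained power
    diagram).  Seeds whose unweighted cell touches the border, or which lie
    in the margin outside the image, are exempt — their areas are truncated
    by the frame and cannot meet a capacity.
    """
    h, w = cfg.shape
    pad = _pad_width(cfg)
    hp, wp = h + 2 * pad, w + 2 * pad
    n = len(seeds)
    pseeds = seeds + pad
    yy, xx = np.meshgrid(np.arange(hp, dtype=float), np.arange(wp, dtype=float), indexing="ij")
    grid = np.stack([yy.ravel(), xx.ravel()], axis=1)
    tree = cKDTree(pseeds)
    k = min(16, n)
    d2, idx = tree.query(grid, k=k)
    d2 = (d2**2).astype(np.float32)
    rows = np.arange(len(grid))
    assign = idx[rows, np.argmin(d2, axis=1)]
    if cfg.area_sigma == 0:
        return assign.reshape(hp, wp), np.zeros(n, np.float32)
    mean_area = np.pi * (cfg.mean_cell_diameter / 2.0) ** 2
    # lognormal law for the *measured* cell areas; rasterization later takes
    # a 1-px boundary share from each cell (empirically ~ 17 + 0.78 sqrt(A)
    # pixels for this line convention), which the capacity target compensates
    measured = mean_area * rng.lognormal(-cfg.area_sigma**2 / 2.0, cfg.area_sigma, n)
    target = measured + 16.9 + 0.78 * np.sqrt(measured + 17.0)
    lab0 = assign.reshape(hp, wp)
    border = np.unique(np.concatenate([lab0[0], lab0[-1], lab0[:, 0], lab0[:, -1]]))
    areas0 = np.bincount(assign, minlength=n)
    free = np.ones(n, bool)
    free[border] = False
    free[areas0 == 0] = False
    weights = np.zeros(n, np.float32)
    for _ in range(80):
        assign = idx[rows, np.argmin(d2 - weights[idx], axis=1)]
        areas = np.bincount(assign, minlength=n).astype(float)
        weights[free] += (0.2 * (target - areas)).astype(np.float32)[free]
    return assign.reshape(hp, wp), weights


def _rasterize(cfg: PhantomConfig, assign: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Watershed-rasterize the tessellation: labels with 1-px 0-lines.

    Runs on a canvas padded by one lattice constant so that every cell —
    including those only partially inside the image — keeps its identity,
    then crops back to the image frame.  The flooded surface is the negative
    distance to the cell-assignment boundary with one marker at each
    region's interior maximum: the boundary band is then the global ridge,
    so the basins reproduce the capacity-calibrated cells exactly and the
    1-px line falls centrally between them.  (Flooding a distance-to-nucleus
    surface instead would mis-assign strongly weighted cells, whose nucleus
    can lie outside the cell.)
    """
    pad = _pad_width(cfg)
    hp, wp = assign.shape
    band = np.zeros((hp, wp), bool)
    band[:, 1:] |= assign[:, 1:] != assign[:, :-1]
    band[:, :-1] |= assign[:, 1:] != assign[:, :-1]
    band[1:, :] |= assign[1:, :] != assign[:-1, :]
    band[:-1, :] |= assign[1:, :] != assign[:-1, :]
    depth = ndimage.distance_transform_edt(~band)
    markers = np.zeros((hp, wp), np.int32)
    present = np.unique(assign)
    positions = ndimage.maximum_position(depth, labels=assign + 1,
                                         index=(present + 1).tolist())
    for lab_idx, (yi, xi) in zip(present, positions):
        markers[yi, xi] = int(lab_idx) + 1
    labels = watershed((-depth).astype(np.float32), markers,
                       connectivity=1, watershed_line=True)
    h, w = cfg.shape
    cropped = _thin_line_blocks(labels[pad:pad + h, pad:pad + w].copy())
    return cropped, labels


from endoseg.raster import thin_line_blocks as _thin_line_blocks


def _stamp_guttae(cfg: PhantomConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Return (all-guttae mask, large-guttae/discard mask)."""
    h, w = cfg.shape
    yy, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    all_mask = np.zeros(cfg.shape, bool)
    discard = np.zeros(cfg.shape, bool)
    centers: list[tuple[float, float, float]] = []
    for _ in range(cfg.guttae_count):
        r = float(rng.lognormal(np.log(cfg.guttae_radius_mean), cfg.guttae_radius_sigma))
        r = min(r, min(h, w) / 3.0)
        if centers and rng.random() < cfg.guttae_confluence:
            cy, cx, cr = centers[rng.integers(len(centers))]
            ang = rng.uniform(0, 2 * np.pi)
            dist = (cr + r) * rng.uniform(0.7, 1.1)
            y, x = cy + dist * np.sin(ang), cx + dist * np.cos(ang)
        else:
            y, x = rng.uniform(r, h - r), rng.uniform(r, w - r)
        y = float(np.clip(y, r, h - r))
        x = float(np.clip(x, r, w - r))
        disc = (yy - y) ** 2 + (xx - x) ** 2 <= r * r
        all_mask |= disc
        if 2 * r > cfg.mean_cell_diameter:
            discard |= disc
        centers.append((y, x, r))
    return all_mask, discard


def _render(cfg: PhantomConfig, labels: np.ndarray, guttae: np.ndarray, rng) -> np.ndarray:
    brightness = rng.uniform(0.55, 0.85, labels.max() + 1)
    img = brightness[labels]
    img[labels == 0] = cfg.edge_intensity
    img = ndimage.gaussian_filter(img, 0.7)
    img[guttae] = cfg.gutta_intensity
    img = ndimage.gaussian_filter(img, 0.4)
    if cfg.blur_strength > 0:
        field = ndimage.gaussian_filter(rng.normal(size=cfg.shape), 40.0)
        field -= field.min()
        if field.max() > 0:
            field /= field.max()
        t = cfg.blur_strength * field
        img = (1 - t) * img + t * ndimage.gaussian_filter(img, cfg.blur_max_sigma)
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, cfg.shape)
    return np.clip(img, 0.0, 1.0)


def region_adjacency(labels: np.ndarray) -> dict[int, set]:
    """Region adjacency: two regions are neighbors iff some 0-line pixel has
    both in its 8-neighborhood."""
    h, w = labels.shape
    lr, lc = np.nonzero(labels == 0)
    shifts = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    stack = np.zeros((len(lr), 8), labels.dtype)
    for s, (di, dj) in enumerate(shifts):
        r = np.clip(lr + di, 0, h - 1)
        c = np.clip(lc + dj, 0, w - 1)
        stack[:, s] = labels[r, c]
    neighbors: dict[int, set] = {}
    for i in range(8):
        for j in range(i + 1, 8):
            a, b = stack[:, i], stack[:, j]
            sel = (a > 0) & (b > 0) & (a != b)
            if not sel.any():
                continue
            pairs = np.unique(np.stack([np.minimum(a[sel], b[sel]),
                                        np.maximum(a[sel], b[sel])], axis=1), axis=0)
            for p, q in pairs:
                neighbors.setdefault(int(p), set()).add(int(q))
                neighbors.setdefault(int(q), set()).add(int(p))
    return neighbors


def _truth_cells(labels: np.ndarray, labels_padded: np.ndarray,
                 discard: np.ndarray) -> list[CellRecord]:
    """Ground-truth cell records from the generating tessellation.

    Countable cells lie strictly inside the frame (no pixel on the
    outermost ring) and do not overlap a discard (large-guttae) area.  For
    a generic tessellation the number of vertices of an interior cell
    equals its number of neighboring cells, so the truth vertex count is
    taken from the region adjacency — computed on the padded canvas, where
    also the neighbors that fall outside the image frame exist.
    """
    ids = np.unique(labels)
    ids = ids[ids > 0]
    border = set(np.unique(np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])).tolist())
    occluded = set(np.unique(labels[discard]).tolist()) if discard.any() else set()
    areas = np.bincount(labels.ravel(), minlength=labels.max() + 1)
    neighbors = region_adjacency(labels_padded)

    selected = [int(i) for i in ids if i not in border and i not in occluded]
    sel_set = set(selected)
    cells = []
    for i in selected:
        nb = neighbors.get(int(i), set())
        cells.append(CellRecord(
            id=int(i),
            area_px=float(areas[i]),
            vertex_count=len(nb),
            neighbor_count=len(nb),
            is_inner=nb <= sel_set and len(nb) > 0,
        ))
    return cells


def generate_phantom(cfg: PhantomConfig) -> PhantomSample:
    """Generate one phantom deterministically from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    seeds = _hex_seeds(cfg, rng)
    assign, _ = _power_labels(cfg, seeds, rng)
    labels, labels_padded = _rasterize(cfg, assign)

    guttae, discard = _stamp_guttae(cfg, rng)

    ann = np.zeros(cfg.shape, float)
    ann[labels == 0] = 1.0
    ann[discard] = 0.5                      # large guttae: edges not inferable
    annotation = Annotation(ann)

    image = _render(cfg, labels, guttae, rng)
    cells = _truth_cells(labels, labels_padded, discard)
    biomarkers = estimate_biomarkers(cells, DEFAULT_PIXEL_SIZE_MM, "vertex")
    return PhantomSample(
        image=image, annotation=annotation, label_image=labels,
        cells=cells, biomarkers=biomarkers, config=cfg,
    )


# ---------------------------------------------------------------- datasets

#: generator knobs per guttae severity score
_GUTTAE_LEVELS = {1: (4, 8.0), 2: (10, 11.0), 3: (20, 14.0)}   # (count, radius mean)
_BLUR_LEVELS = {1: 0.15, 2: 0.4, 3: 0.7}

#: (guttae_score, blur_score) choices per requested complexity bin
_BIN_SCORES = {
    "low": [(1, 1)],
    "medium": [(2, 1), (1, 2), (2, 2)],
    "high": [(3, 2), (2, 3), (3, 3)],
}


def generate_dataset(cfg: PhantomConfig, n: int, seed: int = 0,
                     bin_counts: dict | None = None,
                     images_per_eye: int = 3) -> tuple[list[PhantomSample], pd.DataFrame]:
    """Generate ``n`` phantoms with graded guttae/blur and an eye manifest.

    ``bin_counts`` maps {'none', 'low', 'medium', 'high'} to image counts
    (defaults to half clean and the rest split over the three guttae bins).
    Images are grouped into surrogate eyes of ``images_per_eye`` consecutive
    images, for eye-level fold experiments.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if bin_counts is None:
        clean = n // 2
        per = (n - clean) // 3
        bin_counts = {"none": n - 3 * per, "low": per, "medium": per, "high": per}
    if sum(bin_counts.values()) != n:
        raise ValueError("bin counts must sum to n")
    rng = np.random.default_rng(seed)
    samples, rows = [], []
    i = 0
    for b in ("none", "low", "medium", "high"):
        for _ in range(bin_counts.get(b, 0)):
            sample_seed = int(rng.integers(2**31))
            if b == "none":
                sub = replace(cfg, guttae_count=0, blur_strength=_BLUR_LEVELS[1],
                              seed=sample_seed)
                g_score, b_score = 1, 1
            else:
                g_score, b_score = _BIN_SCORES[b][rng.integers(len(_BIN_SCORES[b]))]
                count, radius = _GUTTAE_LEVELS[g_score]
                sub = replace(cfg, guttae_count=count, guttae_radius_mean=radius,
                              blur_strength=_BLUR_LEVELS[b_score], seed=sample_seed)
            s = generate_phantom(sub)
            s.guttae_score, s.blur_score = g_score, b_score
            samples.append(s)
            rows.append({
                "id": f"ph{i:04d}",
                "eye_id": f"eye{i // images_per_eye:03d}",
                "guttae_bin": b,
                "guttae_score": g_score,
                "blur_score": b_score,
                "grade": g_score + b_score,
                "n_cells": s.biomarkers.n_cells,
                "seed": sample_seed,
            })
            i += 1
    return samples, pd.DataFrame(rows)
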
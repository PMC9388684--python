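"""Trinary annotations and the four probabilistic training targets.

A manual annotation of a specular image is a trinary image: 0 marks cell
bodies, 1 marks cell edges (8-connected curves of 1-pixel width), and 0.5
marks areas to discard (extensive guttae, heavy blur, partial cells).  From
one annotation four training targets are derived:

``edge``
    The binary edge mask convolved with a 7x7 *unnormalized* isotropic
    Gaussian of SD 1 (peak value 1), clipped to [0, 1].  Annotated edge
    pixels therefore keep the value 1 exactly, and the target decays as
    ``exp(-(dr^2 + dc^2) / 2)`` away from isolated edge pixels.
``body``
    Only the *full* cell bodies — 0-regions that neither touch the image
    border nor lie adjacent to a discard area — transformed with the same
    Gaussian and clipped.
``blob``
    The full bodies united with the edges that separate two of them, then
    the same Gaussian transformation.
``roi``
    A binary map of the trustworthy region: the complement of the discard
    mask with the discarded partial cells removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "Annotation",
    "TargetImage",
    "ComplexityGrade",
    "MalformedAnnotationError",
    "ThickEdgeError",
    "load_annotation",
    "save_annotation",
    "make_target",
    "grade_complexity",
    "gaussian_kernel_7x7",
]

#: Pixel alphabet of an annotation file (8-bit) and its trinary meaning.
FILE_ALPHABET = {0: 0.0, 128: 0.5, 255: 1.0}

BODY, DISCARD, EDGE = 0.0, 0.5, 1.0


class MalformedAnnotationError(ValueError):
    """Annotation contains a pixel value outside the {0, 128, 255} alphabet."""


class ThickEdgeError(ValueError):
    """Annotation edges are not 1-pixel wide (a 2x2 all-edge block exists)."""


@dataclass(frozen=True)
class Annotation:
    """A validated trinary annotation image.

    Attributes
    ----------
    pixels:
        2-D float array with values in {0, 0.5, 1}.
    """

    pixels: np.ndarray

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise MalformedAnnotationError("annotation must be a 2-D image")
        if not np.isin(px, (BODY, DISCARD, EDGE)).all():
            bad = np.unique(px[~np.isin(px, (BODY, DISCARD, EDGE))])
            raise MalformedAnnotationError(f"annotation values outside {{0, 0.5, 1}}: {bad[:5]}")
        _check_edge_width(px == EDGE)
        object.__setattr__(self, "pixels", px)

    def edge_mask(self) -> np.ndarray:
        return self.pixels == EDGE

    def discard_mask(self) -> np.ndarray:
        return self.pixels == DISCARD

    def body_mask(self) -> np.ndarray:
        return self.pixels == BODY


@dataclass(frozen=True)
class TargetImage:
    """A training target: per-pixel values in [0, 1] of a given kind."""

    pixels: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("edge", "body", "blob", "roi"):
            raise ValueError(f"unknown target kind: {self.kind!r}")
        px = np.asarray(self.pixels, dtype=float)
        if px.min() < 0 or px.max() > 1:
            raise ValueError("target values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class ComplexityGrade:
    """Guttae/blur complexity grade of an image.

    Each of the two scores is 1 (mild), 2 (moderate) or 3 (severe); the grade
    is their sum and is binned as low (grade <= 2), medium (3-4) or
    high (5-6).
    """

    guttae_score: int
    blur_score: int

    @property
    def grade(self) -> int:
        return self.guttae_score + self.blur_score

    @property
    def bin(self) -> str:
        if self.grade <= 2:
            return "low"
        if self.grade <= 4:
            return "medium"
        return "high"


def grade_complexity(guttae_score: int, blur_score: int) -> ComplexityGrade:
    """Combine guttae and blur severity scores into a complexity grade."""
    for s in (guttae_score, blur_score):
        if s not in (1, 2, 3):
            raise ValueError(f"severity scores must be in {{1, 2, 3}}, got {s}")
    return ComplexityGrade(int(guttae_score), int(blur_score))


def _check_edge_width(edge: np.ndarray) -> None:
    """Reject 2x2 blocks of edge pixels (edges must be 1-px curves)."""
    if edge.shape[0] < 2 or edge.shape[1] < 2:
        return
    block = edge[:-1, :-1] & edge[1:, :-1] & edge[:-1, 1:] & edge[1:, 1:]
    if block.any():
        r, c = np.argwhere(block)[0]
        raise ThickEdgeError(f"2x2 edge block at ({r}, {c}): edges must be 1 px wide")


def load_annotation(path) -> Annotation:
    """Load a trinary annotation from an 8-bit grayscale image file.

    The file alphabet is {0, 128, 255}, mapped to {0, 0.5, 1}.
    """
    raw = np.asarray(Image.open(path).convert("I"))
    values = np.unique(raw)
    unknown = [v for v in values if v not in FILE_ALPHABET]
    if unknown:
        raise MalformedAnnotationError(
            f"{path}: pixel values {unknown[:5]} outside the {{0, 128, 255}} alphabet"
        )
    px = np.zeros(raw.shape, dtype=float)
    px[raw == 128] = DISCARD
    px[raw == 255] = EDGE
    return Annotation(px)


def save_annotation(annotation: Annotation, path) -> None:
    """Write an annotation as an 8-bit grayscale image with alphabet {0, 128, 255}."""
    out = np.zeros(annotation.pixels.shape, dtype=np.uint8)
    out[annotation.pixels == DISCARD] = 128
    out[annotation.pixels == EDGE] = 255
    Image.fromarray(out, mode="L").save(path)


def gaussian_kernel_7x7(sd: float = 1.0) -> np.ndarray:
    """The 7x7 isotropic unnormalized Gaussian kernel (peak 1) of given SD."""
    r = np.arange(-3, 4, dtype=float)
    d2 = r[:, None] ** 2 + r[None, :] ** 2
    return np.exp(-d2 / (2.0 * sd * sd))


def _probabilistic(mask: np.ndarray) -> np.ndarray:
    """Convolve a binary mask with the unnormalized Gaussian and clip to [0, 1]."""
    resp = ndimage.convolve(mask.astype(float), gaussian_kernel_7x7(), mode="constant")
    return np.clip(resp, 0.0, 1.0)


def full_body_labels(annotation: Annotation) -> tuple[np.ndarray, np.ndarray]:
    """Label the cell bodies and flag the *full* ones.

    Returns ``(labels, full)`` where ``labels`` is a 4-connected labeling of
    the 0-regions (cell bodies are separated by 8-connected 1-px edge curves,
    which 4-connectivity cannot cross) and ``full[k]`` tells whether region
    label ``k`` is a full cell: it does not touch the image border and no
    pixel of it is 8-adjacent to a discard pixel.
    """
    body = annotation.body_mask()
    labels, n = ndimage.label(body, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    full = np.zeros(n + 1, dtype=bool)
    if n:
        full[1:] = True
        full[0] = False
        border_labels = np.unique(
            np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
        )
        full[border_labels] = False
        near_discard = ndimage.binary_dilation(
            annotation.discard_mask(), structure=np.ones((3, 3), bool)
        )
        full[np.unique(labels[near_discard])] = False
        full[0] = False
    return labels, full


def make_target(annotation: Annotation, kind: str) -> TargetImage:
    """Derive a training target of the requested kind from an annotation."""
    if kind == "edge":
        return TargetImage(_probabilistic(annotation.edge_mask()), "edge")

    labels, full = full_body_labels(annotation)
    body_mask = full[labels]

    if kind == "body":
        return TargetImage(_probabilistic(body_mask), "body")

    if kind == "blob":
        # edge pixels separating two (or more) full bodies are included
        blob = body_mask.copy()
        edge_idx = np.argwhere(annotation.edge_mask())
        h, w = labels.shape
        for r, c in edge_idx:
            window = labels[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2]
            touching = np.unique(window[window > 0])
            if np.count_nonzero(full[touching]) >= 2:
                blob[r, c] = True
        return TargetImage(_probabilistic(blob), "blob")

    if kind == "roi":
        roi = ~annotation.discard_mask()
        partial_body = annotation.body_mask() & ~body_mask
        roi[partial_body] = False
        return TargetImage(roi.astype(float), "roi")

    raise ValueError(f"unknown target kind: {kind!r}")
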
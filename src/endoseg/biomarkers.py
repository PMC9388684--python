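"""Corneal endothelial biomarkers: ECD, CV, and HEX.

Definitions used throughout the package:

* **ECD** (endothelial cell density) — number of selected cells divided by
  their summed area, in cells/mm^2.  Cell areas are measured in px^2 and
  converted with the pixel size (mm/px); ridge pixels between cells are not
  apportioned to any cell.
* **CV** (polymegethism) — 100 x sample SD / mean of the cell areas, in %.
* **HEX** (pleomorphism) — percentage of six-sided cells.  The *vertex*
  method counts cells with exactly six vertices and uses every selected
  cell; the *neighbor* method counts inner cells (cells all of whose
  neighbors are themselves selected) with exactly six neighboring cells,
  and therefore discards the periphery of the segmentation.

The default pixel size is 1/960 mm/px: the native field of view is about
0.25 mm x 0.55 mm imaged at 240 x 528 px.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CellRecord", "BiomarkerSet", "estimate_biomarkers", "compare_hex_methods", "DEFAULT_PIXEL_SIZE_MM"]

DEFAULT_PIXEL_SIZE_MM = 1.0 / 960.0


@dataclass(frozen=True)
class CellRecord:
    """Per-cell measurements entering the biomarker computation."""

    id: int
    area_px: float
    vertex_count: int
    neighbor_count: int
    is_inner: bool = False

    def __post_init__(self) -> None:
        if self.area_px <= 0:
            raise ValueError("cell area must be positive")


@dataclass(frozen=True)
class BiomarkerSet:
    """ECD [cells/mm^2], CV [%], HEX [%] and the cell count behind them.

    ``hex`` is ``None`` when the requested method could not produce an
    estimate (e.g. the neighbor method with no inner cells).  A fully absent
    estimate (no cells at all) is represented by :func:`no_estimate`.
    """

    n_cells: int
    ecd: float | None
    cv: float | None
    hex: float | None
    hex_method: str = "vertex"
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM

    @property
    def has_estimate(self) -> bool:
        return self.n_cells > 0


def no_estimate(hex_method: str = "vertex", pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM) -> BiomarkerSet:
    """The 'no estimate' result reported when no cell was selected."""
    return BiomarkerSet(0, None, None, None, hex_method, pixel_size_mm)


def _hex_vertex(cells: list[CellRecord]) -> float:
    six = sum(1 for c in cells if c.vertex_count == 6)
    return 100.0 * six / len(cells)


def _hex_neighbor(cells: list[CellRecord]) -> float | None:
    inner = [c for c in cells if c.is_inner]
    if not inner:
        return None
    six = sum(1 for c in inner if c.neighbor_count == 6)
    return 100.0 * six / len(inner)


def estimate_biomarkers(
    cells: list[CellRecord],
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM,
    hex_method: str = "vertex",
) -> BiomarkerSet:
    """Estimate ECD, CV and HEX from the selected cells.

    ECD = n / (sum of areas x pixel_size^2); CV uses the sample (n-1) SD.
    """
    if pixel_size_mm <= 0:
        raise ValueError("pixel size must be positive")
    if hex_method not in ("vertex", "neighbor"):
        raise ValueError(f"unknown hex method: {hex_method!r}")
    if not cells:
        return no_estimate(hex_method, pixel_size_mm)

    areas = np.array([c.area_px for c in cells], dtype=float)
    total_mm2 = areas.sum() * pixel_size_mm**2
    ecd = len(cells) / total_mm2
    cv = 100.0 * areas.std(ddof=1) / areas.mean() if len(cells) > 1 else 0.0
    hex_value = _hex_vertex(cells) if hex_method == "vertex" else _hex_neighbor(cells)
    return BiomarkerSet(len(cells), ecd, cv, hex_value, hex_method, pixel_size_mm)


def compare_hex_methods(cells: list[CellRecord]) -> tuple[float | None, float | None]:
    """HEX by the vertex and by the neighbor method, from the same cell set."""
    if not cells:
        return None, None
    return _hex_vertex(cells), _hex_neighbor(cells)
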
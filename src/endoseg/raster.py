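"""Shared label-image rasterization helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["thin_line_blocks"]


def thin_line_blocks(labels: np.ndarray) -> np.ndarray:
    """Reduce 2x2 blocks of 0-line pixels so separating lines stay 1-px.

    A line pixel may be absorbed by a neighboring region iff its
    4-neighborhood contains exactly one distinct region label (no two
    regions become 4-connected).  A block where no pixel qualifies (an
    X-junction rendered as a 2x2 square) is opened up by pushing one
    adjacent region pixel into the line, after which a corner becomes
    absorbable.  Operates in place and returns the array.
    """
    h, w = labels.shape

    def region_neighbors(i, j):
        out = set()
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            y, x = i + di, j + dj
            if 0 <= y < h and 0 <= x < w and labels[y, x] > 0:
                out.add(int(labels[y, x]))
        return out

    for _ in range(12):
        line = labels == 0
        block = line[:-1, :-1] & line[1:, :-1] & line[:-1, 1:] & line[1:, 1:]
        if not block.any():
            break
        progress = False
        for r, c in np.argwhere(block):
            resolved = False
            for (i, j) in ((r, c), (r + 1, c), (r, c + 1), (r + 1, c + 1)):
                if labels[i, j] != 0:
                    resolved = True
                    break
                neigh = region_neighbors(i, j)
                if len(neigh) == 1:
                    labels[i, j] = neigh.pop()
                    resolved = True
                    break
            if resolved:
                progress = True
                continue
            for (oi, oj) in ((r - 1, c), (r, c - 1), (r + 2, c + 1), (r + 1, c + 2)):
                if 0 <= oi < h and 0 <= oj < w and labels[oi, oj] > 0:
                    labels[oi, oj] = 0
                    progress = True
                    break
        if not progress:
            break
    return labels
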
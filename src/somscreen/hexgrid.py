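"""Hexagonal lattice geometry for square SOM grids.

Nodes live on an n x n grid with "odd-r" offset coordinates: odd rows are
shifted half a cell to the right.  Every interior node then has exactly six
neighbors; border nodes have fewer.  The planar embedding places node
(row, col) at ``x = col + 0.5*(row % 2)``, ``y = row * sqrt(3)/2``, which is
the metric used by the neighborhood kernel during training.
"""
from __future__ import annotations

import math

import numpy as np

# neighbor offsets (drow, dcol) for even and odd rows under odd-r offset
_EVEN = ((-1, -1), (-1, 0), (0, -1), (0, 1), (1, -1), (1, 0))
_ODD = ((-1, 0), (-1, 1), (0, -1), (0, 1), (1, 0), (1, 1))


def neighbors(coord: tuple[int, int], side: int) -> set[tuple[int, int]]:
    """On-grid hexagonal neighbors of ``coord`` on a ``side`` x ``side`` grid."""
    row, col = coord
    if not (0 <= row < side and 0 <= col < side):
        raise ValueError(f"coordinate {coord} off a {side}x{side} grid")
    offs = _ODD if row % 2 else _EVEN
    return {(row + dr, col + dc) for dr, dc in offs
            if 0 <= row + dr < side and 0 <= col + dc < side}


def node_index(coord: tuple[int, int], side: int) -> int:
    return coord[0] * side + coord[1]


def node_coord(index: int, side: int) -> tuple[int, int]:
    return divmod(index, side)


def embedding(side: int) -> np.ndarray:
    """(side^2, 2) array of planar positions, row-major node order."""
    rows, cols = np.divmod(np.arange(side * side), side)
    x = cols + 0.5 * (rows % 2)
    y = rows * (math.sqrt(3) / 2.0)
    return np.column_stack([x, y]).astype(float)


def grid_distances(side: int) -> np.ndarray:
    """(side^2, side^2) Euclidean distances between node centers."""
    pos = embedding(side)
    diff = pos[:, None, :] - pos[None, :, :]
    return np.sqrt((diff ** 2).sum(-1))
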
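"""Frequency-matrix chaos game representation (FCGR) of peptide sequences.

The 20-letter sequence is reduced to 4 symbols (default: hydrophobic /
polar / positive / negative side chains) assigned to the corners of the
unit square.  Starting from the centre, each symbol moves the current
point halfway towards its corner; the visited points are accumulated into
a resolution x resolution grid, flattened row-major and normalised to
sum 1.
"""

from __future__ import annotations

import numpy as np

from pepbench.datasets import PeptideDataset
from pepbench.encode import tables
from pepbench.encode.base import EncodedDataset, EncodingSpec, encode_rows, register

#: Corner coordinates for the four symbol classes, in class order.
CORNERS = ((0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0))


def chaos_game_points(symbols: list[int]) -> list[tuple[float, float]]:
    """The iterated corner-midpoint trajectory, starting from the centre."""
    x, y = 0.5, 0.5
    pts = []
    for s in symbols:
        cx, cy = CORNERS[s]
        x, y = (x + cx) / 2.0, (y + cy) / 2.0
        pts.append((x, y))
    return pts


def fcgr_counts(symbols: list[int], resolution: int) -> np.ndarray:
    """Grid occupancy counts of the chaos-game trajectory (row-major grid)."""
    grid = np.zeros((resolution, resolution))
    for x, y in chaos_game_points(symbols):
        col = min(int(x * resolution), resolution - 1)
        row = min(int(y * resolution), resolution - 1)
        grid[row, col] += 1
    return grid


def _is_power_of_two(v) -> bool:
    return isinstance(v, int) and v >= 1 and (v & (v - 1)) == 0


@register("fcgr", {"resolution": _is_power_of_two}, {"resolution": 8})
def fcgr(
    dataset: PeptideDataset,
    resolution: int = 8,
    reduction: tuple[str, ...] | None = None,
    spec: EncodingSpec | None = None,
) -> EncodedDataset:
    """Chaos-game frequency grid, flattened row-major, normalised to sum 1."""
    spec = spec or EncodingSpec("fcgr", {"resolution": resolution})
    classes = reduction or tables.FCGR_CLASSES
    if len(classes) != 4:
        raise ValueError("fcgr reduction must have exactly 4 classes")
    gmap = tables.group_index(tuple(classes))
    names = [f"fcgr.r{r}.c{c}" for r in range(resolution) for c in range(resolution)]

    def row(s: str) -> np.ndarray:
        counts = fcgr_counts([gmap[a] for a in s], resolution)
        return counts.ravel() / len(s)

    return encode_rows(dataset, spec, names, row)
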
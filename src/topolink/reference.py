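"""Brute-force persistence by boundary-matrix reduction.

A deliberately simple, slow implementation used to validate the union-find
persistence in :mod:`topolink.topology` on small images.  It builds the full
filtered cell complex (pixels as vertices, 4-adjacency edges, 2x2 blocks as
faces), sorts cells by (value, dimension), and runs the standard column
reduction over GF(2).  It shares no code with the production algorithm.
"""

from __future__ import annotations

import numpy as np

from .topology import ChannelImage, PersistenceDiagram, ThresholdGrid

__all__ = ["reduction_persistence"]


def reduction_persistence(image: ChannelImage, grid: ThresholdGrid) -> PersistenceDiagram:
    """H0/H1 diagram of the sublevel filtration via matrix reduction.

    Zero-persistence pairs are dropped; unpaired cells become essential
    classes with death 255.  Intended for images up to roughly 20x20.
    """
    r, s = image.shape
    act = grid.snap(image.values)
    t_max = float(grid.thresholds[-1])

    # cells: (value, dim, key); key is a tuple identifying the cell
    cells: list[tuple[float, int, tuple]] = []
    for i in range(r):
        for j in range(s):
            cells.append((float(act[i, j]), 0, ("v", i, j)))
    for i in range(r):
        for j in range(s):
            if j + 1 < s:
                cells.append((float(max(act[i, j], act[i, j + 1])), 1, ("h", i, j)))
            if i + 1 < r:
                cells.append((float(max(act[i, j], act[i + 1, j])), 1, ("u", i, j)))
    for i in range(r - 1):
        for j in range(s - 1):
            v = float(max(act[i, j], act[i, j + 1], act[i + 1, j], act[i + 1, j + 1]))
            cells.append((v, 2, ("f", i, j)))

    # filtration order: by value, then dimension, then key for determinism
    order = sorted(range(len(cells)), key=lambda c: (cells[c][0], cells[c][1], cells[c][2]))
    pos = {cells[c][2]: rank for rank, c in enumerate(order)}

    def boundary(key: tuple) -> set[int]:
        tag, i, j = key
        if tag == "v":
            return set()
        if tag == "h":
            return {pos[("v", i, j)], pos[("v", i, j + 1)]}
        if tag == "u":
            return {pos[("v", i, j)], pos[("v", i + 1, j)]}
        return {pos[("h", i, j)], pos[("h", i + 1, j)],
                pos[("u", i, j)], pos[("u", i, j + 1)]}

    values = [cells[c][0] for c in order]
    dims = [cells[c][1] for c in order]
    columns = [boundary(cells[c][2]) for c in order]

    low_to_col: dict[int, int] = {}
    paired_birth: set[int] = set()
    bars: list[tuple[float, float, int, bool]] = []
    for j, col in enumerate(columns):
        while col:
            low = max(col)
            k = low_to_col.get(low)
            if k is None:
                break
            col ^= columns[k]
        if col:
            low = max(col)
            low_to_col[low] = j
            paired_birth.add(low)
            b, d = values[low], values[j]
            if b < d:
                bars.append((b, d, dims[low], False))

    for j, col in enumerate(columns):
        # positive cells (empty reduced column) never paired are essential
        if not col and j not in paired_birth:
            bars.append((values[j], t_max, dims[j], True))

    return PersistenceDiagram.from_bars(bars, channel_tag=image.channel_tag)
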
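"""Sublevel-set cubical persistence for single-channel images.

An 8-bit image channel is filtered by pixel value: at threshold ``t`` the
binary complex contains every pixel with value <= t.  Pixels are modelled as
the vertices of a grid graph with 4-connectivity edges and filled 2x2 blocks
(the edge-glued cubical complex), so connected components follow the
4-neighbour convention and a loop is a pixel cycle enclosing at least one
inactive pixel.  Persistence is computed with two union-find sweeps:

* H0 directly, merging components in increasing threshold order under the
  elder rule;
* H1 on the planar dual (faces plus the outer region), sweeping thresholds
  downward, which pairs each loop-creating edge with the face that fills it.

Births and deaths are snapped to the threshold grid, as the filtration only
changes at grid values.  The single surviving component of the full image is
recorded as an essential class with death 255.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelImage",
    "ThresholdGrid",
    "BinaryComplex",
    "PersistenceDiagram",
    "FiltrationGridError",
    "sublevel_filtration",
    "cubical_persistence",
    "euler_characteristic",
    "write_diagrams",
    "read_diagrams",
]

CHANNEL_TAGS = ("gray", "red", "green", "blue")


class FiltrationGridError(ValueError):
    """Raised for threshold grids that cannot support the filtration."""


def _round_half_up(values: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(values, dtype=np.float64) + 0.5)


@dataclass(frozen=True)
class ChannelImage:
    """A single 8-bit channel of an r x s raster image."""

    values: np.ndarray
    channel_tag: str = "gray"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("channel image must be a 2-D grid of size >= 2x2")
        if self.channel_tag not in CHANNEL_TAGS:
            raise ValueError(f"unknown channel tag {self.channel_tag!r}")
        # non-integer inputs are rounded half-up into [0, 255] at ingestion
        arr = _round_half_up(arr)
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        object.__setattr__(self, "values", arr.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ThresholdGrid:
    """Strictly increasing thresholds t1 < ... < tN with t1 = 0, tN = 255."""

    thresholds: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=np.float64)
        if t.ndim != 1 or t.size < 2:
            raise FiltrationGridError("grid needs at least two thresholds")
        if np.any(np.diff(t) <= 0):
            raise FiltrationGridError("thresholds must be strictly increasing")
        if t[0] != 0 or t[-1] != 255:
            raise FiltrationGridError(
                "grid must start at 0 and end at 255; otherwise some pixels "
                "would never activate"
            )
        object.__setattr__(self, "thresholds", t)

    @classmethod
    def default(cls, n: int = 50) -> "ThresholdGrid":
        """N evenly spaced thresholds spanning [0, 255]."""
        return cls(np.linspace(0.0, 255.0, n))

    @property
    def n(self) -> int:
        return self.thresholds.size

    def snap(self, values: np.ndarray) -> np.ndarray:
        """Smallest grid threshold >= each value (activation threshold)."""
        idx = np.searchsorted(self.thresholds, np.asarray(values, dtype=np.float64),
                              side="left")
        return self.thresholds[idx]


@dataclass(frozen=True)
class BinaryComplex:
    """Boolean activation mask of one filtration step."""

    active_mask: np.ndarray
    threshold_index: int


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of (birth, death, dim) bars with an essential-class flag.

    ``essential`` marks classes of the final (full-rectangle) complex; their
    death is recorded as 255 rather than infinity so every coordinate is
    finite.  A non-essential bar may also die exactly at 255 (a hole filled
    by the last activation step); the flag distinguishes the two.
    """

    births: np.ndarray
    deaths: np.ndarray
    dims: np.ndarray
    essential: np.ndarray
    channel_tag: str = "gray"

    def __post_init__(self) -> None:
        b = np.asarray(self.births, dtype=np.float64)
        d = np.asarray(self.deaths, dtype=np.float64)
        q = np.asarray(self.dims, dtype=np.int64)
        e = np.asarray(self.essential, dtype=bool)
        if not (b.shape == d.shape == q.shape == e.shape):
            raise ValueError("diagram columns must have equal length")
        if np.any(b > d):
            raise ValueError("birth must not exceed death")
        order = np.lexsort((e, d, b, q))
        object.__setattr__(self, "births", b[order])
        object.__setattr__(self, "deaths", d[order])
        object.__setattr__(self, "dims", q[order])
        object.__setattr__(self, "essential", e[order])

    def __len__(self) -> int:
        return self.births.size

    def pairs(self, dim: int | None = None) -> np.ndarray:
        """(n, 2) array of (birth, death), optionally restricted to one dim."""
        sel = slice(None) if dim is None else self.dims == dim
        return np.column_stack([self.births[sel], self.deaths[sel]])

    def as_multiset(self) -> list[tuple[float, float, int, bool]]:
        return sorted(zip(self.births.tolist(), self.deaths.tolist(),
                          self.dims.tolist(), self.essential.tolist()))

    @classmethod
    def from_bars(cls, bars, channel_tag: str = "gray") -> "PersistenceDiagram":
        """Build from an iterable of (birth, death, dim, essential) tuples."""
        bars = list(bars)
        if not bars:
            z = np.zeros(0)
            return cls(z, z, z.astype(int), z.astype(bool), channel_tag)
        b, d, q, e = zip(*bars)
        return cls(np.array(b), np.array(d), np.array(q), np.array(e), channel_tag)


def sublevel_filtration(image: ChannelImage, grid: ThresholdGrid) -> list[BinaryComplex]:
    """Nested binary masks: step m activates every pixel with value <= t_m."""
    vals = image.values.astype(np.float64)
    return [
        BinaryComplex(active_mask=vals <= t, threshold_index=m)
        for m, t in enumerate(grid.thresholds)
    ]


def euler_characteristic(mask: np.ndarray | BinaryComplex) -> int:
    """Euler characteristic V - E + F of the active-pixel cubical complex.

    Computed on the edge-glued complex via its homotopy-equivalent nerve:
    chi = #pixels - #4-adjacent pairs + #fully-active 2x2 blocks.
    """
    m = mask.active_mask if isinstance(mask, BinaryComplex) else np.asarray(mask)
    m = m.astype(bool)
    p = int(m.sum())
    horiz = int(np.logical_and(m[:, :-1], m[:, 1:]).sum())
    vert = int(np.logical_and(m[:-1, :], m[1:, :]).sum())
    if m.shape[0] >= 2 and m.shape[1] >= 2:
        blocks = int((m[:-1, :-1] & m[:-1, 1:] & m[1:, :-1] & m[1:, 1:]).sum())
    else:
        blocks = 0
    return p - (horiz + vert) + blocks


class _UnionFind:
    """Union-find tracking each component's birth value and root pixel index."""

    __slots__ = ("parent", "birth", "rep")

    def __init__(self, births: np.ndarray):
        n = births.size
        self.parent = list(range(n))
        self.birth = births.tolist()
        self.rep = list(range(n))  # linearized index of the component root

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:  # path compression
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, a: int, b: int) -> tuple[int, int] | None:
        """Merge components of a and b; return (survivor, loser) roots or None."""
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return None
        # elder rule: smaller birth survives; tie -> smaller root pixel index
        key_a = (self.birth[ra], self.rep[ra])
        key_b = (self.birth[rb], self.rep[rb])
        if key_a <= key_b:
            survivor, loser = ra, rb
        else:
            survivor, loser = rb, ra
        self.parent[loser] = survivor
        return survivor, loser


def _edge_list(r: int, s: int):
    """All 4-adjacency edges as (p, q, kind) with p,q linearized pixel ids.

    kind 0 = horizontal edge between (i,j)-(i,j+1); kind 1 = vertical.
    """
    edges = []
    for i in range(r):
        for j in range(s):
            p = i * s + j
            if j + 1 < s:
                edges.append((p, p + 1, 0))
            if i + 1 < r:
                edges.append((p, p + s, 1))
    return edges


def cubical_persistence(image: ChannelImage, grid: ThresholdGrid) -> PersistenceDiagram:
    """H0/H1 persistence diagram of the sublevel filtration over a grid.

    Bars with zero persistence on the grid are dropped.  Deterministic:
    merge ties are broken by the smallest linearized root pixel index.
    """
    r, s = image.shape
    act = grid.snap(image.values).ravel()  # per-pixel activation threshold
    t_max = float(grid.thresholds[-1])
    bars: list[tuple[float, float, int, bool]] = []

    edges = _edge_list(r, s)
    edge_vals = np.array([max(act[p], act[q]) for p, q, _ in edges])

    # ---- H0: union-find in increasing threshold order --------------------
    uf = _UnionFind(act)
    for ei in np.lexsort((np.arange(len(edges)), edge_vals)):
        p, q, _ = edges[ei]
        merged = uf.union(p, q)
        if merged is not None:
            _, loser = merged
            birth = uf.birth[loser]
            death = float(edge_vals[ei])
            if birth < death:
                bars.append((birth, death, 0, False))
    bars.append((float(act.min()), t_max, 0, True))  # the full image component

    # ---- H1: union-find on the dual, decreasing threshold order ----------
    # Dual nodes: one per 2x2 block (value = max of its four pixels) plus the
    # outer region omega.  A primal edge connects its at-most-two incident
    # blocks; missing blocks are omega.  Sweeping values downward, a dual
    # merge at edge value b kills the younger face-component born at d,
    # which corresponds to the primal loop bar (b, d).
    fr, fs = r - 1, s - 1
    n_faces = fr * fs
    omega = n_faces
    face_val = np.empty(n_faces)
    a2 = act.reshape(r, s)
    for fi in range(fr):
        for fj in range(fs):
            face_val[fi * fs + fj] = max(
                a2[fi, fj], a2[fi, fj + 1], a2[fi + 1, fj], a2[fi + 1, fj + 1]
            )

    parent = list(range(n_faces + 1))
    birth_rev = face_val.tolist() + [np.inf]  # omega enters first (top)

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    def cofaces(p: int, q: int, kind: int) -> tuple[int, int]:
        i, j = divmod(p, s)
        if kind == 0:  # horizontal edge (i,j)-(i,j+1)
            up = (i - 1) * fs + j if i - 1 >= 0 else omega
            down = i * fs + j if i <= fr - 1 else omega
            return up, down
        # vertical edge (i,j)-(i+1,j)
        left = i * fs + (j - 1) if j - 1 >= 0 else omega
        right = i * fs + j if j <= fs - 1 else omega
        return left, right

    for ei in np.lexsort((np.arange(len(edges)), -edge_vals)):
        p, q, kind = edges[ei]
        fa, fb = cofaces(p, q, kind)
        ra, rb = find(fa), find(fb)
        if ra == rb:
            continue
        # reversed elder rule: larger face value entered earlier, survives
        if (birth_rev[ra], -ra) >= (birth_rev[rb], -rb):
            survivor, loser = ra, rb
        else:
            survivor, loser = rb, ra
        parent[loser] = survivor
        b = float(edge_vals[ei])
        d = float(birth_rev[loser])
        if b < d:
            bars.append((b, d, 1, False))

    return PersistenceDiagram.from_bars(bars, channel_tag=image.channel_tag)


def write_diagrams(path, diagrams: dict[str, PersistenceDiagram]) -> None:
    """Serialize per-channel diagrams to a TSV (birth, death, dim, channel, essential)."""
    import pandas as pd

    rows = []
    for tag, dg in diagrams.items():
        for b, d, q, e in zip(dg.births, dg.deaths, dg.dims, dg.essential):
            rows.append({"birth": b, "death": d, "dim": int(q),
                         "channel": tag, "essential": int(e)})
    pd.DataFrame(rows, columns=["birth", "death", "dim", "channel", "essential"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_diagrams(path) -> dict[str, PersistenceDiagram]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out: dict[str, PersistenceDiagram] = {}
    for tag, grp in df.groupby("channel", sort=False):
        out[str(tag)] = PersistenceDiagram(
            grp["birth"].to_numpy(), grp["death"].to_numpy(),
            grp["dim"].to_numpy(), grp["essential"].to_numpy(dtype=bool),
            channel_tag=str(tag),
        )
    return out
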
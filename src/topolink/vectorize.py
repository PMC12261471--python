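"""Fixed-length topological feature vectors from persistence diagrams.

Two summaries are used, both over the filtration range [0, 255]:

* Betti curves: for each grid threshold t_m, the number of dimension-d bars
  alive at t_m (alive means birth <= t < death; the essential class of the
  full image additionally counts at t = 255).  Length N = 50 per dimension.
* First-level persistence landscapes: lambda_1(x) = max over bars of the
  tent function of (b, d), sampled at B = 100 bin centers.  The tent rises
  with slope 1 from b, peaks at (d-b)/2 over the midpoint, and falls to d.

Per channel this yields 50 + 50 + 100 + 100 = 300 features in the order
(Betti H0 | Betti H1 | landscape H0 | landscape H1); concatenating the four
channels (gray, red, green, blue) gives the 1200-D per-entity vector.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .topology import (
    CHANNEL_TAGS,
    ChannelImage,
    PersistenceDiagram,
    ThresholdGrid,
    cubical_persistence,
    _round_half_up,
)

__all__ = [
    "DEFAULT_THRESHOLDS",
    "DEFAULT_BINS",
    "TOPO_VECTOR_LENGTH",
    "triangle_function",
    "betti_curve",
    "landscape_level1",
    "channel_vector",
    "split_channels",
    "image_vector",
    "block_slices",
    "restrict_blocks",
    "write_feature_table",
    "read_feature_table",
]

DEFAULT_THRESHOLDS = 50
DEFAULT_BINS = 100
LANDSCAPE_DOMAIN = (0.0, 255.0)
TOPO_VECTOR_LENGTH = 4 * (2 * DEFAULT_THRESHOLDS + 2 * DEFAULT_BINS)  # 1200


def triangle_function(pair: tuple[float, float], x) -> np.ndarray | float:
    """Tent function of a birth-death pair evaluated at x.

    Zero outside (b, d); x - b on the rising side, d - x on the falling
    side, peaking at (d - b)/2 over the interval midpoint.
    """
    b, d = float(pair[0]), float(pair[1])
    if b > d:
        raise ValueError(f"invalid pair: birth {b} > death {d}")
    x = np.asarray(x, dtype=np.float64)
    out = np.minimum(x - b, d - x)
    out = np.where((x > b) & (x < d), np.maximum(out, 0.0), 0.0)
    return float(out) if out.ndim == 0 else out


def betti_curve(diagram: PersistenceDiagram, grid: ThresholdGrid, dim: int) -> np.ndarray:
    """Number of dim-d bars alive at each grid threshold (length N ints)."""
    if dim not in (0, 1):
        raise ValueError("dim must be 0 or 1")
    t = grid.thresholds
    sel = diagram.dims == dim
    b = diagram.births[sel][:, None]
    d = diagram.deaths[sel][:, None]
    e = diagram.essential[sel][:, None]
    alive = (b <= t[None, :]) & (t[None, :] < d)
    # the essential class of the full image persists through the endpoint
    alive |= e & (t[None, :] == t[-1]) & (b <= t[None, :])
    return alive.sum(axis=0).astype(np.int64)


def landscape_level1(
    diagram: PersistenceDiagram,
    dim: int,
    bins: int = DEFAULT_BINS,
    domain: tuple[float, float] = LANDSCAPE_DOMAIN,
) -> np.ndarray:
    """lambda_1 sampled at the centers of `bins` equal subintervals of domain."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    lo, hi = domain
    centers = lo + (np.arange(bins) + 0.5) * (hi - lo) / bins
    sel = diagram.dims == dim
    b = diagram.births[sel][:, None]
    d = diagram.deaths[sel][:, None]
    if b.size == 0:
        return np.zeros(bins)
    x = centers[None, :]
    tent = np.minimum(x - b, d - x)
    tent = np.where((x > b) & (x < d), np.maximum(tent, 0.0), 0.0)
    return tent.max(axis=0)


def channel_vector(
    diagram: PersistenceDiagram,
    grid: ThresholdGrid,
    bins: int = DEFAULT_BINS,
) -> np.ndarray:
    """(Betti H0 | Betti H1 | landscape H0 | landscape H1) for one channel."""
    return np.concatenate([
        betti_curve(diagram, grid, 0).astype(np.float64),
        betti_curve(diagram, grid, 1).astype(np.float64),
        landscape_level1(diagram, 0, bins),
        landscape_level1(diagram, 1, bins),
    ])


def split_channels(rgb: np.ndarray) -> dict[str, ChannelImage]:
    """Decompose an RGB raster into gray + R + G + B channel images.

    Grayscale is ITU-R 601 luminance 0.299R + 0.587G + 0.114B, rounded
    half-up to an integer.
    """
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (r, s, 3) RGB array")
    red, green, blue = arr[..., 0], arr[..., 1], arr[..., 2]
    gray = _round_half_up(0.299 * red + 0.587 * green + 0.114 * blue)
    return {
        "gray": ChannelImage(gray, "gray"),
        "red": ChannelImage(red, "red"),
        "green": ChannelImage(green, "green"),
        "blue": ChannelImage(blue, "blue"),
    }


def image_vector(
    rgb: np.ndarray,
    grid: ThresholdGrid | None = None,
    bins: int = DEFAULT_BINS,
    return_diagrams: bool = False,
):
    """1200-D topological feature vector of an RGB image.

    Channels are processed in the fixed order (gray, red, green, blue),
    each contributing a 300-entry block.
    """
    grid = grid or ThresholdGrid.default(DEFAULT_THRESHOLDS)
    channels = split_channels(rgb)
    diagrams = {tag: cubical_persistence(channels[tag], grid) for tag in CHANNEL_TAGS}
    vec = np.concatenate([channel_vector(diagrams[tag], grid, bins) for tag in CHANNEL_TAGS])
    if return_diagrams:
        return vec, diagrams
    return vec


def block_slices(
    n_thresholds: int = DEFAULT_THRESHOLDS, bins: int = DEFAULT_BINS
) -> dict[str, list[slice]]:
    """Column slices of the Betti and landscape blocks in the full vector."""
    per_channel = 2 * n_thresholds + 2 * bins
    betti, landscape = [], []
    for c in range(len(CHANNEL_TAGS)):
        base = c * per_channel
        betti.append(slice(base, base + 2 * n_thresholds))
        landscape.append(slice(base + 2 * n_thresholds, base + per_channel))
    return {"betti": betti, "landscape": landscape}


def restrict_blocks(vectors: np.ndarray, which: str) -> np.ndarray:
    """Keep only the Betti or landscape blocks of full topological vectors.

    Used by the Betti-only / landscape-only fusion ablations.  `which` is
    one of {"all", "betti", "landscape"}.
    """
    if which == "all":
        return vectors
    if which not in ("betti", "landscape"):
        raise ValueError(f"unknown block selection {which!r}")
    sl = block_slices()[which]
    vectors = np.atleast_2d(vectors)
    return np.concatenate([vectors[:, s] for s in sl], axis=1)


def write_feature_table(path, table: dict[str, np.ndarray]) -> None:
    """One row per entity id; columns f0000..f1199 in the documented layout."""
    ids = list(table)
    mat = np.vstack([table[i] for i in ids]) if ids else np.zeros((0, TOPO_VECTOR_LENGTH))
    cols = [f"f{i:04d}" for i in range(mat.shape[1])]
    df = pd.DataFrame(mat, index=pd.Index(ids, name="id"), columns=cols)
    with open(path, "w") as fh:
        fh.write("# topolink feature table: per channel (gray,red,green,blue): "
                 "Betti H0|Betti H1|landscape H0|landscape H1\n")
        df.to_csv(fh, sep="\t")


def read_feature_table(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="id")
    return {str(i): df.loc[i].to_numpy(dtype=np.float64) for i in df.index}
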
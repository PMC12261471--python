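"""Per-entity input production: molecular images, contact-map images,
sequence embeddings and the projection heads to the 512-D latent space.

Backends are pluggable.  Molecular depiction uses RDKit when installed; a
deterministic in-repo skeletal renderer handles a restricted SMILES subset
(rings and linear chains) so the full pipeline runs without any chemistry
dependency.  Sequence-model embeddings (768-D for drugs, 1024-D for
proteins) are ingested from tables or produced by a seeded mock generator;
running the pretrained language models themselves is out of scope here.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .autodiff import Tensor

__all__ = [
    "EntityRecord",
    "RenderError",
    "EmbeddingSchemaError",
    "EMBEDDING_DIMS",
    "LATENT_DIM",
    "render_molecule",
    "contact_map_to_image",
    "load_embedding_table",
    "save_embedding_table",
    "mock_embeddings",
    "read_fasta",
    "ProjectionHead",
    "project",
]

EMBEDDING_DIMS = {"drug": 768, "target": 1024}
LATENT_DIM = 512


class RenderError(ValueError):
    """A SMILES string could not be rendered; carries the offending input."""


class EmbeddingSchemaError(ValueError):
    """An embedding table row has the wrong width; carries offending ids."""


@dataclass(frozen=True)
class EntityRecord:
    id: str
    kind: str  # "drug" | "target"
    sequence: str  # SMILES (drug) or amino acids (target)

    def __post_init__(self) -> None:
        if self.kind not in ("drug", "target"):
            raise ValueError(f"unknown entity kind {self.kind!r}")
        if not self.sequence:
            raise ValueError(f"entity {self.id!r} has an empty sequence")


# --------------------------------------------------------------------------
# molecular depiction
# --------------------------------------------------------------------------

_ATOM_CHARS = set("BCNOPSFIbcnops")


def _parse_restricted_smiles(smiles: str):
    """Tokenize a restricted SMILES subset into atoms and ring-bond marks.

    Supports atom letters (incl. Cl/Br two-letter halogens), single-digit
    ring-closure labels and branch parentheses (branches are flattened onto
    the backbone).  Raises RenderError on anything else.
    """
    atoms: list[str] = []
    open_rings: dict[str, int] = {}
    closures: list[tuple[int, int]] = []
    i = 0
    while i < len(smiles):
        ch = smiles[i]
        if smiles[i:i + 2] in ("Cl", "Br"):
            atoms.append(smiles[i:i + 2])
            i += 2
            continue
        if ch in _ATOM_CHARS:
            atoms.append(ch)
            i += 1
            continue
        if ch.isdigit():
            if not atoms:
                raise RenderError(f"ring label before any atom in {smiles!r}")
            if ch in open_rings:  # close; labels are reusable afterwards
                closures.append((open_rings.pop(ch), len(atoms) - 1))
            else:
                open_rings[ch] = len(atoms) - 1
            i += 1
            continue
        if ch in "()=-#:/\\":
            i += 1
            continue
        raise RenderError(f"cannot render SMILES {smiles!r}: unsupported token {ch!r}")
    if not atoms:
        raise RenderError(f"cannot render SMILES {smiles!r}: no atoms")
    if open_rings:
        raise RenderError(
            f"unbalanced ring label(s) {sorted(open_rings)} in {smiles!r}")
    bonds = [(k, k + 1) for k in range(len(atoms) - 1)]
    bonds.extend(closures)
    return atoms, bonds


def _render_synthetic(smiles: str, size: int) -> np.ndarray:
    """Deterministic skeletal drawing: ring closures become regular polygons,
    chains a zig-zag backbone.  Black strokes on white, no text."""
    atoms, bonds = _parse_restricted_smiles(smiles)
    n = len(atoms)
    ring_bonds = [b for b in bonds if abs(b[0] - b[1]) != 1]

    coords = np.zeros((n, 2))
    placed = np.zeros(n, dtype=bool)
    cursor = 0.0
    for a, b in sorted(ring_bonds):
        k = b - a + 1  # ring size
        ang = 2 * np.pi * np.arange(k) / k - np.pi / 2
        radius = k / (2 * np.pi) * 1.6
        cx = cursor + radius
        coords[a:b + 1, 0] = cx + radius * np.cos(ang)
        coords[a:b + 1, 1] = radius * np.sin(ang)
        placed[a:b + 1] = True
        cursor = cx + radius + 1.0
    for k in range(n):
        if not placed[k]:
            # zig-zag chain continuing right of everything placed so far
            cursor += 0.9
            coords[k] = (cursor, 0.45 if k % 2 else -0.45)
            placed[k] = True

    span = coords.max(axis=0) - coords.min(axis=0)
    scale = (size * 0.7) / max(span.max(), 1.0)
    xy = (coords - coords.min(axis=0)) * scale
    xy += (size - span * scale) / 2.0

    img = Image.new("RGB", (size, size), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    width = max(3, size // 42)
    for a, b in bonds:
        draw.line([tuple(xy[a]), tuple(xy[b])], fill=(0, 0, 0), width=width)
    for k in range(n):
        # seal line joints so aliasing cannot open pinhole loops at vertices
        x, y = xy[k]
        draw.ellipse([x - width, y - width, x + width, y + width], fill=(0, 0, 0))
    return np.asarray(img, dtype=np.uint8)


def _render_rdkit(smiles: str, size: int) -> np.ndarray:
    from rdkit import Chem
    from rdkit.Chem.Draw import rdMolDraw2D

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise RenderError(f"cannot render SMILES {smiles!r}: RDKit parse failure")
    drawer = rdMolDraw2D.MolDraw2DCairo(size, size)
    rdMolDraw2D.PrepareAndDrawMolecule(drawer, mol)
    drawer.FinishDrawing()
    png = drawer.GetDrawingText()
    with Image.open(io.BytesIO(png)) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def render_molecule(smiles: str, size: int = 256, backend: str = "auto") -> np.ndarray:
    """Render a SMILES string to a size x size RGB raster (uint8).

    backend: "rdkit", "synthetic", or "auto" (RDKit if importable, else the
    in-repo skeletal renderer).  Deterministic: identical input and backend
    produce identical pixels.
    """
    if not smiles:
        raise RenderError("cannot render an empty SMILES string")
    if backend == "auto":
        try:
            import rdkit  # noqa: F401
            backend = "rdkit"
        except ImportError:
            backend = "synthetic"
    if backend == "rdkit":
        return _render_rdkit(smiles, size)
    if backend == "synthetic":
        return _render_synthetic(smiles, size)
    raise ValueError(f"unknown renderer backend {backend!r}")


# --------------------------------------------------------------------------
# contact maps
# --------------------------------------------------------------------------

def contact_map_to_image(matrix: np.ndarray, size: int = 300) -> np.ndarray:
    """Render an n x n contact map in [0, 1] to a size x size RGB image.

    Values are scaled to [0, 255] (rounded half-up), resampled by nearest
    neighbour, and replicated onto three identical channels.  The scaling is
    monotone, so the sublevel filtration order of the map is preserved.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("contact map must be a square matrix")
    if m.size == 0 or m.min() < 0.0 or m.max() > 1.0:
        raise ValueError("contact map entries must lie in [0, 1]")
    scaled = np.floor(m * 255.0 + 0.5).astype(np.uint8)
    n = m.shape[0]
    idx = (np.arange(size) * n) // size
    resized = scaled[np.ix_(idx, idx)]
    return np.repeat(resized[:, :, None], 3, axis=2)


# --------------------------------------------------------------------------
# embedding tables and mocks
# --------------------------------------------------------------------------

def load_embedding_table(path, kind: str) -> dict[str, np.ndarray]:
    """Load a TSV of per-entity embeddings (id column + numeric columns)."""
    expected = EMBEDDING_DIMS[kind]
    df = pd.read_csv(path, sep="\t", index_col="id")
    widths = df.notna().sum(axis=1)
    bad = [str(i) for i in df.index[widths != expected]]
    if bad:
        raise EmbeddingSchemaError(
            f"{kind} embeddings must have {expected} entries; offending ids: {bad}"
        )
    return {str(i): df.loc[i].to_numpy(dtype=np.float64) for i in df.index}


def save_embedding_table(path, table: dict[str, np.ndarray]) -> None:
    ids = list(table)
    mat = np.vstack([table[i] for i in ids])
    cols = [f"e{i:04d}" for i in range(mat.shape[1])]
    pd.DataFrame(mat, index=pd.Index(ids, name="id"), columns=cols).to_csv(path, sep="\t")


def _stable_seed(seed: int, kind: str, entity_id: str) -> int:
    digest = hashlib.sha256(f"{seed}:{kind}:{entity_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def mock_embeddings(ids, kind: str, seed: int) -> dict[str, np.ndarray]:
    """Deterministic unit-variance stand-in embeddings keyed by id.

    Each vector is drawn from a generator seeded by a stable hash of
    (seed, kind, id), so tables are reproducible and order-independent.
    """
    dim = EMBEDDING_DIMS[kind]
    out = {}
    for entity_id in ids:
        rng = np.random.default_rng(_stable_seed(seed, kind, str(entity_id)))
        out[str(entity_id)] = rng.standard_normal(dim)
    return out


def read_fasta(path) -> dict[str, str]:
    """Protein sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# --------------------------------------------------------------------------
# projection heads
# --------------------------------------------------------------------------

@dataclass
class ProjectionHead:
    """Two fully connected layers with ReLU activations mapping an input
    family (drug/target sequence embedding or topological vector) to the
    common 512-D latent space."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    @classmethod
    def initialize(cls, in_dim: int, seed: int, hidden: int = LATENT_DIM,
                   out_dim: int = LATENT_DIM) -> "ProjectionHead":
        rng = np.random.default_rng(seed)
        return cls(
            W1=rng.normal(0.0, np.sqrt(2.0 / in_dim), (in_dim, hidden)),
            b1=np.zeros(hidden),
            W2=rng.normal(0.0, np.sqrt(2.0 / hidden), (hidden, out_dim)),
            b2=np.zeros(out_dim),
        )

    @property
    def in_dim(self) -> int:
        return self.W1.shape[0]


def project(values: np.ndarray, head: ProjectionHead) -> np.ndarray:
    """FC -> ReLU -> FC -> ReLU projection to the latent space."""
    x = np.atleast_2d(np.asarray(values, dtype=np.float64))
    if x.shape[1] != head.in_dim:
        raise ValueError(f"head expects inputs of length {head.in_dim}, got {x.shape[1]}")
    h = np.maximum(x @ head.W1 + head.b1, 0.0)
    out = np.maximum(h @ head.W2 + head.b2, 0.0)
    return out[0] if np.asarray(values).ndim == 1 else out


def head_tensors(head: ProjectionHead) -> list[Tensor]:
    """Trainable Tensor views of a projection head's parameters."""
    return [Tensor(head.W1.copy(), True), Tensor(head.b1.copy(), True),
            Tensor(head.W2.copy(), True), Tensor(head.b2.copy(), True)]
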
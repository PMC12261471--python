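"""Synthetic fixtures with known ground truth.

Two generators cover the two halves of the pipeline:

* ``gen_topo_image`` plants dark blobs and rings (annuli) on a light canvas.
  Because the sublevel filtration activates low values first, the dark
  foreground appears early: at a mid-range threshold the planted Betti
  numbers are beta0 = blobs + rings and beta1 = rings, and each ring
  contributes one long H1 bar (the hole fills only when the light interior
  activates near 255).

* ``gen_dti_dataset`` plants a low-rank interaction structure: drugs and
  targets get latent vectors, and the pairs whose noisy latent inner product
  falls in the top density-quantile are the positives.  Mock sequence-model
  embeddings are noisy linear images of the latents (signal-bearing);
  mock topological vectors are either signal-bearing or pure noise,
  controlled by ``topo_signal`` -- the noise setting is the default study
  condition, so the fusion gate must discover which modality is informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .adapters import EMBEDDING_DIMS, EntityRecord, save_embedding_table
from .vectorize import TOPO_VECTOR_LENGTH, write_feature_table

__all__ = ["TopoImageSpec", "PlantedDTISpec", "SyntheticDTIDataset",
           "gen_topo_image", "gen_dti_dataset"]


@dataclass(frozen=True)
class TopoImageSpec:
    n_blobs: int = 0
    n_rings: int = 0
    size: int = 64
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blobs < 0 or self.n_rings < 0 or self.n_blobs + self.n_rings == 0:
            raise ValueError("need at least one blob or ring")
        if self.size < 16:
            raise ValueError("canvas too small")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def gen_topo_image(spec: TopoImageSpec) -> tuple[np.ndarray, tuple[int, int]]:
    """Dark shapes on a light canvas; returns (RGB image, (beta0, beta1)).

    Ground truth refers to the dark foreground at a mid-range threshold:
    beta0 = n_blobs + n_rings, beta1 = n_rings.  Shapes are placed disjointly
    by rejection sampling; a spec whose shapes cannot fit raises.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    n_shapes = spec.n_blobs + spec.n_rings
    # jittered-grid placement: one shape per cell guarantees disjointness
    g = int(np.ceil(np.sqrt(n_shapes)))
    cell = size / g
    outer_r = 0.3 * cell
    if outer_r < 4.0:
        raise ValueError(
            f"cannot place {n_shapes} disjoint shapes on a {size}x{size} canvas"
        )
    yy, xx = np.mgrid[0:size, 0:size]

    cells = [(i, j) for i in range(g) for j in range(g)]
    chosen = [cells[k] for k in rng.permutation(len(cells))[:n_shapes]]
    jitter = rng.uniform(-0.1 * cell, 0.1 * cell, size=(n_shapes, 2))
    centers = [((i + 0.5) * cell + dy, (j + 0.5) * cell + dx)
               for (i, j), (dy, dx) in zip(chosen, jitter)]

    canvas = np.full((size, size), 255.0)
    for idx, (cy, cx) in enumerate(centers):
        dist = np.hypot(yy - cy, xx - cx)
        if idx < spec.n_blobs:
            canvas[dist <= outer_r] = 0.0
        else:
            ring = (dist <= outer_r) & (dist >= outer_r / 2.0)
            canvas[ring] = 0.0

    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, canvas.shape)
    canvas = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)
    rgb = np.repeat(canvas[:, :, None], 3, axis=2)
    return rgb, (spec.n_blobs + spec.n_rings, spec.n_rings)


@dataclass(frozen=True)
class PlantedDTISpec:
    n_drugs: int = 200
    n_targets: int = 150
    latent_dim: int = 8
    density: float = 0.05
    noise_sd: float = 0.1
    topo_signal: bool = False   # default: only the sequence side is informative
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must lie in (0, 1)")
        if min(self.n_drugs, self.n_targets, self.latent_dim) < 1:
            raise ValueError("degenerate dataset spec")
        n_pos = int(round(self.density * self.n_drugs * self.n_targets))
        if n_pos < 1 or n_pos >= self.n_drugs * self.n_targets:
            raise ValueError("density leaves no positives or no negatives")


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_SMILES_FRAGMENTS = np.array(["C", "CC", "CO", "CN", "c1ccccc1", "C(=O)O", "CCl"])


def _fake_sequences(rng, n_drugs, n_targets):
    drugs = ["".join(rng.choice(_SMILES_FRAGMENTS, size=rng.integers(2, 6)))
             for _ in range(n_drugs)]
    targets = ["".join(rng.choice(_AA, size=rng.integers(50, 200)))
               for _ in range(n_targets)]
    return drugs, targets


@dataclass
class SyntheticDTIDataset:
    spec: PlantedDTISpec
    drugs: list[EntityRecord]
    targets: list[EntityRecord]
    pairs: pd.DataFrame                      # drug_id, target_id, label
    drug_llm: dict[str, np.ndarray]
    target_llm: dict[str, np.ndarray]
    drug_topo: dict[str, np.ndarray]
    target_topo: dict[str, np.ndarray]
    latent_drugs: np.ndarray = field(repr=False, default=None)
    latent_targets: np.ndarray = field(repr=False, default=None)

    def write(self, directory) -> None:
        """Emit the dataset in the exact formats the readers consume."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        table = self.pairs.copy()
        table["SMILES"] = table["drug_id"].map(
            {r.id: r.sequence for r in self.drugs})
        table["sequence"] = table["target_id"].map(
            {r.id: r.sequence for r in self.targets})
        table.to_csv(directory / "pairs.tsv", sep="\t", index=False)
        save_embedding_table(directory / "drug_embeddings.tsv", self.drug_llm)
        save_embedding_table(directory / "target_embeddings.tsv", self.target_llm)
        write_feature_table(directory / "drug_topo.tsv", self.drug_topo)
        write_feature_table(directory / "target_topo.tsv", self.target_topo)


def _noisy_linear(latent: np.ndarray, out_dim: int, noise_sd: float, rng,
                  signal: bool) -> np.ndarray:
    n, k = latent.shape
    if not signal:
        return rng.standard_normal((n, out_dim))
    proj = rng.standard_normal((k, out_dim)) / np.sqrt(k)
    return latent @ proj + noise_sd * rng.standard_normal((n, out_dim))


def gen_dti_dataset(spec: PlantedDTISpec) -> SyntheticDTIDataset:
    """Planted low-rank DTI dataset with balanced negatives.

    Positives are exactly the top density-quantile of the noisy latent
    inner-product scores; negatives are an equal-size uniform sample of the
    remaining pairs.  Deterministic for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    U = rng.standard_normal((spec.n_drugs, spec.latent_dim))
    V = rng.standard_normal((spec.n_targets, spec.latent_dim))
    scores = U @ V.T + spec.noise_sd * rng.standard_normal((spec.n_drugs, spec.n_targets))

    n_total = spec.n_drugs * spec.n_targets
    n_pos = int(round(spec.density * n_total))
    flat = scores.ravel()
    pos_idx = np.argsort(flat)[::-1][:n_pos]
    neg_pool = np.setdiff1d(np.arange(n_total), pos_idx, assume_unique=False)
    neg_idx = rng.choice(neg_pool, size=min(n_pos, neg_pool.size), replace=False)

    drug_ids = [f"d{i:04d}" for i in range(spec.n_drugs)]
    target_ids = [f"t{i:04d}" for i in range(spec.n_targets)]
    rows = []
    for idx, label in [(pos_idx, 1), (neg_idx, 0)]:
        di, ti = np.unravel_index(idx, scores.shape)
        for d, t in zip(di, ti):
            rows.append((drug_ids[d], target_ids[t], label))
    pairs = pd.DataFrame(rows, columns=["drug_id", "target_id", "label"])
    pairs = pairs.sample(frac=1.0, random_state=spec.seed).reset_index(drop=True)

    drug_seqs, target_seqs = _fake_sequences(rng, spec.n_drugs, spec.n_targets)
    drugs = [EntityRecord(i, "drug", s) for i, s in zip(drug_ids, drug_seqs)]
    targets = [EntityRecord(i, "target", s) for i, s in zip(target_ids, target_seqs)]

    drug_llm = _noisy_linear(U, EMBEDDING_DIMS["drug"], spec.noise_sd, rng, True)
    target_llm = _noisy_linear(V, EMBEDDING_DIMS["target"], spec.noise_sd, rng, True)
    drug_topo = _noisy_linear(U, TOPO_VECTOR_LENGTH, spec.noise_sd, rng,
                              spec.topo_signal)
    target_topo = _noisy_linear(V, TOPO_VECTOR_LENGTH, spec.noise_sd, rng,
                                spec.topo_signal)

    as_table = lambda ids, mat: {i: mat[k] for k, i in enumerate(ids)}
    return SyntheticDTIDataset(
        spec=spec, drugs=drugs, targets=targets, pairs=pairs,
        drug_llm=as_table(drug_ids, drug_llm),
        target_llm=as_table(target_ids, target_llm),
        drug_topo=as_table(drug_ids, drug_topo),
        target_topo=as_table(target_ids, target_topo),
        latent_drugs=U, latent_targets=V,
    )
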
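# topolink

Topological image features and gated multimodal fusion for drug–target
interaction (DTI) link prediction.

## The problem

Predicting whether a small-molecule drug binds a protein target is a core
screening task in drug discovery. Sequence-derived embeddings (from
pretrained chemical and protein language models) capture composition well
but can miss *shape*: ring systems in a 2-D molecular depiction, or the
contact patterns of a folded protein. `topolink` extracts that shape
information with persistent homology and learns how to blend it with
sequence embeddings inside a graph neural network link classifier.

The package is aimed at computational chemists and method developers who
want each stage — topological featurization, fusion, graph learning,
evaluation protocol — as an importable, separately testable component, with
synthetic generators so the whole pipeline runs with no external data or
pretrained models.

## The method

**Topological features.** A 2-D image channel (pixel values γ ∈ [0, 255]) is
filtered by sublevel sets: at threshold *t*, the binary complex X_t contains
every pixel with γ ≤ t, giving a nested family X_{t1} ⊂ … ⊂ X_{tN} over
N = 50 thresholds 0 = t1 < … < t50 = 255. Persistent homology tracks
connected components (H0) and loops (H1) across the filtration, yielding a
persistence diagram of (birth, death) bars per dimension. Each diagram is
vectorized two ways:

* **Betti curves** β_d(t_m) — the number of dimension-*d* features alive at
  each threshold (50 values per dimension);
* **Persistence landscapes** λ₁(x) = max over bars of the tent function
  Λ_{(b,d)}(x) = min(x−b, d−x)₊, sampled at 100 bin centers of [0, 255].

Per channel that is 50+50+100+100 = 300 features; concatenating the gray,
red, green and blue channels gives a 1200-D vector per entity. Drugs are
depicted from SMILES at 256×256 (RDKit, or a built-in skeletal renderer);
protein contact maps are rendered to 300×300 grayscale.

**Fusion.** Sequence embeddings (768-D drug / 1024-D protein) and the
1200-D topological vectors are projected by two FC+ReLU layers into a common
512-D space. A learnable gate mixes them coordinate-wise:

    α = σ(W [f_LLM ; f_TDA] + b),    f = α ⊙ f_LLM + (1 − α) ⊙ f_TDA

with W ∈ R^{512×1024}, so every fused coordinate is a convex combination of
the two modalities.

**Graph learning.** Fused vectors become node features of a bipartite
drug–target graph whose message edges are the *positive training pairs
only* (evaluation edges never propagate). Two heterogeneous
mean-aggregation (GraphSAGE-style) layers with batch normalization and
dropout produce node embeddings; an MLP scores each concatenated
(drug ‖ target) pair; training minimizes binary cross-entropy with Adam and
early stopping (patience 5) on validation loss.

**Evaluation.** Random 70/10/20 splits, or cold splits where 20% of the
drugs and/or targets are held out with *all* of their interactions in the
test set (the remainder splits 7/8 train, 1/8 validation). Metrics: AUROC,
AUPRC, sensitivity, specificity, averaged over five seeded runs.

## Worked example

`examples/` contains one short script per capability. For instance
`python examples/01_image_topology.py` prints

```
planted ground truth: beta0=3, beta1=1

persistent bars (persistence > 64):
  H0: born    0.0, dies  255.0
  H0: born    0.0, dies  255.0
  H0: born    0.0, dies  255.0  essential
  H1: born    5.2, dies  255.0

Betti numbers at mid-threshold t=130: beta0=3, beta1=1
```

— two planted blobs and one ring give three long-lived components and one
long-lived loop; the ring's hole only fills when its light interior
activates at the top of the filtration. `python
examples/04_planted_benchmark.py` trains the full pipeline on a planted
low-rank interaction dataset and prints

```
held-out metrics, mean +/- sd over 2 runs:
  auroc        0.925 +/- 0.010
  auprc        0.922 +/- 0.028
  sensitivity  0.837 +/- 0.011
  specificity  0.830 +/- 0.018
```

showing the model recovers the planted interaction structure from held-out
pairs. A thin CLI mirrors the library
(`topolink synth|split|featurize|train|evaluate --help`).

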
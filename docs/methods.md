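# Methods

This note records the modelling choices, parameter conventions and known
limitations of `topolink`, in the spirit of a model-description appendix.

## Cubical persistence of images

**Complex.** A pixel grid is modelled with 4-connectivity: pixels are the
vertices of the complex, edges join edge-adjacent pixels, and fully active
2×2 blocks are filled as squares. This "edge-glued" construction makes two
diagonally touching pixels *disconnected* (they share no edge), which is
the convention most people expect from connected-component labelling, and
makes the full rectangle contractible (β0 = 1, β1 = 0 at the final
threshold, asserted for every image in the tests). The Euler characteristic
is computed on the homotopy-equivalent nerve as χ = P − A + Q
(P active pixels, A 4-adjacent active pairs, Q fully active 2×2 blocks).

**Filtration and snapping.** Pixel values are compared with ≤ against a
strictly increasing grid t1 = 0 < … < tN = 255 (default: 50 evenly spaced
values). Because the complex only changes at grid values, births and deaths
are snapped to the grid: a pixel with value γ activates at the smallest
t_m ≥ γ. Non-integer input images are rounded half-up into [0, 255] at
ingestion. A grid not ending at 255 is rejected — pixels above its top
threshold would never activate.

**Algorithm.** H0 is computed by union-find over pixels and edges in
increasing filtration order, with the elder rule (the earlier-born component
survives a merge; ties broken by the smallest linearized root pixel index,
making diagrams byte-deterministic). H1 uses planar duality: loops of the
sublevel complex correspond to connected components of the face-dual graph
(2×2 blocks plus an outer node) under the *reversed* filtration, so a second
union-find sweep in decreasing order pairs each loop-creating edge with the
face value that fills the loop. Bars with zero persistence after snapping
are dropped. The single surviving H0 class is recorded as an *essential*
class with death written as 255 (not ∞), keeping all coordinates finite for
vectorization.

**Liveness convention.** A bar (b, d) is alive at threshold t iff
b ≤ t < d; the essential class additionally counts at t = 255. A
non-essential bar that dies exactly at 255 (a hole filled by the last
activation step) is *not* alive at 255 — otherwise the final-complex
property β1(255) = 0 would be violated. Diagrams therefore carry an explicit
essential flag rather than inferring it from death = 255.

**Validation.** An independent brute-force boundary-matrix reduction over
the full filtered complex (`topolink.reference`) is kept in the package and
must agree exactly (multiset equality per dimension) with the union-find
implementation on random images; Betti curves are additionally checked
against per-threshold component labelling and the Euler identity
β1 = β0 − χ.

## Vectorization

Betti curves use the grid itself (N = 50 entries per dimension). Landscapes
sample λ₁ at the centers of B = 100 equal subintervals of the *global*
domain [0, 255] — a per-diagram domain would make features incomparable
across entities. Only the first landscape level is used. The per-channel
layout is (Betti H0 | Betti H1 | landscape H0 | landscape H1) = 300 values,
channels ordered (gray, red, green, blue) for 1200 total. Grayscale is
ITU-R 601 luminance (0.299R + 0.587G + 0.114B, rounded half-up). Contact
maps are single-channel; they are replicated onto three identical channels
so the same 4-channel pipeline applies to both entity kinds.

## Input adapters

Molecular depiction uses RDKit when available. The built-in fallback is a
deliberately crude deterministic skeletal renderer for a restricted SMILES
subset (atoms, branches flattened onto the backbone, numeric ring closures
drawn as regular polygons): adequate for exercising the topology stack
(a benzene ring yields exactly one long-lived loop), not a chemically
faithful depiction — crossing bonds in multi-ring molecules can create
spurious loops. Mock sequence embeddings are unit-variance Gaussians seeded
by a stable hash of (seed, kind, id), so tables are reproducible and
order-independent. The projection heads are two FC+ReLU layers
(input → 512 → 512); the hidden width equals the output width, the minimal
shape consistent with a two-layer projection into the 512-D latent space.

## Fusion and the gate

One gate per entity kind (drugs, targets). Gates are zero-initialized so
training starts at α = 0.5, exactly the static-fusion baseline. The
Betti-only and landscape-only ablations restrict the topological vector to
the corresponding blocks (400 or 800 columns) *before* projection, leaving
the rest of the architecture unchanged.

## Graph model and training

Message passing uses positive training edges only. Including validation or
test interactions in propagation would leak evaluation information into
node embeddings, so absolute numbers may sit below those of a transductive
variant that propagates over all known edges. Each layer computes, per node
type and direction-specific weights,
h' = ReLU(BN(W_self h + W_nbr · mean of opposite-type neighbours)), widths
512 → 256 → 128; isolated nodes (cold-split holdouts) receive a zero
neighbour mean and fall back to their self term. The pair MLP is
256 → 64 → 1 with a logistic output. Defaults: dropout 0.2, Adam at 1e-3,
mini-batches of 128 supervision edges reshuffled each epoch, at most 100
epochs, early stopping after 5 non-improving validation epochs,
best-validation checkpoint restored. Epochs must be mini-batch passes, not
single full-batch steps: with one gradient step per epoch, patience-5
stopping fires after five steps and checkpoint selection is dominated by
early validation noise, which measurably degrades held-out AUROC.

Batch normalization keeps running statistics for evaluation with
momentum 1.0: every forward pass runs over the *full* node set (only the
loss is mini-batched), so each step's batch statistics are already the
population statistics, and a slow running average would only create a
train/eval mismatch that inflates early validation loss.

Training is implemented on a small in-repo reverse-mode autodiff engine
over numpy arrays (`topolink.autodiff`); gradients are verified against
finite differences in the test suite. Node input features are z-scored
per column before the projection heads (raw Betti counts and landscape
heights differ in scale by orders of magnitude).

## Evaluation protocol

Random splits are exact-floor 70/10/20. Cold splits hold out
round(fraction × #entities) entities (at least one); all their pairs go to
test, the remaining pairs split 7/8 train, 1/8 validation. `cold_both`
additionally holds out a 1/8 share of the remaining entities for
validation, so validation and test entities never appear in any training
pair. AUROC uses the Mann–Whitney convention (ties half credit), AUPRC is
step-interpolated average precision; sensitivity/specificity are measured
at a fixed 0.5 threshold. Reports aggregate mean ± sd over a seed list
(default five) and serialize deterministically, so identical seed lists
give byte-identical reports.

## Synthetic generators

`gen_topo_image` plants dark (≈0) disks and annuli on a light (≈255)
canvas — dark-on-light because the sublevel filtration activates low values
first, matching line drawings of molecules. Shapes are placed on a
jittered grid (one shape per cell), which guarantees disjointness; additive
Gaussian noise is clipped to [0, 255]. Ground truth at a mid-range
threshold: β0 = blobs + rings, β1 = rings, with each ring contributing an
H1 bar of persistence > 128.

`gen_dti_dataset` draws latent vectors u_d, v_t (dimension 8 by default)
and labels the top density-quantile of the noisy inner products u·v as
positives (exactly round(density·n_pairs) of them); negatives are an
equal-count uniform sample of the remainder, matching a balanced benchmark.
Mock sequence embeddings are noisy linear images of the latents
(signal-bearing). The mock topological vectors are *pure noise* by default
(`topo_signal=True` makes them signal-bearing instead): this study
condition asks the fusion gate to discover which modality is informative,
and noise_sd = 0.1 keeps labels strongly determined by the latents (the
inner-product scale is ≈ √8). What the generator does **not** emulate:
realistic chemistry, contact-map statistics, degree heterogeneity, or
correlated assay noise — passing tests demonstrate correct mechanics and
recoverable planted structure, not real-world benchmark performance.

## Observed behaviour of the gate on planted data (negative result)

On the planted benchmark (sequence side signal-bearing, topological side
pure noise) the trained gate's mean α settles slightly *below* 0.5, i.e.
weight drifts toward the noise modality, even though ablations confirm the
sequence modality is the more useful one for held-out prediction
(llm_only 0.899 > static_half 0.892 > top_only 0.784 AUROC at the default
settings). The mechanism:
the gate input is the node's own feature vector, and iid full-rank noise
vectors act as node identifiers, so gradient descent can lower *training*
loss fastest by tailoring per-node weights to the noise — a memorization
pathway the rank-8 signal cannot match. The drift is symmetric (swapping
which modality is noise flips its direction) and robust to mini-batching,
removing batch normalization, weight decay, and extra dropout. The gate is
trained on training loss, not on generalization, and on this adversarial
synthetic contrast the two disagree; on real data, where both modalities
are structured, a gate preferring the stronger modality remains plausible.
The test asserting the intended direction is kept and currently fails, as a
documented known limitation.

## Numerical conventions

Half-up rounding everywhere a real value becomes an 8-bit intensity
(0.5 → 128 when scaling [0,1] contact maps by 255). Nearest-neighbour
resampling for contact maps preserves the value order, hence the
filtration order. Probabilities use numerically stable sigmoid/softplus
forms. All randomness flows through `numpy.random.default_rng` seeded
explicitly; dropout masks derive from the training seed, so loss histories
are exactly reproducible.

## Problem sizes

Default test and acceptance runs use images up to 128×128, oracle
cross-checks on ≤ 10×10 images (where brute-force reduction is exact and
fast), and the 200×150-entity planted benchmark with five seeds; these
sizes make the full suite and the acceptance script each run in about a
minute on one CPU while exercising every code path at full feature widths.
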
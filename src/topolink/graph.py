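"""Heterogeneous drug-target graph, GraphSAGE-style GNN and pair classifier.

The interaction data form a bipartite graph whose nodes carry fused
sequence+topology embeddings.  Message passing uses ONLY positive training
edges: validation and test interactions never contribute to propagation, so
evaluation edges cannot leak into the learned representations.  Each of the
two layers applies, per node type,

    h' = act( BN( W_self h  +  W_nbr mean_{opposite-type neighbours} h ) )

with separate neighbour transforms for the drug->target and target->drug
directions, batch normalization and dropout.  A drug-target pair is scored
by an MLP on the concatenated node embeddings with a logistic output.

The whole stack -- projection heads, fusion gates, GNN, MLP -- is trained
jointly with Adam on binary cross-entropy, with early stopping on the
validation loss and checkpoint restoration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor, concat
from .nn import BatchNorm1d, Dropout, Linear

__all__ = [
    "DTIGraph",
    "ModelConfig",
    "NodeInputs",
    "PairClassifier",
    "EarlyStopping",
    "build_graph",
    "DTIModel",
    "gnn_forward",
    "predict_pairs",
    "train_model",
]

PARTITIONS = ("train", "val", "test")


@dataclass
class NodeInputs:
    """Raw per-node feature matrices, row-aligned with the graph's id lists."""

    drug_llm: np.ndarray    # (n_drugs, 768)
    drug_topo: np.ndarray   # (n_drugs, 1200) or a block-restricted width
    target_llm: np.ndarray  # (n_targets, 1024)
    target_topo: np.ndarray

    @classmethod
    def from_tables(cls, drug_ids, target_ids, drug_llm, drug_topo,
                    target_llm, target_topo) -> "NodeInputs":
        stack = lambda tab, ids: np.vstack([tab[i] for i in ids])
        return cls(stack(drug_llm, drug_ids), stack(drug_topo, drug_ids),
                   stack(target_llm, target_ids), stack(target_topo, target_ids))


@dataclass
class DTIGraph:
    drug_ids: list[str]
    target_ids: list[str]
    message_edges: np.ndarray                    # (m, 2) drug/target indices
    supervision: dict[str, np.ndarray]           # partition -> (k, 3) d, t, label

    def __post_init__(self) -> None:
        self.drug_index = {d: i for i, d in enumerate(self.drug_ids)}
        self.target_index = {t: i for i, t in enumerate(self.target_ids)}
        n_d, n_t = len(self.drug_ids), len(self.target_ids)
        # row-normalized incidence matrices for mean aggregation; isolated
        # nodes keep an all-zero row (empty neighbour mean = zero vector)
        inc = np.zeros((n_d, n_t))
        for d, t in self.message_edges:
            inc[d, t] = 1.0
        deg_d = inc.sum(axis=1, keepdims=True)
        deg_t = inc.sum(axis=0, keepdims=True)
        self.adj_dt = np.divide(inc, deg_d, out=np.zeros_like(inc), where=deg_d > 0)
        self.adj_td = np.divide(inc, deg_t, out=np.zeros_like(inc), where=deg_t > 0).T

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)


def build_graph(split: dict[str, pd.DataFrame], drug_ids=None, target_ids=None) -> DTIGraph:
    """Assemble the graph from labelled pair partitions.

    Message edges are exactly the positive training pairs; validation/test
    edges appear only as supervision.  Raises on ids without features/nodes
    and on overlapping partitions.
    """
    frames = {p: split[p] for p in PARTITIONS if p in split and len(split[p])}
    if "train" not in frames:
        raise ValueError("split must contain a non-empty train partition")
    all_pairs = pd.concat(frames.values(), ignore_index=True)
    keys = [set(map(tuple, frames[p][["drug_id", "target_id"]].to_numpy()))
            for p in frames]
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            overlap = keys[i] & keys[j]
            if overlap:
                raise ValueError(f"partitions overlap on pairs: {sorted(overlap)[:5]}")

    if drug_ids is None:
        drug_ids = sorted(all_pairs["drug_id"].astype(str).unique())
    if target_ids is None:
        target_ids = sorted(all_pairs["target_id"].astype(str).unique())
    d_index = {d: i for i, d in enumerate(drug_ids)}
    t_index = {t: i for i, t in enumerate(target_ids)}
    dangling = sorted(set(all_pairs["drug_id"].astype(str)) - set(d_index)) + \
        sorted(set(all_pairs["target_id"].astype(str)) - set(t_index))
    if dangling:
        raise ValueError(f"supervision edges reference unknown ids: {dangling}")

    supervision = {}
    for part, df in frames.items():
        supervision[part] = np.column_stack([
            df["drug_id"].astype(str).map(d_index).to_numpy(),
            df["target_id"].astype(str).map(t_index).to_numpy(),
            df["label"].to_numpy(dtype=np.int64),
        ])
    train = supervision["train"]
    pos = train[train[:, 2] == 1]
    return DTIGraph(list(drug_ids), list(target_ids),
                    message_edges=pos[:, :2].copy(), supervision=supervision)


@dataclass
class ModelConfig:
    latent: int = 512          # common projected width for both modalities
    hidden1: int = 256         # first GNN layer output width
    hidden2: int = 128         # second GNN layer / node embedding width
    mlp_hidden: int = 64
    dropout: float = 0.2
    lr: float = 1e-3
    batch_size: int = 128      # supervision edges per gradient step
    max_epochs: int = 100
    patience: int = 5
    use_batchnorm: bool = True
    fusion_mode: str = "dynamic"   # dynamic | static_half | top_only | llm_only
    standardize: bool = True       # z-score node inputs before the heads
    seed: int = 0


class _Head:
    """Two FC+ReLU layers projecting one input family to the latent space."""

    def __init__(self, in_dim: int, latent: int, rng):
        self.fc1 = Linear(in_dim, latent, rng)
        self.fc2 = Linear(latent, latent, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu()).relu()

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters()


class _SageLayer:
    """One heterogeneous mean-aggregation layer (both node types)."""

    def __init__(self, in_dim: int, out_dim: int, rng, use_batchnorm: bool,
                 dropout: float):
        self.self_d = Linear(in_dim, out_dim, rng)
        self.nbr_d = Linear(in_dim, out_dim, rng)   # target -> drug direction
        self.self_t = Linear(in_dim, out_dim, rng)
        self.nbr_t = Linear(in_dim, out_dim, rng)   # drug -> target direction
        self.bn_d = BatchNorm1d(out_dim) if use_batchnorm else None
        self.bn_t = BatchNorm1d(out_dim) if use_batchnorm else None
        self.drop = Dropout(dropout)

    def __call__(self, h_d: Tensor, h_t: Tensor, adj_dt: Tensor, adj_td: Tensor,
                 train_mode: bool, rng) -> tuple[Tensor, Tensor]:
        z_d = self.self_d(h_d) + self.nbr_d(adj_dt @ h_t)
        z_t = self.self_t(h_t) + self.nbr_t(adj_td @ h_d)
        if self.bn_d is not None:
            z_d = self.bn_d(z_d, train_mode)
            z_t = self.bn_t(z_t, train_mode)
        z_d, z_t = z_d.relu(), z_t.relu()
        z_d = self.drop(z_d, train_mode, rng)
        z_t = self.drop(z_t, train_mode, rng)
        return z_d, z_t

    def parameters(self):
        ps = (self.self_d.parameters() + self.nbr_d.parameters()
              + self.self_t.parameters() + self.nbr_t.parameters())
        if self.bn_d is not None:
            ps += self.bn_d.parameters() + self.bn_t.parameters()
        return ps


@dataclass
class PairClassifier:
    """MLP weights scoring a concatenated (drug || target) embedding."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray


class DTIModel:
    """End-to-end model: heads -> fusion gates -> 2-layer GNN -> pair MLP."""

    def __init__(self, inputs: NodeInputs, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        L = config.latent

        if config.standardize:
            self._norms = {
                name: (m.mean(axis=0), m.std(axis=0) + 1e-8)
                for name, m in [("drug_llm", inputs.drug_llm),
                                ("drug_topo", inputs.drug_topo),
                                ("target_llm", inputs.target_llm),
                                ("target_topo", inputs.target_topo)]
            }
        else:
            self._norms = None

        self.head_drug_llm = _Head(inputs.drug_llm.shape[1], L, rng)
        self.head_drug_tda = _Head(inputs.drug_topo.shape[1], L, rng)
        self.head_target_llm = _Head(inputs.target_llm.shape[1], L, rng)
        self.head_target_tda = _Head(inputs.target_topo.shape[1], L, rng)
        # zero-initialized gates start at alpha = 0.5 (static baseline)
        self.gate_drug = Linear(2 * L, L, rng, zero_init=True)
        self.gate_target = Linear(2 * L, L, rng, zero_init=True)
        self.sage1 = _SageLayer(L, config.hidden1, rng, config.use_batchnorm,
                                config.dropout)
        self.sage2 = _SageLayer(config.hidden1, config.hidden2, rng,
                                config.use_batchnorm, config.dropout)
        self.mlp1 = Linear(2 * config.hidden2, config.mlp_hidden, rng)
        self.mlp2 = Linear(config.mlp_hidden, 1, rng)
        self.last_alpha: dict[str, np.ndarray] = {}

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for head in (self.head_drug_llm, self.head_drug_tda,
                     self.head_target_llm, self.head_target_tda):
            ps += head.parameters()
        ps += self.gate_drug.parameters() + self.gate_target.parameters()
        ps += self.sage1.parameters() + self.sage2.parameters()
        ps += self.mlp1.parameters() + self.mlp2.parameters()
        return ps

    # -- forward pieces -------------------------------------------------
    def _normed(self, inputs: NodeInputs, name: str) -> Tensor:
        m = getattr(inputs, {"drug_llm": "drug_llm", "drug_topo": "drug_topo",
                             "target_llm": "target_llm",
                             "target_topo": "target_topo"}[name])
        if self._norms is not None:
            mu, sd = self._norms[name]
            m = (m - mu) / sd
        return Tensor(m)

    def fused_features(self, inputs: NodeInputs) -> tuple[Tensor, Tensor]:
        mode = self.config.fusion_mode
        f_llm_d = self.head_drug_llm(self._normed(inputs, "drug_llm"))
        f_tda_d = self.head_drug_tda(self._normed(inputs, "drug_topo"))
        f_llm_t = self.head_target_llm(self._normed(inputs, "target_llm"))
        f_tda_t = self.head_target_tda(self._normed(inputs, "target_topo"))

        def mix(f_llm, f_tda, gate, kind):
            if mode == "dynamic":
                alpha = gate(concat([f_llm, f_tda], axis=1)).sigmoid()
                self.last_alpha[kind] = alpha.data
                return alpha * f_llm + (1.0 - alpha) * f_tda
            if mode == "static_half":
                self.last_alpha[kind] = np.full((f_llm.shape[0], 1), 0.5)
                return 0.5 * f_llm + 0.5 * f_tda
            if mode == "llm_only":
                self.last_alpha[kind] = np.ones((f_llm.shape[0], 1))
                return f_llm
            if mode == "top_only":
                self.last_alpha[kind] = np.zeros((f_llm.shape[0], 1))
                return f_tda
            raise ValueError(f"unknown fusion mode {mode!r}")

        return (mix(f_llm_d, f_tda_d, self.gate_drug, "drug"),
                mix(f_llm_t, f_tda_t, self.gate_target, "target"))

    def node_embeddings(self, inputs: NodeInputs, graph: DTIGraph,
                        train_mode: bool = False,
                        rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        h_d, h_t = self.fused_features(inputs)
        adj_dt, adj_td = Tensor(graph.adj_dt), Tensor(graph.adj_td)
        h_d, h_t = self.sage1(h_d, h_t, adj_dt, adj_td, train_mode, rng)
        h_d, h_t = self.sage2(h_d, h_t, adj_dt, adj_td, train_mode, rng)
        return h_d, h_t

    def pair_logits(self, inputs: NodeInputs, graph: DTIGraph, pairs: np.ndarray,
                    train_mode: bool = False,
                    rng: np.random.Generator | None = None) -> Tensor:
        h_d, h_t = self.node_embeddings(inputs, graph, train_mode, rng)
        z = concat([h_d.take_rows(pairs[:, 0]), h_t.take_rows(pairs[:, 1])], axis=1)
        return self.mlp2(self.mlp1(z).relu())

    def predict_proba(self, inputs: NodeInputs, graph: DTIGraph,
                      pairs: np.ndarray) -> np.ndarray:
        return self.pair_logits(inputs, graph, pairs).sigmoid().data.ravel()

    def pair_classifier(self) -> PairClassifier:
        return PairClassifier(self.mlp1.W.data.copy(), self.mlp1.b.data.copy(),
                              self.mlp2.W.data.copy(), self.mlp2.b.data.copy())

    # -- checkpointing ---------------------------------------------------
    def state(self) -> list[np.ndarray]:
        arrays = [p.data.copy() for p in self.parameters()]
        for layer in (self.sage1, self.sage2):
            for bn in (layer.bn_d, layer.bn_t):
                if bn is not None:
                    arrays += [bn.running_mean.copy(), bn.running_var.copy()]
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, a in zip(params, arrays):
            p.data = a.copy()
        rest = arrays[len(params):]
        k = 0
        for layer in (self.sage1, self.sage2):
            for bn in (layer.bn_d, layer.bn_t):
                if bn is not None:
                    bn.running_mean = rest[k].copy()
                    bn.running_var = rest[k + 1].copy()
                    k += 2


def gnn_forward(graph: DTIGraph, model: DTIModel, inputs: NodeInputs,
                train_mode: bool = False, seed: int = 0):
    """Node embeddings for all drugs and targets (numpy; deterministic in
    eval mode)."""
    rng = np.random.default_rng(seed)
    h_d, h_t = model.node_embeddings(inputs, graph, train_mode, rng)
    return h_d.data, h_t.data


def predict_pairs(drug_emb: dict[str, np.ndarray], target_emb: dict[str, np.ndarray],
                  pairs, classifier: PairClassifier) -> np.ndarray:
    """Interaction probability for each (drug_id, target_id) pair."""
    probs = []
    for d, t in pairs:
        if d not in drug_emb:
            raise KeyError(f"unknown drug id {d!r}")
        if t not in target_emb:
            raise KeyError(f"unknown target id {t!r}")
        z = np.concatenate([drug_emb[d], target_emb[t]])
        h = np.maximum(z @ classifier.W1 + classifier.b1, 0.0)
        logit = (h @ classifier.W2 + classifier.b2).item()
        probs.append(1.0 / (1.0 + np.exp(-logit)) if logit >= 0
                     else np.exp(logit) / (1.0 + np.exp(logit)))
    return np.asarray(probs)


class EarlyStopping:
    """Stop after `patience` consecutive epochs without validation improvement."""

    def __init__(self, patience: int = 5):
        self.patience = patience
        self.best = np.inf
        self.bad_epochs = 0
        self.improved = False

    def update(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; True means stop now."""
        if val_loss < self.best:
            self.best = val_loss
            self.bad_epochs = 0
            self.improved = True
        else:
            self.bad_epochs += 1
            self.improved = False
        return self.bad_epochs >= self.patience


def _bce_from_logits(logits: np.ndarray, labels: np.ndarray) -> float:
    z, y = np.asarray(logits, dtype=np.float64).ravel(), np.asarray(labels, dtype=np.float64)
    return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))


def train_model(graph: DTIGraph, inputs: NodeInputs, config: ModelConfig):
    """Train the end-to-end model with Adam on BCE and early stopping.

    Returns (model, history) where history has one row per epoch with the
    train/validation losses and the mean gate weights of both entity kinds.
    The best-validation checkpoint is restored before returning.
    """
    train = graph.supervision.get("train")
    if train is None or len(train) == 0:
        raise ValueError("cannot train on an empty train split")
    val = graph.supervision.get("val")
    model = DTIModel(inputs, config)
    opt = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    stopper = EarlyStopping(config.patience)

    rows = []
    best_state = model.state()
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train))
        epoch_loss = 0.0
        for start in range(0, len(train), config.batch_size):
            batch = train[order[start:start + config.batch_size]]
            y = Tensor(batch[:, 2].astype(np.float64).reshape(-1, 1))
            opt.zero_grad()
            logits = model.pair_logits(inputs, graph, batch, train_mode=True,
                                       rng=rng)
            loss = (logits.softplus() - logits * y).mean()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
        epoch_loss /= len(train)

        if val is not None and len(val):
            val_logits = model.pair_logits(inputs, graph, val, train_mode=False)
            val_loss = _bce_from_logits(val_logits.data, val[:, 2])
        else:
            val_loss = epoch_loss
        mean_alpha = {k: float(a.mean()) for k, a in model.last_alpha.items()}
        rows.append({
            "epoch": epoch,
            "train_loss": epoch_loss,
            "val_loss": val_loss,
            "mean_alpha_drug": mean_alpha.get("drug", np.nan),
            "mean_alpha_target": mean_alpha.get("target", np.nan),
        })
        stop = stopper.update(val_loss)
        if stopper.improved:
            best_state = model.state()
        if stop:
            break

    model.load_state(best_state)
    return model, pd.DataFrame(rows)
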
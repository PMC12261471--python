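"""Evaluation protocol: random and cold splits, metrics, repeat runs.

Random splits divide labelled pairs 70/10/20 into train/validation/test.
Cold splits hold out a fraction of entities (drugs, targets, or both): every
interaction of a held-out entity goes to the test set, and the remaining
pairs are divided 7/8 train, 1/8 validation, so test-set entities are
provably absent from training.  Metrics are AUROC (Mann-Whitney, ties at
half credit), AUPRC (step-interpolated average precision), and sensitivity/
specificity at a fixed probability threshold.  Experiments are averaged over
several independent seeded runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .graph import ModelConfig, NodeInputs, build_graph, train_model

__all__ = [
    "SplitSpec",
    "MetricReport",
    "UndefinedMetricError",
    "random_split",
    "cold_split",
    "make_split",
    "compute_metrics",
    "run_experiment",
    "training_fraction_sweep",
    "write_split",
    "ExperimentConfig",
]

SPLIT_MODES = ("random", "unseen_drugs", "unseen_targets", "cold_both")


class UndefinedMetricError(ValueError):
    """Metrics are undefined when only one class is present."""


@dataclass(frozen=True)
class SplitSpec:
    mode: str = "random"
    ratios: tuple[float, float, float] = (0.70, 0.10, 0.20)
    holdout_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in SPLIT_MODES:
            raise ValueError(f"unknown split mode {self.mode!r}")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must lie in (0, 1)")


def random_split(pairs: pd.DataFrame, ratios=(0.70, 0.10, 0.20),
                 seed: int = 0) -> dict[str, pd.DataFrame]:
    """Disjoint exhaustive train/val/test partition of labelled pairs."""
    n = len(pairs)
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    if n_train == 0 or n_val == 0 or n - n_train - n_val == 0:
        raise ValueError(f"{n} pairs are too few for a {ratios} split")
    order = np.random.default_rng(seed).permutation(n)
    return {
        "train": pairs.iloc[order[:n_train]].reset_index(drop=True),
        "val": pairs.iloc[order[n_train:n_train + n_val]].reset_index(drop=True),
        "test": pairs.iloc[order[n_train + n_val:]].reset_index(drop=True),
    }


def _holdout(entities: np.ndarray, fraction: float, rng) -> set[str]:
    k = max(1, int(round(fraction * entities.size)))
    return set(rng.choice(entities, size=k, replace=False).tolist())


def cold_split(pairs: pd.DataFrame, mode: str, holdout_fraction: float = 0.20,
               seed: int = 0) -> dict[str, pd.DataFrame]:
    """Entity-cold partition.

    unseen_drugs / unseen_targets: hold out the given fraction of that entity
    kind; all their interactions form the test set; the remaining pairs are
    split 7/8 train, 1/8 validation.  cold_both: hold out both kinds for
    test, and a further 1/8-worth of the remaining entities for validation,
    so validation/test entities never appear in any training pair.
    """
    rng = np.random.default_rng(seed)
    drugs = pairs["drug_id"].astype(str).to_numpy()
    targets = pairs["target_id"].astype(str).to_numpy()

    if mode == "unseen_drugs":
        held = _holdout(np.unique(drugs), holdout_fraction, rng)
        test_mask = np.isin(drugs, list(held))
    elif mode == "unseen_targets":
        held = _holdout(np.unique(targets), holdout_fraction, rng)
        test_mask = np.isin(targets, list(held))
    elif mode == "cold_both":
        held_d = _holdout(np.unique(drugs), holdout_fraction, rng)
        held_t = _holdout(np.unique(targets), holdout_fraction, rng)
        test_mask = np.isin(drugs, list(held_d)) | np.isin(targets, list(held_t))
        rest_d = np.unique(drugs[~test_mask])
        rest_t = np.unique(targets[~test_mask])
        val_d = _holdout(rest_d, 1 / 8, rng)
        val_t = _holdout(rest_t, 1 / 8, rng)
        val_mask = (~test_mask) & (np.isin(drugs, list(val_d))
                                   | np.isin(targets, list(val_t)))
        train = pairs[~test_mask & ~val_mask].reset_index(drop=True)
        if len(train) == 0 or (train["label"] == 1).sum() == 0:
            raise ValueError("cold holdout removed all positive training pairs")
        return {"train": train,
                "val": pairs[val_mask].reset_index(drop=True),
                "test": pairs[test_mask].reset_index(drop=True)}
    else:
        raise ValueError(f"unknown cold-split mode {mode!r}")

    rest = pairs[~test_mask]
    if len(rest) == 0 or (rest["label"] == 1).sum() == 0:
        raise ValueError("cold holdout removed all positive training pairs")
    order = rng.permutation(len(rest))
    n_train = int(np.floor(len(rest) * 7 / 8))
    return {
        "train": rest.iloc[order[:n_train]].reset_index(drop=True),
        "val": rest.iloc[order[n_train:]].reset_index(drop=True),
        "test": pairs[test_mask].reset_index(drop=True),
    }


def make_split(pairs: pd.DataFrame, spec: SplitSpec) -> dict[str, pd.DataFrame]:
    if spec.mode == "random":
        return random_split(pairs, spec.ratios, spec.seed)
    return cold_split(pairs, spec.mode, spec.holdout_fraction, spec.seed)


def write_split(path, split: dict[str, pd.DataFrame]) -> None:
    """TSV with columns drug_id, target_id, label, partition."""
    frames = []
    for part, df in split.items():
        out = df[["drug_id", "target_id", "label"]].copy()
        out["partition"] = part
        frames.append(out)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def compute_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """AUROC, AUPRC, sensitivity and specificity of probability scores."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if labels.min() == labels.max():
        raise UndefinedMetricError("metrics undefined with a single class")
    pred = scores >= threshold
    pos, neg = labels == 1, labels == 0
    return {
        "auroc": float(roc_auc_score(labels, scores)),
        "auprc": float(average_precision_score(labels, scores)),
        "sensitivity": float((pred & pos).sum() / pos.sum()),
        "specificity": float((~pred & neg).sum() / neg.sum()),
    }


@dataclass
class MetricReport:
    per_run: pd.DataFrame            # one row per seed
    mean: dict[str, float]
    sd: dict[str, float]
    n_runs: int

    METRICS = ("auroc", "auprc", "sensitivity", "specificity")

    @classmethod
    def from_runs(cls, rows: list[dict]) -> "MetricReport":
        df = pd.DataFrame(rows)
        mean = {m: float(df[m].mean()) for m in cls.METRICS}
        sd = {m: float(df[m].std(ddof=1)) if len(df) > 1 else 0.0
              for m in cls.METRICS}
        return cls(per_run=df, mean=mean, sd=sd, n_runs=len(df))

    def to_json(self) -> str:
        payload = {
            "n_runs": self.n_runs,
            "mean": self.mean,
            "sd": self.sd,
            "per_run": self.per_run.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class ExperimentConfig:
    """One experiment: a dataset, a split protocol, a model, several seeds."""

    pairs: pd.DataFrame
    inputs_for: "callable"           # (drug_ids, target_ids) -> NodeInputs
    split: SplitSpec = field(default_factory=SplitSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    threshold: float = 0.5


def _single_run(config: ExperimentConfig, seed: int,
                train_subsample: float = 1.0) -> tuple[dict, pd.DataFrame]:
    from dataclasses import replace

    split = make_split(config.pairs, replace(config.split, seed=seed))
    if train_subsample < 1.0:
        tr = split["train"]
        keep = np.random.default_rng(seed).permutation(len(tr))
        keep = keep[: max(1, int(round(train_subsample * len(tr))))]
        tr = tr.iloc[np.sort(keep)].reset_index(drop=True)
        if len(tr) == 0 or tr["label"].min() == tr["label"].max():
            raise UndefinedMetricError(
                f"train fraction {train_subsample} leaves a single-class train set")
        split = {**split, "train": tr}

    drug_ids = sorted(config.pairs["drug_id"].astype(str).unique())
    target_ids = sorted(config.pairs["target_id"].astype(str).unique())
    graph = build_graph(split, drug_ids, target_ids)
    inputs = config.inputs_for(drug_ids, target_ids)
    model_cfg = ModelConfig(**{**config.model.__dict__, "seed": seed})
    model, history = train_model(graph, inputs, model_cfg)

    test = graph.supervision["test"]
    probs = model.predict_proba(inputs, graph, test)
    metrics = compute_metrics(probs, test[:, 2], config.threshold)
    # gate weights of the restored best-validation checkpoint (predict_proba
    # above ran an eval forward, refreshing model.last_alpha)
    metrics.update({
        "seed": seed,
        "epochs": int(history["epoch"].max()),
        "mean_alpha_drug": float(model.last_alpha["drug"].mean()),
        "mean_alpha_target": float(model.last_alpha["target"].mean()),
    })
    return metrics, history


def run_experiment(config: ExperimentConfig,
                   return_histories: bool = False):
    """Train/evaluate once per seed and aggregate mean +/- sd metrics."""
    rows, histories = [], []
    for seed in config.seeds:
        metrics, history = _single_run(config, seed)
        rows.append(metrics)
        histories.append(history)
    report = MetricReport.from_runs(rows)
    if return_histories:
        return report, histories
    return report


def training_fraction_sweep(config: ExperimentConfig,
                            fractions) -> dict[float, MetricReport]:
    """Re-run the experiment with subsampled training partitions.

    Validation and test sets are untouched.  Fractions that leave an empty
    or single-class training set are skipped with a warning.
    """
    import warnings

    out: dict[float, MetricReport] = {}
    for frac in fractions:
        if not 0.0 < frac <= 1.0:
            raise ValueError("training fractions must lie in (0, 1]")
        rows = []
        try:
            for seed in config.seeds:
                metrics, _ = _single_run(config, seed, train_subsample=frac)
                rows.append(metrics)
        except UndefinedMetricError as err:
            warnings.warn(f"skipping fraction {frac}: {err}", stacklevel=2)
            continue
        out[frac] = MetricReport.from_runs(rows)
    return out
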
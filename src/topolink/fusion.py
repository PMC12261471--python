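"""Gated fusion of sequence and topological embeddings.

For one entity with projected sequence embedding f_llm and projected
topological embedding f_tda (both 512-D), a learnable gate computes

    alpha = sigmoid(W [f_llm ; f_tda] + b),      W in R^{512 x 1024}
    f     = alpha * f_llm + (1 - alpha) * f_tda  (elementwise),

so each latent coordinate of the fused embedding is a convex combination of
the two modalities.  One independent gate is kept per entity kind (drugs,
targets).  Zero-initialized gates start at alpha = 0.5, i.e. the static
equal-weight baseline; training moves alpha toward the more informative
modality.  Ablation variants replace the dynamic gate with a fixed rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FusionGate", "fuse", "fuse_variant", "alpha_trace", "FUSION_MODES"]

FUSION_MODES = ("dynamic", "static_half", "top_only", "llm_only")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class FusionGate:
    """Learnable (W, b) producing the per-coordinate mixing weights alpha."""

    W: np.ndarray  # (dim, 2*dim)
    b: np.ndarray  # (dim,)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.W.ndim != 2 or self.W.shape[1] != 2 * self.W.shape[0]:
            raise ValueError("gate W must have shape (dim, 2*dim)")
        if self.b.shape != (self.W.shape[0],):
            raise ValueError("gate b must have shape (dim,)")

    @classmethod
    def zeros(cls, dim: int = 512) -> "FusionGate":
        """Zero initialization: alpha = 0.5 everywhere (the static baseline)."""
        return cls(np.zeros((dim, 2 * dim)), np.zeros(dim))

    @property
    def dim(self) -> int:
        return self.W.shape[0]


def fuse(f_llm: np.ndarray, f_tda: np.ndarray, gate: FusionGate):
    """Dynamic fusion: returns (alpha, fused) for 1-D or batched inputs."""
    f_llm = np.asarray(f_llm, dtype=np.float64)
    f_tda = np.asarray(f_tda, dtype=np.float64)
    if f_llm.shape != f_tda.shape or f_llm.shape[-1] != gate.dim:
        raise ValueError(
            f"fusion inputs must both have width {gate.dim}; "
            f"got {f_llm.shape} and {f_tda.shape}"
        )
    cat = np.concatenate([f_llm, f_tda], axis=-1)
    alpha = _sigmoid(cat @ gate.W.T + gate.b)
    fused = alpha * f_llm + (1.0 - alpha) * f_tda
    return alpha, fused


def fuse_variant(f_llm, f_tda, mode: str, gate: FusionGate | None = None) -> np.ndarray:
    """Fusion ablations.

    dynamic -> gated fusion; static_half -> elementwise mean (alpha = 0.5);
    top_only -> topological embedding; llm_only -> sequence embedding.  The
    Betti-only / landscape-only variants are realized upstream by restricting
    the topological vector blocks before projection (vectorize.restrict_blocks).
    """
    f_llm = np.asarray(f_llm, dtype=np.float64)
    f_tda = np.asarray(f_tda, dtype=np.float64)
    if mode == "dynamic":
        if gate is None:
            raise ValueError("dynamic fusion requires a gate")
        return fuse(f_llm, f_tda, gate)[1]
    if mode == "static_half":
        return 0.5 * f_llm + 0.5 * f_tda
    if mode == "top_only":
        return f_tda.copy()
    if mode == "llm_only":
        return f_llm.copy()
    raise ValueError(f"unknown fusion mode {mode!r}; choose from {FUSION_MODES}")


def alpha_trace(history: pd.DataFrame) -> pd.DataFrame:
    """Per-epoch mean gate weights for drugs and targets from a training log."""
    cols = ["epoch", "mean_alpha_drug", "mean_alpha_target"]
    missing = [c for c in cols if c not in history.columns]
    if missing:
        raise ValueError(f"training history lacks columns {missing}")
    return history[cols].copy()
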
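"""Flat YAML run configuration for the command-line pipeline.

Every constant of the method is a named, overridable key; the defaults are
the pipeline's standard settings (50 thresholds, 100 landscape bins, 512-D
latent space, patience 5, five seeds).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    # data paths (unused keys may stay None in mock mode)
    pairs_path: str | None = None
    image_dir: str | None = None
    contact_map_dir: str | None = None
    drug_embeddings: str | None = None
    target_embeddings: str | None = None
    drug_topo: str | None = None
    target_topo: str | None = None
    mock_seed: int | None = None          # enables mock embeddings when set
    out_dir: str = "runs/latest"

    # topology settings
    n_thresholds: int = 50
    n_bins: int = 100
    image_size: int = 256
    contact_map_size: int = 300

    # split protocol
    split_mode: str = "random"
    train_ratio: float = 0.70
    val_ratio: float = 0.10
    test_ratio: float = 0.20
    holdout_fraction: float = 0.20

    # fusion / model hyperparameters
    fusion_mode: str = "dynamic"
    topo_blocks: str = "all"              # all | betti | landscape
    latent: int = 512
    hidden1: int = 256
    hidden2: int = 128
    mlp_hidden: int = 64
    dropout: float = 0.2
    lr: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 5
    use_batchnorm: bool = True
    threshold: float = 0.5

    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)

    def validate(self) -> "RunConfig":
        if abs(self.train_ratio + self.val_ratio + self.test_ratio - 1.0) > 1e-9:
            raise ConfigError("train/val/test ratios must sum to 1")
        if self.fusion_mode not in ("dynamic", "static_half", "top_only", "llm_only"):
            raise ConfigError(f"unknown fusion mode {self.fusion_mode!r}")
        if self.topo_blocks not in ("all", "betti", "landscape"):
            raise ConfigError(f"unknown topo block selection {self.topo_blocks!r}")
        if self.pairs_path is None and self.mock_seed is None:
            raise ConfigError("either pairs_path or mock_seed must be set")
        if self.pairs_path is not None and not Path(self.pairs_path).exists():
            raise ConfigError(f"pairs file not found: {self.pairs_path}")
        return self

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({**asdict(self), "seeds": list(self.seeds)}, fh,
                           sort_keys=True)


def load_config(path) -> RunConfig:
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except FileNotFoundError as err:
        raise ConfigError(str(err)) from err
    except yaml.YAMLError as err:
        raise ConfigError(f"malformed config: {err}") from err
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "seeds" in raw:
        raw["seeds"] = tuple(raw["seeds"])
    return RunConfig(**raw).validate()
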
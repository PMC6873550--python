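"""Flat run configuration mapping 1:1 onto the model/training symbols.

The configuration file is a flat YAML mapping whose keys mirror the
hyperparameter symbols used throughout (``layers`` l, ``layer_size`` w,
``embedding_size`` m, ``dropout`` d, ``batch_size`` b, ``cell_type``, the
SMILES variant, and the training/sampling knobs).  Unknown keys are
rejected so that typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .model import ModelHyperparams
from .training import TrainConfig
from .variants import VARIANT_KINDS, check_variant


@dataclass(frozen=True)
class RunConfig:
    # architecture (Table-style symbols)
    layers: int = 2
    layer_size: int = 96
    embedding_size: int | None = None
    dropout: float = 0.0
    cell_type: str = "lstm"
    # data / variant
    smiles_variant: str = "randomized_restricted"
    # training
    batch_size: int = 32
    epochs: int = 80
    learning_rate: float = 3e-3
    lr_decay_factor: float = 0.7
    lr_patience: int = 5
    clip_norm: float = 1.0
    ucjsd_sample_size: int = 256
    max_len: int = 64
    augmentation: bool = True
    # evaluation
    sample_size: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        check_variant(self.smiles_variant, VARIANT_KINDS)

    def hyperparams(self, vocab_size: int) -> ModelHyperparams:
        return ModelHyperparams(
            layers=self.layers,
            width=self.layer_size,
            embedding=self.embedding_size,
            dropout=self.dropout,
            cell=self.cell_type,
            vocab_size=vocab_size,
        )

    def train_config(self, seed: int | None = None) -> TrainConfig:
        return TrainConfig(
            batch_size=self.batch_size,
            max_epochs=self.epochs,
            lr_init=self.learning_rate,
            lr_decay_factor=self.lr_decay_factor,
            lr_patience=self.lr_patience,
            clip_norm=self.clip_norm,
            ucjsd_sample_size=self.ucjsd_sample_size,
            max_len=self.max_len,
            seed=self.seed if seed is None else seed,
            augmentation=self.augmentation,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: configuration must be a flat mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)
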
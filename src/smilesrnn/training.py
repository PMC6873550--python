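"""Training orchestration for SMILES sequence models.

Each epoch: (re)generate the epoch's strings (randomized variants get a
fresh writing of every molecule, for the training *and* the validation
set), shuffle, split into minibatches padded with the end token, take
teacher-forced gradient steps with the global gradient norm clipped to
``clip_norm``, then score the epoch by the UC-JSD of equal-length NLL
vectors from the training, validation and freshly sampled sets.

The learning-rate schedule decays by a fixed factor whenever the smoothed
(trailing window of 4) UC-JSD has not improved for ``lr_patience``
consecutive epochs; the best epoch of a finished run is the argmin of the
same smoothed series.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .metrics import NLLTriplet, uc_jsd
from .model import SmilesRNN
from .rngutil import child_seed, rng_for
from .tokenizer import encode_sequence, pad_batch
from .variants import AugmentationPlan, epoch_strings

UCJSD_SMOOTHING_WINDOW = 4


@dataclass(frozen=True)
class TrainConfig:
    """Knobs of one training run."""

    batch_size: int = 128
    max_epochs: int = 10
    lr_init: float = 1e-3
    lr_decay_factor: float = 0.7
    lr_patience: int = 5
    lr_improve_tol: float = 1e-4
    clip_norm: float = 1.0
    ucjsd_sample_size: int = 2048
    max_len: int = 128
    seed: int = 0
    augmentation: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be > 0")
        if not 0 < self.lr_decay_factor < 1:
            raise ValueError("lr_decay_factor must be in (0, 1)")


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    uc_jsd: float
    learning_rate: float
    mean_train_nll: float
    mean_valid_nll: float


@dataclass
class TrainResult:
    model: SmilesRNN
    records: list[EpochRecord]
    snapshots: list[dict[str, np.ndarray]] = field(default_factory=list)
    max_clipped_norm: float = 0.0

    @property
    def uc_jsd_series(self) -> list[float]:
        return [r.uc_jsd for r in self.records]

    @property
    def best_epoch(self) -> int:
        return select_best_epoch(self.uc_jsd_series)

    def restore_best(self) -> SmilesRNN:
        """Load the best epoch's parameters back into the model."""
        if self.snapshots:
            self.model.set_params(self.snapshots[self.best_epoch])
        return self.model


class Adam:
    """Standard adaptive first-order optimizer (default moments)."""

    def __init__(self, params: dict[str, np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p -= (lr * (self.m[k] / bias1) / (np.sqrt(self.v[k] / bias2) + self.eps)).astype(p.dtype)


def clip_gradients(grads: dict[str, np.ndarray], clip_norm: float) -> float:
    """Scale gradients in place so the global norm is at most ``clip_norm``.

    Returns the post-clip global norm.
    """
    total = float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads.values())))
    if total > clip_norm:
        scale = clip_norm / total
        for g in grads.values():
            g *= scale
        return clip_norm
    return total


def smoothed_series(values: Sequence[float], window: int = UCJSD_SMOOTHING_WINDOW) -> list[float]:
    """Trailing moving average; prefix entries use the available history."""
    out = []
    for i in range(len(values)):
        lo = max(0, i - window + 1)
        out.append(float(np.mean(values[lo : i + 1])))
    return out


def select_best_epoch(uc_jsd_series: Sequence[float]) -> int:
    """Argmin of the smoothed UC-JSD series; ties broken by earliest epoch."""
    if len(uc_jsd_series) == 0:
        raise ValueError("empty series")
    sm = smoothed_series(uc_jsd_series)
    return int(np.argmin(sm))  # argmin returns the first minimum


def adaptive_lr_step(
    history: Sequence[EpochRecord] | Sequence[float], current_lr: float, cfg: TrainConfig
) -> float:
    """Learning rate after the latest epoch; decays on smoothed-UC-JSD plateaus.

    If the smoothed UC-JSD has not improved (by more than ``lr_improve_tol``)
    for ``lr_patience`` consecutive epochs, the rate is multiplied by
    ``lr_decay_factor`` once per full patience span; it never increases.
    """
    if len(history) == 0:
        raise ValueError("empty history")
    values = [r.uc_jsd if isinstance(r, EpochRecord) else float(r) for r in history]
    sm = smoothed_series(values)
    best = sm[0]
    since_improve = 0
    for val in sm[1:]:
        if val < best - cfg.lr_improve_tol:
            best = val
            since_improve = 0
        else:
            since_improve += 1
    decays = since_improve // cfg.lr_patience
    return min(current_lr, cfg.lr_init * cfg.lr_decay_factor**decays)


def _nll_subsample(nlls: np.ndarray, size: int, rng) -> np.ndarray:
    if len(nlls) <= size:
        return nlls
    return nlls[rng.choice(len(nlls), size=size, replace=False)]


def train(
    model: SmilesRNN,
    training_smiles: Sequence[str],
    validation_smiles: Sequence[str],
    plan: AugmentationPlan,
    cfg: TrainConfig,
    run_dir: str | Path | None = None,
    keep_snapshots: bool = True,
) -> TrainResult:
    """Run the full training protocol and return per-epoch records.

    The model's vocabulary must cover every string any epoch can produce
    (build it from a union of epoch writings); an out-of-vocabulary token in
    the training or validation set is a hard error, since silently skipping
    strings would corrupt every NLL comparison downstream.
    """
    if len(training_smiles) == 0:
        raise ValueError("empty training set")
    if len(validation_smiles) == 0:
        raise ValueError("empty validation set")
    eff_plan = replace(plan, regenerate_each_epoch=cfg.augmentation)
    optimizer = Adam(model.params)
    records: list[EpochRecord] = []
    result = TrainResult(model, records)
    lr = cfg.lr_init
    run_dir = Path(run_dir) if run_dir is not None else None
    if run_dir is not None:
        run_dir.mkdir(parents=True, exist_ok=True)

    eval_size = min(cfg.ucjsd_sample_size, len(training_smiles), len(validation_smiles))
    for epoch in range(cfg.max_epochs):
        train_strings = epoch_strings(training_smiles, eff_plan, epoch)
        valid_plan = replace(eff_plan, base_seed=child_seed(eff_plan.base_seed, "valid"))
        valid_strings = epoch_strings(validation_smiles, valid_plan, epoch)
        try:
            encoded = [encode_sequence(s, model.vocab) for s in train_strings]
            encoded_valid = [encode_sequence(s, model.vocab) for s in valid_strings]
        except KeyError as exc:
            raise KeyError(
                f"epoch {epoch}: {exc.args[0]} — vocabulary must be built from the "
                "union of all epoch strings"
            ) from None

        shuffle_rng = rng_for(cfg.seed, "shuffle", epoch)
        order = shuffle_rng.permutation(len(encoded))
        drop_rng = rng_for(cfg.seed, "dropout", epoch)
        for lo in range(0, len(order), cfg.batch_size):
            rows = [encoded[i] for i in order[lo : lo + cfg.batch_size]]
            X = pad_batch(rows, model.vocab)
            _, grads = model.loss_and_grads(X, dropout_rng=drop_rng)
            norm = clip_gradients(grads, cfg.clip_norm)
            assert norm <= cfg.clip_norm + 1e-6
            result.max_clipped_norm = max(result.max_clipped_norm, norm)
            optimizer.step(model.params, grads, lr)

        # epoch scoring: equal-length NLL vectors for the three sets
        eval_rng = rng_for(cfg.seed, "ucjsd", epoch)
        train_nll = _nll_subsample(model.encoded_nlls(encoded), eval_size, eval_rng)
        valid_nll = _nll_subsample(model.encoded_nlls(encoded_valid), eval_size, eval_rng)
        sampled = model.sample(
            eval_size, max_len=cfg.max_len, seed=child_seed(cfg.seed, "epoch_sample", epoch)
        )
        sampled_nll = np.array([nll for _, nll, _ in sampled])
        score = uc_jsd(NLLTriplet(train_nll, valid_nll, sampled_nll))
        records.append(
            EpochRecord(
                epoch=epoch,
                uc_jsd=score,
                learning_rate=lr,
                mean_train_nll=float(train_nll.mean()),
                mean_valid_nll=float(valid_nll.mean()),
            )
        )
        if keep_snapshots:
            result.snapshots.append(model.copy_params())
        if run_dir is not None:
            model.save(run_dir / f"epoch_{epoch:04d}.ckpt", epoch=epoch)
        lr = adaptive_lr_step(records, lr, cfg)

    if run_dir is not None:
        write_epoch_log(records, run_dir / "epochs.csv")
    return result


def write_epoch_log(records: Sequence[EpochRecord], path: str | Path) -> None:
    """Epoch log CSV with deterministic 6-decimal formatting."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["epoch", "uc_jsd", "learning_rate", "mean_train_nll", "mean_valid_nll"]
        )
        for r in records:
            writer.writerow(
                [
                    r.epoch,
                    f"{r.uc_jsd:.6f}",
                    f"{r.learning_rate:.6f}",
                    f"{r.mean_train_nll:.6f}",
                    f"{r.mean_valid_nll:.6f}",
                ]
            )
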
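"""Stratified splitting, normalisation and training of the classifier.

The evaluation protocol mirrors a 50/20/30 train/validation/test split
stratified by label (forty balanced subjects give 20/8/12 overall and
10/4/6 per class), per-frequency z-score normalisation fitted on the
training partition only, and full-batch Adam with early stopping on the
validation loss, restoring the best-validation checkpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortDataset
from .nn.autodiff import Tensor, softmax_cross_entropy
from .nn.model import AttentionResNet, NetworkConfig, build_model

__all__ = [
    "PARTITIONS",
    "SplitAssignment",
    "split_dataset",
    "Normalizer",
    "TrainConfig",
    "TrainedClassifier",
    "train_model",
    "save_checkpoint",
    "load_checkpoint",
]

PARTITIONS = ("train", "validation", "test")


@dataclass(frozen=True)
class SplitAssignment:
    """Subject-to-partition map plus the fractions and seed that made it."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int

    def ids(self, partition: str) -> list[str]:
        if partition not in PARTITIONS:
            raise ValueError(f"unknown partition {partition!r}")
        return [sid for sid, p in self.assignment.items() if p == partition]

    def indices(self, cohort: CohortDataset, partition: str) -> np.ndarray:
        wanted = set(self.ids(partition))
        return np.array([i for i, sid in enumerate(cohort.subject_ids) if sid in wanted], dtype=int)

    def sizes(self) -> dict[str, int]:
        return {p: len(self.ids(p)) for p in PARTITIONS}


def _largest_remainder(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Apportion ``n`` items to the fractions; ties favour earlier partitions."""
    quotas = [f * n for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    # stable sort on -remainder keeps train > validation > test on ties
    for idx in sorted(range(len(fractions)), key=lambda i: -remainders[i]):
        if sum(counts) == n:
            break
        counts[idx] += 1
    return counts


def split_dataset(
    cohort: CohortDataset,
    fractions: tuple[float, float, float] = (0.5, 0.2, 0.3),
    seed: int = 0,
) -> SplitAssignment:
    """Deterministic label-stratified train/validation/test assignment.

    Within each class, subjects are shuffled by ``seed`` and apportioned
    by the largest-remainder rule, so 20 subjects per class at
    (0.5, 0.2, 0.3) always give 10/4/6.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("need three positive fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    if len(cohort) == 0:
        raise ValueError("cannot split an empty cohort")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    labels = cohort.labels
    ids = cohort.subject_ids
    for label in sorted(set(labels)):
        class_ids = [str(s) for s in ids[labels == label]]
        order = rng.permutation(len(class_ids))
        counts = _largest_remainder(len(class_ids), fractions)
        cursor = 0
        for partition, count in zip(PARTITIONS, counts):
            for k in order[cursor : cursor + count]:
                assignment[class_ids[k]] = partition
            cursor += count
    return SplitAssignment(assignment=assignment, fractions=fractions, seed=seed)


class Normalizer:
    """Per-frequency (column-wise) z-score fitted on training matrices.

    Impedance magnitudes fall by an order of magnitude across the sweep,
    so each frequency column is standardised with statistics pooled over
    training subjects and electrode pairs.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mean_ is not None

    def fit(self, stacked: np.ndarray) -> "Normalizer":
        """``stacked``: (subjects, pairs, frequencies) training magnitudes."""
        x = np.asarray(stacked, dtype=np.float64)
        if x.ndim != 3 or x.shape[0] == 0:
            raise ValueError("need a non-empty (subjects, pairs, frequencies) array")
        self.mean_ = x.mean(axis=(0, 1))
        std = x.std(axis=(0, 1))
        self.std_ = np.where(std > 0, std, 1.0)
        return self

    def transform(self, stacked: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("Normalizer must be fitted on the training partition first")
        return (np.asarray(stacked, dtype=np.float64) - self.mean_) / self.std_


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (full-batch Adam with early stopping)."""

    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 30
    min_delta: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("learning_rate", "max_epochs", "patience", "min_delta", "beta1", "beta2", "eps")
        }


class _Adam:
    def __init__(self, params: list[Tensor], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        c = self.cfg
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m[:] = c.beta1 * m + (1 - c.beta1) * p.grad
            v[:] = c.beta2 * v + (1 - c.beta2) * p.grad**2
            mhat = m / (1 - c.beta1**self.t)
            vhat = v / (1 - c.beta2**self.t)
            p.data -= c.learning_rate * mhat / (np.sqrt(vhat) + c.eps)


@dataclass
class TrainedClassifier:
    """A fitted model with its normaliser and training history."""

    model: AttentionResNet
    normalizer: Normalizer
    history: pd.DataFrame
    train_config: TrainConfig

    def predict_proba(self, stacked: np.ndarray) -> np.ndarray:
        """Fatty-liver and healthy probabilities for (N, pairs, freqs) input."""
        return self.model.predict_proba(self.normalizer.transform(stacked))

    def predict_scores(self, stacked: np.ndarray) -> np.ndarray:
        """Positive-class (fatty liver) probability per subject."""
        return self.predict_proba(stacked)[:, 1]


def _loss_and_acc(model: AttentionResNet, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    logits = model.forward(Tensor(x[:, None]))
    loss = softmax_cross_entropy(logits, y)
    acc = float((logits.data.argmax(axis=1) == y).mean())
    return float(loss.data), acc


def train_model(
    config: NetworkConfig,
    split: SplitAssignment,
    cohort: CohortDataset,
    hyperparams: TrainConfig | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Train a classifier on the cohort's training partition.

    Full-batch Adam minimises the two-class cross-entropy; after every
    epoch the validation loss is evaluated and the best-validation
    parameters are kept.  Training stops when validation loss has not
    improved by at least ``min_delta`` for ``patience`` consecutive
    epochs.  Deterministic given
    (``config.init_seed``, ``split``, ``seed``).
    """
    hp = hyperparams if hyperparams is not None else TrainConfig()
    stacked = cohort.stack()
    y_all = cohort.y
    idx_train = split.indices(cohort, "train")
    idx_val = split.indices(cohort, "validation")
    if idx_train.size == 0:
        raise ValueError("empty training partition")

    normalizer = Normalizer().fit(stacked[idx_train])
    x_train = normalizer.transform(stacked[idx_train])
    y_train = y_all[idx_train]
    x_val = normalizer.transform(stacked[idx_val]) if idx_val.size else None
    y_val = y_all[idx_val] if idx_val.size else None

    # `seed` is reserved for stochastic training variants (minibatch
    # shuffling, augmentation); full-batch training folds it into the
    # initialisation so distinct seeds still explore distinct optima.
    model = build_model(
        NetworkConfig(**{**config.to_dict(), "init_seed": int(config.init_seed) + int(seed)})
    )
    optimizer = _Adam(model.parameters(), hp)

    records = []
    best_state = model.state_dict()
    best_val = np.inf
    best_epoch = 0
    since_best = 0
    for epoch in range(1, hp.max_epochs + 1):
        model.zero_grad()
        logits = model.forward(Tensor(x_train[:, None]))
        loss = softmax_cross_entropy(logits, y_train)
        loss.backward()
        optimizer.step()

        train_loss = float(loss.data)
        train_acc = float((logits.data.argmax(axis=1) == y_train).mean())
        if x_val is not None:
            val_loss, val_acc = _loss_and_acc(model, x_val, y_val)
        else:
            val_loss, val_acc = train_loss, train_acc
        records.append(
            {"epoch": epoch, "train_loss": train_loss, "train_acc": train_acc, "val_loss": val_loss, "val_acc": val_acc}
        )
        if val_loss < best_val - hp.min_delta:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
            since_best = 0
        else:
            if val_loss < best_val:  # still track the best weights
                best_val = val_loss
                best_state = model.state_dict()
                best_epoch = epoch
            since_best += 1
            if since_best >= hp.patience:
                break

    model.load_state_dict(best_state)
    history = pd.DataFrame.from_records(records)
    history.attrs["best_epoch"] = best_epoch
    return TrainedClassifier(model=model, normalizer=normalizer, history=history, train_config=hp)


def save_checkpoint(trained: TrainedClassifier, path: str | Path) -> None:
    """Serialise weights + network config + normaliser statistics.

    ``path`` gets two files: ``<path>.npz`` (arrays) and ``<path>.json``
    (configs); loading reproduces predictions bitwise.
    """
    path = Path(path)
    arrays = {f"param.{k}": v for k, v in trained.model.state_dict().items()}
    arrays["normalizer.mean"] = trained.normalizer.mean_
    arrays["normalizer.std"] = trained.normalizer.std_
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "network": trained.model.config.to_dict(),
        "training": trained.train_config.to_dict(),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> TrainedClassifier:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arrays = np.load(path.with_suffix(".npz"))
    model = build_model(NetworkConfig.from_dict(meta["network"]))
    state = {k[len("param.") :]: arrays[k] for k in arrays.files if k.startswith("param.")}
    model.load_state_dict(state)
    normalizer = Normalizer()
    normalizer.mean_ = arrays["normalizer.mean"]
    normalizer.std_ = arrays["normalizer.std"]
    return TrainedClassifier(
        model=model,
        normalizer=normalizer,
        history=pd.DataFrame(),
        train_config=TrainConfig(**meta["training"]),
    )
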
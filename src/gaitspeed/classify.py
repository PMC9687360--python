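"""Participant-grouped cross-validation of the biLSTM speed classifier.

Evaluation follows the grouped k-fold protocol: participants — not
patterns — are partitioned into k folds, so no individual contributes to
both the training and the test side of a fold (with 34 participants and
k = 17 each test fold holds exactly two participants, i.e. 24 patterns).
Feature channels are z-scored with statistics computed on the training
patterns only. Accuracy is aggregated over fold-level accuracies (mean and
SD across folds and repeats); training wall time is recorded for reporting
but never asserted on.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field

import numpy as np

from .bilstm import BiLSTMNet, TrainSettings
from .core import SPEED_CLASSES, SpeedClass
from .patterns import CombinationDataset, WalkPattern

__all__ = [
    "BiLstmConfig",
    "CVResult",
    "TrainedModel",
    "make_grouped_folds",
    "train_bilstm",
    "evaluate_accuracy",
    "cross_validate",
]


@dataclass(frozen=True)
class BiLstmConfig:
    """Classifier and training hyperparameters.

    Defaults favour the "simple structure" philosophy: a single biLSTM
    layer (100 units per direction), Adam at 1e-3, batch 16, at most 100
    epochs with early stopping on a training-loss plateau. ``fast()`` gives
    a reduced setting for CPU-bound experiment sweeps.
    """

    hidden_units: int = 100
    n_classes: int = 3
    max_epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    seed: int = 0
    normalization: str = "per_feature_zscore_trainstats"
    early_stop_patience: int = 5
    early_stop_tol: float = 1e-4
    clip_norm: float | None = 2.0
    pool: str = "mean"  # sequence readout: "mean" (time-averaged) or "last"

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.batch_size < 0:
            raise ValueError("batch_size must be >= 0 (0 = full batch)")
        if self.optimizer_name != "adam":
            raise ValueError(f"unsupported optimizer: {self.optimizer_name!r}")
        if self.normalization not in ("per_feature_zscore_trainstats", "none"):
            raise ValueError(f"unknown normalization: {self.normalization!r}")

    @classmethod
    def fast(cls, seed: int = 0) -> "BiLstmConfig":
        """Reduced configuration for desk-scale CPU sweeps.

        Full-batch Adam at a higher learning rate: fewer Python-level
        steps per epoch, and training runs to a genuine loss plateau so
        fold accuracies reflect the data rather than the optimizer.
        """
        return cls(
            hidden_units=16,
            max_epochs=60,
            batch_size=0,
            learning_rate=1e-2,
            seed=seed,
            early_stop_patience=6,
            early_stop_tol=1e-3,
        )

    def train_settings(self) -> TrainSettings:
        return TrainSettings(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            early_stop_patience=self.early_stop_patience,
            early_stop_tol=self.early_stop_tol,
            clip_norm=self.clip_norm,
        )


@dataclass
class TrainedModel:
    """A fitted network plus the training-set normalization statistics."""

    net: BiLSTMNet
    mean: np.ndarray  # (n_features, 1)
    std: np.ndarray  # (n_features, 1)
    classes: tuple[SpeedClass, ...]
    train_seconds: float
    loss_history: list[float]


@dataclass
class CVResult:
    """Cross-validation summary: accuracies as percentages, time in minutes."""

    fold_accuracies: list[float]  # fractions in [0, 1], one per fold x repeat
    n_folds: int
    n_repeats: int
    fold_train_seconds: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.fold_accuracies) != self.n_folds * self.n_repeats:
            raise ValueError("fold_accuracies must have n_folds * n_repeats entries")

    @property
    def mean_accuracy(self) -> float:
        return 100.0 * float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        if len(self.fold_accuracies) < 2:
            return 0.0
        return 100.0 * float(np.std(self.fold_accuracies, ddof=1))

    @property
    def mean_training_time(self) -> float:
        """Mean per-fold training time in minutes (recorded, never asserted)."""
        if not self.fold_train_seconds:
            return 0.0
        return float(np.mean(self.fold_train_seconds)) / 60.0

    @property
    def sd_training_time(self) -> float:
        if len(self.fold_train_seconds) < 2:
            return 0.0
        return float(np.std(self.fold_train_seconds, ddof=1)) / 60.0


def make_grouped_folds(
    dataset: CombinationDataset, k: int = 17, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition participants into k folds; return (train, test) pattern indices.

    Every pattern of a participant lands in exactly one test fold, so the
    test folds partition the dataset and no participant ever spans the
    train/test divide of a fold.
    """
    participants = dataset.participants()
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(participants):
        raise ValueError(f"k={k} exceeds the {len(participants)} distinct participants")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(participants))
    groups = np.array_split(order, k)
    pid_of = np.array([p.participant_id for p in dataset.patterns])
    folds = []
    for grp in groups:
        test_pids = {participants[i] for i in grp}
        test_mask = np.isin(pid_of, sorted(test_pids))
        folds.append((np.flatnonzero(~test_mask), np.flatnonzero(test_mask)))
    return folds


def _stack(patterns: list[WalkPattern]) -> tuple[np.ndarray, np.ndarray]:
    """Patterns -> (B, T, D) array and integer labels in canonical class order."""
    x = np.stack([p.matrix.T for p in patterns])  # (B, T, D)
    label_index = {c: i for i, c in enumerate(SPEED_CLASSES)}
    y = np.array([label_index[p.label] for p in patterns], dtype=int)
    return x, y


def train_bilstm(patterns: list[WalkPattern], config: BiLstmConfig) -> TrainedModel:
    """Fit the biLSTM on a list of walk patterns (z-scored with their own stats)."""
    if not patterns:
        raise ValueError("no training patterns")
    x, y = _stack(patterns)
    present = set(y.tolist())
    if len(present) < config.n_classes:
        missing = [SPEED_CLASSES[i].value for i in range(config.n_classes) if i not in present]
        raise ValueError(f"class(es) missing from training data: {missing}")
    if config.normalization == "per_feature_zscore_trainstats":
        mean = x.mean(axis=(0, 1))
        std = x.std(axis=(0, 1))
        std[std == 0.0] = 1.0
    else:
        mean = np.zeros(x.shape[2])
        std = np.ones(x.shape[2])
    net = BiLSTMNet(
        input_dim=x.shape[2],
        hidden=config.hidden_units,
        n_classes=config.n_classes,
        seed=config.seed,
        pool=config.pool,
    )
    t0 = time.perf_counter()
    history = net.fit((x - mean) / std, y, config.train_settings(), seed=config.seed)
    elapsed = time.perf_counter() - t0
    return TrainedModel(
        net=net,
        mean=mean,
        std=std,
        classes=SPEED_CLASSES[: config.n_classes],
        train_seconds=elapsed,
        loss_history=history,
    )


def evaluate_accuracy(model: TrainedModel, patterns: list[WalkPattern]) -> float:
    """Fraction of patterns classified correctly."""
    x, y = _stack(patterns)
    pred = model.net.predict((x - model.mean) / model.std)
    return float(np.mean(pred == y))


def _derived_seed(seed: int, repeat: int, fold: int) -> int:
    return int(np.random.SeedSequence([seed, repeat, fold]).generate_state(1)[0] % (2**31))


def cross_validate(
    dataset: CombinationDataset,
    config: BiLstmConfig,
    k: int = 17,
    n_repeats: int = 1,
    seed: int = 0,
    fold_seed: int | None = None,
) -> CVResult:
    """Grouped k-fold cross-validation, optionally repeated with fresh shuffles.

    Each repeat reshuffles the participant-to-fold assignment and re-seeds
    the network initialization, so k folds x n_repeats independent
    train/evaluate runs are aggregated (17 x 16 = 272 in the full protocol).

    ``fold_seed`` decouples the participant-to-fold shuffle from ``seed``:
    runs over different feature subsets that share a ``fold_seed`` are
    evaluated on identical partitions, making their accuracies directly
    (pairwise) comparable. Defaults to ``seed``.
    """
    accs: list[float] = []
    times: list[float] = []
    if fold_seed is None:
        fold_seed = seed
    for rep in range(n_repeats):
        folds = make_grouped_folds(dataset, k=k, seed=_derived_seed(fold_seed, rep, 0))
        for f_i, (train_idx, test_idx) in enumerate(folds):
            fold_cfg = dataclasses.replace(config, seed=_derived_seed(seed, rep, f_i + 1))
            model = train_bilstm([dataset.patterns[i] for i in train_idx], fold_cfg)
            accs.append(evaluate_accuracy(model, [dataset.patterns[i] for i in test_idx]))
            times.append(model.train_seconds)
    return CVResult(
        fold_accuracies=accs,
        n_folds=k,
        n_repeats=n_repeats,
        fold_train_seconds=times,
    )
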
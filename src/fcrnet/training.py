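"""Training loop, stratified cross-validation, and the evaluation surfaces.

Metrics follow the motor-imagery benchmarking convention: per-fold accuracy
and Cohen's kappa, a pooled confusion matrix, per-electrode accuracy tables
(the model rebuilt with C=1 per channel), and unweighted means over the
frontal / central / parietal electrode groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .network import Adam, FCRNet, NetworkConfig, assemble_fcrnet
from .simulate import EpochedRecording

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig", "EvaluationReport", "RegionMap", "DEFAULT_REGIONS",
    "train_model", "cross_validate", "cohen_kappa", "confusion_matrix",
    "per_channel_evaluation", "region_average",
]


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 2e-3
    folds: int = 10
    seed: int = 0
    standardize: bool = True

    def validate(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be positive")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class RegionMap:
    """Named electrode groups (disjoint)."""

    regions: dict = field(default_factory=lambda: dict(DEFAULT_REGIONS))

    def validate(self, montage) -> None:
        seen = set()
        for name, channels in self.regions.items():
            if not channels:
                raise ValueError(f"region {name!r} is empty")
            for ch in channels:
                if ch in seen:
                    raise ValueError(f"channel {ch!r} in two regions")
                seen.add(ch)
                if ch not in montage:
                    raise ValueError(f"channel {ch!r} not in montage")


DEFAULT_REGIONS = {
    "frontal": ("Fz", "FC3", "FC1", "FCz", "FC2", "FC4"),
    "central": ("C5", "C3", "C1", "Cz", "C2", "C4", "C6"),
    "parietal": ("CP3", "CP1", "CPz", "CP2", "CP4", "P1", "Pz", "P2", "POz"),
}


@dataclass
class EvaluationReport:
    fold_accuracy: np.ndarray
    fold_kappa: np.ndarray
    confusion: np.ndarray
    pooled_kappa: float
    seed: int
    per_channel: pd.DataFrame = None
    region_means: dict = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracy, ddof=1)) \
            if len(self.fold_accuracy) > 1 else 0.0

    @property
    def mean_kappa(self) -> float:
        return float(np.mean(self.fold_kappa))

    def summary(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_kappa": self.mean_kappa,
            "pooled_kappa": self.pooled_kappa,
            "n_folds": len(self.fold_accuracy),
            "seed": self.seed,
        }


def decimate_epochs(x: np.ndarray, factor: int) -> np.ndarray:
    """Zero-phase anti-aliased downsampling of the time axis.

    Standard input conditioning before the network when the oscillations of
    interest sit far below the recording Nyquist; factor 1 is the identity.
    """
    if factor == 1:
        return x
    from scipy.signal import decimate

    return decimate(x, factor, axis=-1, zero_phase=True)


def _standardize(train: np.ndarray, *others):
    """Per-channel standardization with training-set statistics."""
    mean = train.mean(axis=(0, 2), keepdims=True)
    std = train.std(axis=(0, 2), keepdims=True) + 1e-12
    return tuple((arr - mean) / std for arr in (train,) + others)


def _as_array(data) -> tuple:
    if isinstance(data, EpochedRecording):
        return data.signals, data.labels
    raise TypeError("expected an EpochedRecording or (X, y)")


def train_model(model: FCRNet, x: np.ndarray, y: np.ndarray,
                config: TrainingConfig = TrainingConfig(),
                seed: int = None) -> list:
    """Train in place; returns the per-epoch mean loss history.

    Deterministic given the seed (all shuffling, dropout and the fuzzy-block
    centroid refresh derive from it).  Centroids start at zero and are
    refreshed between epochs by fuzzy c-means over the LSTM outputs collected
    during the preceding epoch.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    logger.info("training: %d trials, %d epochs, seed %d",
                x.shape[0], config.epochs, seed)
    opt = Adam(model.params, lr=config.learning_rate)
    n = x.shape[0]
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        collected = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            model.zero_grads()
            loss, _ = model.loss_and_grads(x[idx], y[idx], training=True,
                                           rng=rng)
            if not np.isfinite(loss):
                last = losses[-1] if losses else float("nan")
                raise TrainingError(
                    f"loss diverged at epoch {epoch} (last finite {last:.4f})"
                )
            opt.step()
            if model.fnb is not None:
                model.fnb.clip_alpha()
                collected.append(model.last_lstm_output.copy())
            losses.append(loss)
        if model.fnb is not None and collected:
            model.refresh_centroids(np.vstack(collected), epoch_index=epoch + 1,
                                    seed=seed + 7919)
        history.append(float(np.mean(losses)))
    return history


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    return cm


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a confusion matrix.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with expected agreement ``p_e`` from
    the marginal products; for balanced K-class marginals this reduces to
    ``(accuracy - 1/K) / (1 - 1/K)``.  A degenerate single-cell matrix (p_e=1)
    yields 0 with a warning.
    """
    cm = np.asarray(confusion, dtype=float)
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be nonnegative")
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm) / total
    p_e = float(np.sum(cm.sum(axis=0) * cm.sum(axis=1)) / total ** 2)
    if np.isclose(p_e, 1.0):
        warnings.warn("degenerate marginals (p_e = 1); kappa defined as 0",
                      stacklevel=2)
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def cross_validate(data, model_factory, k: int = 10, seed: int = 0,
                   training: TrainingConfig = TrainingConfig()) -> EvaluationReport:
    """Stratified k-fold cross-validation; every trial is tested exactly once.

    ``model_factory(fold_seed) -> FCRNet`` builds a fresh model per fold.
    """
    x, y = _as_array(data) if isinstance(data, EpochedRecording) else data
    classes, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class count ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs, kappas = [], []
    pooled = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        x_tr, x_te = x[tr], x[te]
        if training.standardize:
            x_tr, x_te = _standardize(x_tr, x_te)
        model = model_factory(seed * 1000 + fold)
        train_model(model, x_tr, y[tr], training, seed=seed * 1000 + fold)
        pred = model.predict(x_te)
        cm = confusion_matrix(y[te], pred, len(classes))
        pooled += cm
        accs.append(np.mean(pred == y[te]))
        kappas.append(cohen_kappa(cm))
        logger.info("fold %d/%d: accuracy %.3f", fold + 1, k, accs[-1])
    return EvaluationReport(
        fold_accuracy=np.array(accs), fold_kappa=np.array(kappas),
        confusion=pooled, pooled_kappa=cohen_kappa(pooled), seed=seed,
    )


def per_channel_evaluation(recording: EpochedRecording, network: NetworkConfig,
                           channels=None, k: int = 5, seed: int = 0,
                           training: TrainingConfig = TrainingConfig(),
                           ) -> pd.DataFrame:
    """Cross-validated accuracy per single electrode.

    The model is rebuilt with C=1 on each channel's epochs, keeping all other
    hyperparameters; rows are channels plus a ``mean`` row.
    """
    channels = list(recording.channel_names) if channels is None else list(channels)
    rows = {}
    for ch in channels:
        sub = recording.pick_channels([ch])
        cfg = replace(network, input_shape=(1, recording.n_samples))
        report = cross_validate(
            (sub.signals, sub.labels),
            lambda s, cfg=cfg: assemble_fcrnet(cfg, seed=s),
            k=k, seed=seed, training=training,
        )
        rows[ch] = report.mean_accuracy
    table = pd.DataFrame({"accuracy": rows})
    table.loc["mean"] = table["accuracy"].mean()
    return table


def region_average(per_channel: pd.DataFrame,
                   regions: RegionMap = None) -> dict:
    """Unweighted mean of member-channel accuracies per named region."""
    regions = regions or RegionMap()
    out = {}
    for name, channels in regions.regions.items():
        if not channels:
            raise ValueError(f"region {name!r} is empty")
        missing = [c for c in channels if c not in per_channel.index]
        if missing:
            raise KeyError(f"region {name!r}: channels {missing} not in table")
        out[name] = float(per_channel.loc[list(channels), "accuracy"].mean())
    return out
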
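"""Beat / non-beat classifier with a scikit-learn estimator interface.

:class:`BeatValidatorCNN` wraps the NumPy network in a familiar
``fit(X, y)`` / ``predict(X)`` / ``predict_proba(X)`` surface so it
composes with sklearn model selection.  ``X`` is an ``(n, input_len)``
array of raw segment amplitudes (no filtering; optional per-segment
z-scoring behind ``zscore_input``); ``y`` holds labels, either the
strings ``"beat"`` / ``"non_beat"`` or ``{1, 0}``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .augment import Segment
from .nn import ModelSpec, TrainConfig, lr_for_epoch

__all__ = ["BeatValidatorCNN", "segments_to_arrays", "predict_beat_probability",
           "train_validator"]

BEAT, NON_BEAT = 1, 0


def segments_to_arrays(segments: list[Segment]):
    """Stack segments into (X, y, groups) arrays for :meth:`fit`."""
    X = np.stack([s.values for s in segments]).astype(np.float32)
    y = np.asarray([BEAT if s.label == "beat" else NON_BEAT for s in segments])
    groups = np.asarray([s.record_id for s in segments])
    return X, y, groups


class BeatValidatorCNN(BaseEstimator, ClassifierMixin):
    """1D CNN that decides whether a window holds a centered heartbeat.

    Parameters mirror :class:`~ecgseg.nn.ModelSpec` and
    :class:`~ecgseg.nn.TrainConfig`; see those for meaning and defaults.

    Attributes (after ``fit``)
    --------------------------
    model_ : CNNModel
        The trained network.
    history_ : list of dict
        Per-epoch ``{"epoch", "lr", "train_loss", "train_err", "val_loss",
        "val_err"}``.
    classes_ : ndarray
        ``[0, 1]`` (non-beat, beat).
    n_parameters_ : int
    """

    def __init__(self, input_len: int = 300,
                 kernel_widths: tuple[int, ...] = (49, 25, 9, 9),
                 channels: tuple[int, ...] = (32, 32, 64, 64),
                 dense_widths: tuple[int, ...] = (512, 128),
                 dropout: float = 0.5, zscore_input: bool = False,
                 epochs: int = 30,
                 lr_schedule: tuple[tuple[int, float], ...] = (
                     (3, 0.01), (7, 0.005), (10, 0.001), (10, 0.0001)),
                 momentum: float = 0.9, batch_size: int = 256,
                 val_fraction: float = 0.30, decision_threshold: float = 0.5,
                 random_state: int = 0):
        self.input_len = input_len
        self.kernel_widths = kernel_widths
        self.channels = channels
        self.dense_widths = dense_widths
        self.dropout = dropout
        self.zscore_input = zscore_input
        self.epochs = epochs
        self.lr_schedule = lr_schedule
        self.momentum = momentum
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.decision_threshold = decision_threshold
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _spec(self) -> ModelSpec:
        return ModelSpec(input_len=self.input_len,
                         kernel_widths=tuple(self.kernel_widths),
                         channels=tuple(self.channels),
                         dense_widths=tuple(self.dense_widths),
                         dropout=self.dropout, zscore_input=self.zscore_input)

    def _train_cfg(self) -> TrainConfig:
        return TrainConfig(epochs=self.epochs,
                           lr_schedule=tuple(tuple(s) for s in self.lr_schedule),
                           momentum=self.momentum, batch_size=self.batch_size,
                           val_fraction=self.val_fraction, seed=self.random_state)

    @staticmethod
    def _normalize_y(y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "US":
            return np.asarray([BEAT if v == "beat" else NON_BEAT for v in y])
        return y.astype(np.int64)

    def _split(self, y: np.ndarray, groups: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
        """Boolean validation mask, stratified within each (record, label)."""
        val = np.zeros(y.size, dtype=bool)
        for g in np.unique(groups):
            for lbl in (NON_BEAT, BEAT):
                idx = np.flatnonzero((groups == g) & (y == lbl))
                if idx.size == 0:
                    continue
                n_val = int(round(self.val_fraction * idx.size))
                if idx.size > 1:
                    n_val = min(max(n_val, 1), idx.size - 1)
                val[rng.permutation(idx)[:n_val]] = True
        return val

    def fit(self, X, y, groups=None):
        """Train on labelled segments.

        ``groups`` (record ids) controls the stratified 70/30
        train/validation split; without it all samples form one group.
        """
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.input_len:
            raise ValueError(f"X must be (n, {self.input_len}), got {X.shape}")
        y = self._normalize_y(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain both classes")
        if groups is None:
            groups = np.zeros(y.size, dtype=int)
        groups = np.asarray(groups)

        cfg = self._train_cfg()
        rng = np.random.default_rng(cfg.seed)
        model = nn.CNNModel(self._spec(), seed=cfg.seed)

        val_mask = self._split(y, groups, rng)
        Xtr, ytr = X[~val_mask], y[~val_mask]
        Xva, yva = X[val_mask], y[val_mask]

        history = []
        n = Xtr.shape[0]
        for epoch in range(1, cfg.epochs + 1):
            lr = lr_for_epoch(epoch, cfg)
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                b = order[start: start + cfg.batch_size]
                losses.append(model.train_batch(Xtr[b], ytr[b], lr,
                                                cfg.momentum, rng))
            tr_loss, tr_err = self._evaluate(model, Xtr, ytr)
            va_loss, va_err = self._evaluate(model, Xva, yva)
            history.append({"epoch": epoch, "lr": lr,
                            "batch_loss": float(np.mean(losses)),
                            "train_loss": tr_loss, "train_err": tr_err,
                            "val_loss": va_loss, "val_err": va_err})

        self.model_ = model
        self.history_ = history
        self.classes_ = np.array([NON_BEAT, BEAT])
        self.n_parameters_ = model.n_parameters()
        return self

    @staticmethod
    def _evaluate(model: nn.CNNModel, X: np.ndarray, y: np.ndarray,
                  batch: int = 1024) -> tuple[float, float]:
        if X.shape[0] == 0:
            return float("nan"), float("nan")
        losses, wrong = [], 0
        for s in range(0, X.shape[0], batch):
            p = model.predict_proba(X[s: s + batch])
            yy = y[s: s + batch]
            losses.append(-np.log(p[np.arange(yy.size), yy] + 1e-12))
            wrong += int(np.sum(p.argmax(axis=1) != yy))
        return float(np.mean(np.concatenate(losses))), wrong / X.shape[0]

    # ------------------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 1:
            X = X[None, :]
        out = np.empty((X.shape[0], 2), dtype=np.float64)
        for s in range(0, X.shape[0], 1024):
            out[s: s + 1024] = self.model_.predict_proba(X[s: s + 1024])
        return out

    def predict(self, X) -> np.ndarray:
        """1 (beat) iff p(beat) >= decision_threshold, else 0."""
        p = self.predict_proba(X)[:, BEAT]
        return (p >= self.decision_threshold).astype(np.int64)

    # ------------------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        check_is_fitted(self, "model_")
        return nn.save_model(self.model_, path)

    @classmethod
    def load(cls, path: str | Path) -> "BeatValidatorCNN":
        model = nn.load_model(path)
        spec = model.spec
        est = cls(input_len=spec.input_len, kernel_widths=spec.kernel_widths,
                  channels=spec.channels, dense_widths=spec.dense_widths,
                  dropout=spec.dropout, zscore_input=spec.zscore_input)
        est.model_ = model
        est.history_ = []
        est.classes_ = np.array([NON_BEAT, BEAT])
        est.n_parameters_ = model.n_parameters()
        return est


def predict_beat_probability(estimator: BeatValidatorCNN, values: np.ndarray) -> float:
    """Probability that a single model-length window holds a centered beat."""
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 1 or values.size != estimator.input_len:
        raise ValueError(
            f"expected a 1-D window of length {estimator.input_len}, "
            f"got shape {values.shape}")
    return float(estimator.predict_proba(values[None, :])[0, BEAT])


def train_validator(segments: list[Segment], **params) -> BeatValidatorCNN:
    """Fit a validator straight from a list of labelled segments."""
    X, y, groups = segments_to_arrays(segments)
    est = BeatValidatorCNN(**params)
    return est.fit(X, y, groups=groups)
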
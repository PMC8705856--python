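"""Segment-level moving/stationary classification.

The normalized DDR sequence is cut into fixed-width segments of 10 values
(roughly one second of data at the 13-30 Hz event-driven rates of phone
accelerometers).  A stacked bidirectional LSTM labels every segment 0
(stationary) or 1 (moving): wheelchair maneuvers are weak, temporally
extended patterns, and judging one segment reliably requires looking at the
segments before and after it — exactly what a bidirectional recurrence
provides.  A per-segment feed-forward baseline is included for comparison;
lacking temporal context, it produces noisier label streams around bumps
and speed changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neural_network import MLPClassifier

from . import _lstm
from .errors import ConfigurationError, InsufficientDataError, ValidationError
from .io import MOVING, IntervalTruth
from .ddr import NormalizedSequence

DEFAULT_SEGMENT_WIDTH = 10

CHECKPOINT_FORMAT = "wheelbouts-bilstm"
CHECKPOINT_VERSION = 1


@dataclass
class SegmentSeries:
    """Consecutive non-overlapping width-W windows of normalized values."""

    values: np.ndarray  # (n_segments, W)
    start_s: np.ndarray  # time of first sample in each segment
    end_s: np.ndarray  # time of last sample in each segment

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.start_s = np.asarray(self.start_s, dtype=float)
        self.end_s = np.asarray(self.end_s, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("segment values must be 2-D (n_segments, W)")
        n = self.values.shape[0]
        if len(self.start_s) != n or len(self.end_s) != n:
            raise ValidationError("segment time arrays must match segment count")
        if np.any(self.end_s < self.start_s):
            raise ValidationError("segment end before start")
        if n > 1 and np.any(self.start_s[1:] < self.end_s[:-1]):
            raise ValidationError("segments must be ordered and non-overlapping")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class MotionLabels:
    """Binary per-segment labels (0 stationary, 1 moving), optionally with
    classifier probabilities."""

    labels: np.ndarray
    probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be 0 or 1")
        if self.probs is not None:
            self.probs = np.asarray(self.probs, dtype=float)
            if len(self.probs) != len(self.labels):
                raise ValidationError("probs length must match labels")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class TrainConfig:
    """Training protocol knobs (validation split, early stopping)."""

    val_fraction: float = 0.25
    patience_epochs: int = 100
    max_epochs: int = 2000
    learning_rate: float = 1e-3
    chunk_len: int = 50
    seed: int = 0


@dataclass
class ClassifierConfig:
    """Topology + training configuration of the segment classifier."""

    segment_width: int = DEFAULT_SEGMENT_WIDTH
    lstm_layers: int = 2
    hidden_units_per_direction: int = 32
    dense_units: int = 20
    threshold: float = 0.5
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.segment_width < 2:
            raise ConfigurationError("segment_width must be >= 2")
        if self.dense_units < 1:
            raise ConfigurationError("dense_units must be >= 1")
        if not 0 < self.threshold < 1:
            raise ConfigurationError("threshold must be in (0, 1)")
        if not 0 < self.train.val_fraction < 1:
            raise ConfigurationError("val_fraction must be in (0, 1)")


def segment(seq: NormalizedSequence, width: int = DEFAULT_SEGMENT_WIDTH) -> SegmentSeries:
    """Evenly divide the normalized sequence into width-W segments.

    The trailing remainder of fewer than W values is discarded: at 13-30 Hz
    a segment spans about one second, so the precision lost is under one
    second — the same granularity the classifier works at anyway.
    """
    n = len(seq)
    if n < width:
        raise InsufficientDataError(f"need at least {width} values, got {n}")
    k = n // width
    vals = seq.v[: k * width].reshape(k, width)
    t = seq.t_s[: k * width].reshape(k, width)
    return SegmentSeries(values=vals, start_s=t[:, 0], end_s=t[:, -1])


def label_from_truth(segs: SegmentSeries, truth: IntervalTruth) -> MotionLabels:
    """Label a segment 1 iff at least half of its covered time overlaps a
    moving interval (ties go to moving, which favors bout-boundary recall).

    Every segment must be covered by the truth intervals.
    """
    labels = np.zeros(len(segs), dtype=np.int8)
    for i, (s, e) in enumerate(zip(segs.start_s, segs.end_s)):
        span = max(e - s, 1e-12)
        covered = 0.0
        moving = 0.0
        for a, b, st in zip(truth.start_s, truth.end_s, truth.state):
            ov = min(e, b) - max(s, a)
            if ov > 0:
                covered += ov
                if st == MOVING:
                    moving += ov
        if covered < span - 1e-9:
            raise ValidationError(
                f"truth intervals do not cover segment {i} [{s:.3f}, {e:.3f}]"
            )
        labels[i] = 1 if moving / covered >= 0.5 else 0
    return MotionLabels(labels=labels)


def _chunk(X: np.ndarray, y: np.ndarray, L: int):
    """Cut the (temporally ordered) segment stream into full-length
    non-overlapping training sequences; a trailing partial chunk is dropped."""
    k = len(X) // L
    if k == 0:
        raise InsufficientDataError(
            f"need at least {L} segments to form one training sequence"
        )
    return X[: k * L].reshape(k, L, X.shape[1]), y[: k * L].reshape(k, L).astype(float)


class BiLSTMMotionClassifier(ClassifierMixin, BaseEstimator):
    """Bidirectional-LSTM segment labeler (scikit-learn estimator API).

    ``X`` is an (n_segments, segment_width) array of normalized DDR values in
    temporal order; ``y`` the 0/1 motion labels.  Training chunks the stream
    into sequences of ``chunk_len`` segments and minimizes per-timestep
    binary cross-entropy with Adam; the parameters kept are those of the
    epoch with the best validation accuracy, and training stops early once
    the validation accuracy has not improved for ``patience`` epochs.
    Prediction runs the full stream as a single sequence so every segment
    sees its complete temporal context.

    Fully deterministic for a fixed ``random_state``.
    """

    def __init__(
        self,
        segment_width: int = DEFAULT_SEGMENT_WIDTH,
        hidden_units: int = 32,
        n_lstm_layers: int = 2,
        dense_units: int = 20,
        threshold: float = 0.5,
        chunk_len: int = 50,
        val_fraction: float = 0.25,
        patience: int = 100,
        max_epochs: int = 2000,
        learning_rate: float = 1e-3,
        random_state: int | None = 0,
    ):
        self.segment_width = segment_width
        self.hidden_units = hidden_units
        self.n_lstm_layers = n_lstm_layers
        self.dense_units = dense_units
        self.threshold = threshold
        self.chunk_len = chunk_len
        self.val_fraction = val_fraction
        self.patience = patience
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.random_state = random_state

    @classmethod
    def from_config(cls, cfg: ClassifierConfig) -> "BiLSTMMotionClassifier":
        return cls(
            segment_width=cfg.segment_width,
            hidden_units=cfg.hidden_units_per_direction,
            n_lstm_layers=cfg.lstm_layers,
            dense_units=cfg.dense_units,
            threshold=cfg.threshold,
            chunk_len=cfg.train.chunk_len,
            val_fraction=cfg.train.val_fraction,
            patience=cfg.train.patience_epochs,
            max_epochs=cfg.train.max_epochs,
            learning_rate=cfg.train.learning_rate,
            random_state=cfg.train.seed,
        )

    def _validate_cfg(self) -> None:
        if self.segment_width < 2:
            raise ConfigurationError("segment_width must be >= 2")
        if not 0 < self.threshold < 1:
            raise ConfigurationError("threshold must be in (0, 1)")
        if not 0 < self.val_fraction < 1:
            raise ConfigurationError("val_fraction must be in (0, 1)")
        if self.patience < 0 or self.max_epochs < 1:
            raise ConfigurationError("patience >= 0 and max_epochs >= 1 required")

    def _init_params(self) -> dict:
        rng = np.random.default_rng(self.random_state)
        return _lstm.init_params(
            rng, self.segment_width, self.hidden_units, self.n_lstm_layers,
            self.dense_units,
        )

    def build(self) -> "BiLSTMMotionClassifier":
        """Initialize (untrained) network parameters; usable for forward
        passes and determinism checks before any training."""
        self._validate_cfg()
        self.params_ = self._init_params()
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = self.segment_width
        self.n_epochs_ = 0
        self.best_val_accuracy_ = float("nan")
        self.history_ = []
        return self

    def fit(self, X, y, validation: tuple | None = None):
        """Train on the ordered segment stream ``(X, y)``.

        ``validation``: optional ``(X_val, y_val)`` stream used for early
        stopping; when omitted, the trailing ``val_fraction`` of training
        chunks is held out.
        """
        self._validate_cfg()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != self.segment_width:
            raise ValidationError(
                f"X must be (n_segments, {self.segment_width}), got {X.shape}"
            )
        if len(np.unique(y)) < 2:
            raise ValidationError("training data must contain both classes")

        if validation is not None:
            Xv = np.asarray(validation[0], dtype=float)
            yv = np.asarray(validation[1])
            Xtr, ytr = X, y
        else:
            n_val_chunks = max(1, int(round((len(X) // self.chunk_len) * self.val_fraction)))
            cut = len(X) - n_val_chunks * self.chunk_len
            if cut < self.chunk_len:
                raise InsufficientDataError("too few segments for a train/val split")
            Xtr, ytr = X[:cut], y[:cut]
            Xv, yv = X[cut:], y[cut:]
        if len(np.unique(ytr)) < 2:
            raise ValidationError("training split must contain both classes")

        Xc, yc = _chunk(Xtr, ytr, self.chunk_len)
        self.params_ = self._init_params()
        shuffle_rng = np.random.default_rng(
            None if self.random_state is None else [int(self.random_state), 1]
        )
        opt = _lstm.Adam(self.params_, lr=self.learning_rate)
        best = -np.inf
        best_loss = np.inf
        best_params = {k: v.copy() for k, v in self.params_.items()}
        best_epoch = 0
        since_improve = 0
        self.history_ = []
        epoch = 0
        yv_arr = np.asarray(yv, dtype=float)
        for epoch in range(1, self.max_epochs + 1):
            # one Adam step per training sequence, order reshuffled each epoch
            losses = []
            for i in shuffle_rng.permutation(len(Xc)):
                P, cache = _lstm.forward(Xc[i : i + 1], self.params_, self.n_lstm_layers)
                losses.append(_lstm.bce_loss(P, yc[i : i + 1]))
                grads = _lstm.backward(
                    P, yc[i : i + 1], cache, self.params_, self.n_lstm_layers
                )
                opt.step(self.params_, grads)
            loss = float(np.mean(losses))
            pv = self._forward_stream(np.asarray(Xv, dtype=float))
            val_acc = float(np.mean((pv > self.threshold).astype(int) == yv_arr))
            val_loss = _lstm.bce_loss(pv[None], yv_arr[None])
            self.history_.append(
                {"epoch": epoch, "loss": loss, "val_accuracy": val_acc, "val_loss": val_loss}
            )
            # early stopping watches validation accuracy; the parameters kept
            # are from the best epoch, with accuracy ties (the metric is
            # coarsely quantized on a small validation set) broken by
            # validation cross-entropy
            improved_acc = val_acc > best
            if improved_acc or (val_acc == best and val_loss < best_loss):
                best = val_acc
                best_loss = val_loss
                best_params = {k: v.copy() for k, v in self.params_.items()}
                best_epoch = epoch
            if improved_acc:
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= max(self.patience, 1):
                    break
        self.params_ = best_params
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = self.segment_width
        self.n_epochs_ = epoch
        self.best_epoch_ = best_epoch
        self.best_val_accuracy_ = float(best)
        return self

    def _forward_stream(self, X: np.ndarray) -> np.ndarray:
        P, _ = _lstm.forward(X[None], self.params_, self.n_lstm_layers)
        return P[0]

    def _accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        p = self._forward_stream(np.asarray(X, dtype=float))
        return float(np.mean((p > self.threshold).astype(int) == np.asarray(y)))

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.segment_width:
            raise ValidationError(
                f"X must be (n_segments, {self.segment_width}), got {X.shape}"
            )
        if not hasattr(self, "params_"):
            raise ValidationError("classifier is not fitted (call fit or build)")
        p = self._forward_stream(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > self.threshold).astype(np.int8)

    def predict_labels(self, segs: SegmentSeries) -> MotionLabels:
        """Domain-typed prediction over a :class:`SegmentSeries`."""
        if segs.width != self.segment_width:
            raise ValidationError(
                f"segment width {segs.width} != model width {self.segment_width}"
            )
        p = self.predict_proba(segs.values)[:, 1]
        return MotionLabels(labels=(p > self.threshold).astype(np.int8), probs=p)

    def save(self, path) -> None:
        """Save a versioned checkpoint (.npz with a JSON header)."""
        header = json.dumps(
            {
                "format": CHECKPOINT_FORMAT,
                "version": CHECKPOINT_VERSION,
                "config": {
                    k: getattr(self, k)
                    for k in (
                        "segment_width", "hidden_units", "n_lstm_layers",
                        "dense_units", "threshold", "chunk_len", "val_fraction",
                        "patience", "max_epochs", "learning_rate", "random_state",
                    )
                },
            }
        )
        with open(path, "wb") as fh:
            np.savez(fh, __header__=np.array(header), **self.params_)

    @classmethod
    def load(cls, path) -> "BiLSTMMotionClassifier":
        with np.load(path, allow_pickle=False) as data:
            header = json.loads(str(data["__header__"]))
            if header.get("format") != CHECKPOINT_FORMAT:
                raise ValidationError(f"{path}: not a wheelbouts checkpoint")
            if header.get("version") != CHECKPOINT_VERSION:
                raise ValidationError(
                    f"{path}: unsupported checkpoint version {header.get('version')}"
                )
            model = cls(**header["config"])
            model.params_ = {k: data[k] for k in data.files if k != "__header__"}
        model.classes_ = np.array([0, 1])
        model.n_features_in_ = model.segment_width
        return model


class BaselineANNClassifier(ClassifierMixin, BaseEstimator):
    """Per-segment feed-forward baseline (no recurrence).

    Classifies each width-W segment independently with a single hidden
    layer, so its decisions use no temporal context — around bumps and
    abrupt speed changes its label stream is noticeably noisier than the
    recurrent model's.
    """

    def __init__(
        self,
        segment_width: int = DEFAULT_SEGMENT_WIDTH,
        dense_units: int = 20,
        threshold: float = 0.5,
        max_epochs: int = 500,
        random_state: int | None = 0,
    ):
        self.segment_width = segment_width
        self.dense_units = dense_units
        self.threshold = threshold
        self.max_epochs = max_epochs
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != self.segment_width:
            raise ValidationError(
                f"X must be (n_segments, {self.segment_width}), got {X.shape}"
            )
        if len(np.unique(y)) < 2:
            raise ValidationError("training data must contain both classes")
        self._mlp = MLPClassifier(
            hidden_layer_sizes=(self.dense_units,),
            max_iter=self.max_epochs,
            random_state=self.random_state,
        )
        self._mlp.fit(X, y.astype(int))
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = self.segment_width
        return self

    def predict_proba(self, X) -> np.ndarray:
        proba = self._mlp.predict_proba(np.asarray(X, dtype=float))
        if proba.shape[1] == 1:  # degenerate single-class guard
            proba = np.column_stack([1 - proba[:, 0], proba[:, 0]])
        return proba

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > self.threshold).astype(np.int8)

    def predict_labels(self, segs: SegmentSeries) -> MotionLabels:
        p = self.predict_proba(segs.values)[:, 1]
        return MotionLabels(labels=(p > self.threshold).astype(np.int8), probs=p)
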
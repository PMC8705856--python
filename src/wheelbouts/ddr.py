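"""Dynamic differential reference (DDR) preprocessing.

Raw accelerometer readings mix the true acceleration with sensor and
environmental noise that drifts slowly, so consecutive readings share almost
the same noise term.  Differencing consecutive readings per axis therefore
cancels the noise (and gravity, and any constant bias) while preserving the
rapid changes that wheelchair maneuvers produce.  The four steps are:

1. forward-difference each axis,
2. fuse the three differenced axes into a Euclidean magnitude (placement
   invariance: the magnitude is unchanged by axis permutation or sign flip),
3. clip outliers above ``Q3 + 1.5*IQR`` down to that bound,
4. MinMax-scale to [0, 1] so heterogeneous devices land on a common scale.

All statistics (quartiles, min, max) are computed once over the whole
recording — this is an offline batch method, not a streaming one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InsufficientDataError, ValidationError
from .io import RawRecording

IQR_FACTOR = 1.5


@dataclass
class DifferentiatedRecording:
    """Per-axis forward differences; each difference is timestamped at the
    later of the two samples it spans."""

    rx: np.ndarray
    ry: np.ndarray
    rz: np.ndarray
    t_s: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t_s)
        if any(len(a) != n for a in (self.rx, self.ry, self.rz)):
            raise ValidationError("differentiated axes must share one length")
        if n > 1 and np.any(np.diff(self.t_s) <= 0):
            raise ValidationError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_s)


@dataclass
class MagnitudeSequence:
    """Euclidean magnitude of the differenced axes (nonnegative)."""

    d: np.ndarray
    t_s: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.t_s = np.asarray(self.t_s, dtype=float)
        if len(self.d) != len(self.t_s):
            raise ValidationError("magnitude and time lengths differ")
        if np.any(self.d < 0):
            raise ValidationError("magnitudes must be >= 0")

    def __len__(self) -> int:
        return len(self.d)


@dataclass
class OutlierBounds:
    """Quartile summary of a magnitude sequence."""

    q1: float
    q2: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def upper(self) -> float:
        return self.q3 + IQR_FACTOR * self.iqr


@dataclass
class NormalizedSequence:
    """MinMax-scaled magnitude sequence, values in [0, 1]."""

    v: np.ndarray
    t_s: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.t_s = np.asarray(self.t_s, dtype=float)
        if len(self.v) != len(self.t_s):
            raise ValidationError("value and time lengths differ")
        if np.any((self.v < -1e-12) | (self.v > 1 + 1e-12)):
            raise ValidationError("normalized values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.v)


def differentiate(rec: RawRecording) -> DifferentiatedRecording:
    """Forward-difference each axis: out[i] = raw[i+1] - raw[i].

    Differences are taken between consecutive samples regardless of the
    (irregular, event-driven) inter-sample gap; the sample spacing is not a
    rate denominator here.
    """
    if len(rec) < 2:
        raise InsufficientDataError("differentiation needs at least 2 samples")
    return DifferentiatedRecording(
        rx=np.diff(rec.ax),
        ry=np.diff(rec.ay),
        rz=np.diff(rec.az),
        t_s=rec.t_s[1:],
    )


def combine_axes(diff: DifferentiatedRecording) -> MagnitudeSequence:
    """Fuse the three differenced axes into one Euclidean magnitude."""
    d = np.sqrt(diff.rx**2 + diff.ry**2 + diff.rz**2)
    return MagnitudeSequence(d=d, t_s=diff.t_s)


def outlier_bounds(mag: MagnitudeSequence) -> OutlierBounds:
    """Quartiles of the full sequence via linear interpolation of order
    statistics; the clip ceiling is ``Q3 + 1.5*IQR``."""
    if len(mag) < 4:
        raise InsufficientDataError("need at least 4 values for quartiles")
    q1, q2, q3 = np.percentile(mag.d, [25, 50, 75])
    return OutlierBounds(q1=float(q1), q2=float(q2), q3=float(q3))


def clip_outliers(mag: MagnitudeSequence) -> MagnitudeSequence:
    """Replace values above the upper bound with the bound itself.

    Magnitudes are nonnegative so only the upper fence applies.  Bounds are
    computed once on the input, before any replacement.
    """
    upper = outlier_bounds(mag).upper
    return MagnitudeSequence(d=np.minimum(mag.d, upper), t_s=mag.t_s)


def normalize(mag: MagnitudeSequence) -> NormalizedSequence:
    """MinMax-scale to [0, 1]; a constant sequence maps to all zeros
    (a flat differentiated magnitude carries no motion signal)."""
    if len(mag) < 2:
        raise InsufficientDataError("need at least 2 values to normalize")
    lo, hi = float(np.min(mag.d)), float(np.max(mag.d))
    if hi > lo:
        v = (mag.d - lo) / (hi - lo)
    else:
        v = np.zeros_like(mag.d)
    return NormalizedSequence(v=v, t_s=mag.t_s)


def ddr_pipeline(rec: RawRecording) -> NormalizedSequence:
    """Run the four DDR stages in order on a raw recording."""
    if len(rec) < 5:
        raise InsufficientDataError("DDR needs at least 5 samples")
    return normalize(clip_outliers(combine_axes(differentiate(rec))))


class DDRTransformer(TransformerMixin, BaseEstimator):
    """Stateless scikit-learn transformer form of the DDR pipeline.

    ``transform`` accepts an (n, 3) array of tri-axial accelerations (row
    order = time order) and returns an (n-1, 1) column of normalized
    differentiated magnitudes.  All scaling statistics are per-call, so
    ``fit`` is a no-op (as in :class:`sklearn.preprocessing.Normalizer`).
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValidationError("expected an (n, 3) acceleration array")
        self.n_features_in_ = 3
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValidationError("expected an (n, 3) acceleration array")
        if X.shape[0] < 5:
            raise InsufficientDataError("DDR needs at least 5 samples")
        d = np.sqrt((np.diff(X, axis=0) ** 2).sum(axis=1))
        q1, _, q3 = np.percentile(d, [25, 50, 75])
        d = np.minimum(d, q3 + IQR_FACTOR * (q3 - q1))
        lo, hi = d.min(), d.max()
        v = (d - lo) / (hi - lo) if hi > lo else np.zeros_like(d)
        return v[:, None]
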
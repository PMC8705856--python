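"""Rule-based smoothing of the classifier's 0/1 stream.

Three artifacts are repaired, all defined on maximal runs of equal labels:

* **spike** — a short burst of 1s inside a long stationary stretch (an
  external knock while parked); merged into the surrounding 0s.
* **dip** — a short burst of 0s inside a long moving stretch (a hard speed
  change mid-bout); merged into the surrounding 1s.
* **oscillation** — rapid alternation of short runs where a bout starts or
  ends roughly; the wheelchair is mostly moving during such a region, so
  the two thirds of it adjacent to the sustained moving run are assigned to
  moving and the remaining third to stationary.

"Short" means a run of at most ``short_run_max`` segments (default 3, about
3 s at one-second segments); "long" means strictly longer.  Runs touching
the stream boundary are never rewritten by the spike/dip rules — there is
no evidence about what lies beyond the stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .classify import MotionLabels
from .errors import ConfigurationError


@dataclass
class SmoothingConfig:
    short_run_max: int = 3
    oscillation_min_runs: int = 3
    max_passes: int = 10

    def __post_init__(self) -> None:
        if self.short_run_max < 1:
            raise ConfigurationError("short_run_max must be >= 1")
        if self.oscillation_min_runs < 2:
            raise ConfigurationError("oscillation_min_runs must be >= 2")
        if self.max_passes < 1:
            raise ConfigurationError("max_passes must be >= 1")


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encoding: list of (value, start_index, length)."""
    out = []
    n = len(labels)
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        out.append((int(labels[i]), i, j - i))
        i = j
    return out


def _remove_short_runs(labels: np.ndarray, cfg: SmoothingConfig, target: int) -> np.ndarray:
    """Rewrite short target-valued runs flanked by long opposite runs.

    ``target=1`` removes spikes, ``target=0`` removes dips.  Decisions are
    made on the run structure of the input, then applied at once.
    """
    s = cfg.short_run_max
    runs = _runs(labels)
    out = labels.copy()
    for k, (val, start, length) in enumerate(runs):
        if val != target or length > s:
            continue
        if k == 0 or k == len(runs) - 1:
            continue  # boundary runs are never removed
        pv, _, pl = runs[k - 1]
        nv, _, nl = runs[k + 1]
        if pv != target and pl > s and nv != target and nl > s:
            out[start : start + length] = 1 - target
    return out


def remove_spikes(labels: MotionLabels, cfg: SmoothingConfig | None = None) -> MotionLabels:
    """Merge short 1-runs inside long stationary stretches into the 0s."""
    cfg = cfg or SmoothingConfig()
    return MotionLabels(labels=_remove_short_runs(np.asarray(labels.labels), cfg, target=1))


def remove_dips(labels: MotionLabels, cfg: SmoothingConfig | None = None) -> MotionLabels:
    """Merge short 0-runs inside long moving stretches into the 1s."""
    cfg = cfg or SmoothingConfig()
    return MotionLabels(labels=_remove_short_runs(np.asarray(labels.labels), cfg, target=0))


def resolve_oscillations(labels: MotionLabels, cfg: SmoothingConfig | None = None) -> MotionLabels:
    """Rewrite alternation regions at rough bout starts/stops.

    A region is a maximal block of consecutive short runs containing at
    least ``oscillation_min_runs`` runs.  When exactly one of its two
    neighbors is a long moving run, the ``ceil(2L/3)`` segments nearest that
    run become 1 and the rest 0 (L = region length in segments).  Regions
    without that one-sided moving anchor are left for the spike/dip rules.
    """
    cfg = cfg or SmoothingConfig()
    s = cfg.short_run_max
    arr = np.asarray(labels.labels)
    runs = _runs(arr)
    out = arr.copy()
    k = 0
    while k < len(runs):
        if runs[k][2] <= s:
            j = k
            while j < len(runs) and runs[j][2] <= s:
                j += 1
            block = runs[k:j]
            if len(block) >= cfg.oscillation_min_runs:
                left_long_one = k > 0 and runs[k - 1][0] == 1 and runs[k - 1][2] > s
                right_long_one = j < len(runs) and runs[j][0] == 1 and runs[j][2] > s
                if left_long_one != right_long_one:
                    start = block[0][1]
                    L = sum(r[2] for r in block)
                    m = math.ceil(2 * L / 3)
                    region = np.zeros(L, dtype=arr.dtype)
                    if right_long_one:
                        region[L - m :] = 1
                    else:
                        region[:m] = 1
                    out[start : start + L] = region
            k = j
        else:
            k += 1
    return MotionLabels(labels=out)


def smooth(labels: MotionLabels, cfg: SmoothingConfig | None = None) -> MotionLabels:
    """Apply oscillation resolution, then spike and dip removal, iterating
    to a fixpoint (at most ``max_passes`` rounds).

    Oscillations are resolved first: the run-length rules would otherwise
    chew through an alternation region one run at a time and destroy the
    2/3-1/3 geometry.  The result is idempotent.
    """
    cfg = cfg or SmoothingConfig()
    cur = np.asarray(labels.labels)
    for _ in range(cfg.max_passes):
        x = resolve_oscillations(MotionLabels(labels=cur), cfg)
        x = remove_spikes(x, cfg)
        x = remove_dips(x, cfg)
        nxt = np.asarray(x.labels)
        if np.array_equal(nxt, cur):
            break
        cur = nxt
    return MotionLabels(labels=cur)


class LabelSmoother(TransformerMixin, BaseEstimator):
    """scikit-learn transformer form of :func:`smooth` (stateless)."""

    def __init__(self, short_run_max: int = 3, oscillation_min_runs: int = 3,
                 max_passes: int = 10):
        self.short_run_max = short_run_max
        self.oscillation_min_runs = oscillation_min_runs
        self.max_passes = max_passes

    def _cfg(self) -> SmoothingConfig:
        return SmoothingConfig(
            short_run_max=self.short_run_max,
            oscillation_min_runs=self.oscillation_min_runs,
            max_passes=self.max_passes,
        )

    def fit(self, X, y=None):
        self._cfg()  # validates
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X).ravel()
        return np.asarray(smooth(MotionLabels(labels=X), self._cfg()).labels)
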
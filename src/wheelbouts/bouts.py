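"""Bout extraction and mobility metrics.

A mobility bout is a period of continuous wheelchair movement — the unit in
which mobility is measured, since each bout is a transition between
locations.  Bouts come from maximal runs of moving-labeled segments; the
derived metrics are the ones used to summarize a user's activity: number of
bouts, accumulated moving time, and the longest and average continuous
movement periods.
"""

from __future__ import annotations

import numpy as np

from .classify import MotionLabels, SegmentSeries
from .errors import ValidationError
from .io import Bout, MobilityMetrics

DEFAULT_MIN_BOUT_S = 2.0


def extract_bouts(
    labels: MotionLabels,
    segs: SegmentSeries,
    min_bout: float = DEFAULT_MIN_BOUT_S,
) -> list[Bout]:
    """Convert maximal 1-runs into bouts; drop bouts shorter than ``min_bout``.

    A bout spans from the start time of its first segment to the end time of
    its last, so duration granularity equals the segment span (under one
    second of precision loss).
    """
    lab = np.asarray(labels.labels)
    if len(lab) != len(segs):
        raise ValidationError(
            f"labels ({len(lab)}) and segments ({len(segs)}) are misaligned"
        )
    bouts: list[Bout] = []
    i = 0
    n = len(lab)
    while i < n:
        if lab[i] == 1:
            j = i
            while j < n and lab[j] == 1:
                j += 1
            b = Bout(start=float(segs.start_s[i]), end=float(segs.end_s[j - 1]))
            if b.duration >= min_bout:
                bouts.append(b)
            i = j
        else:
            i += 1
    return bouts


def compute_metrics(bouts: list[Bout]) -> MobilityMetrics:
    """Summarize a bout list; an empty list yields all-zero metrics."""
    if not bouts:
        return MobilityMetrics(
            n_bouts=0, accumulated_movement=0.0, max_continuous=0.0, mean_continuous=0.0
        )
    durations = np.array([b.duration for b in bouts])
    return MobilityMetrics(
        n_bouts=len(bouts),
        accumulated_movement=float(durations.sum()),
        max_continuous=float(durations.max()),
        mean_continuous=float(durations.mean()),
    )
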
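"""End-to-end convenience wrapper: raw recording -> bouts and metrics."""

from __future__ import annotations

from dataclasses import dataclass

from .bouts import DEFAULT_MIN_BOUT_S, compute_metrics, extract_bouts
from .classify import BiLSTMMotionClassifier, MotionLabels, SegmentSeries, segment
from .ddr import NormalizedSequence, ddr_pipeline
from .io import Bout, MobilityMetrics, RawRecording
from .postprocess import SmoothingConfig, smooth


@dataclass
class AnalysisResult:
    """Everything the pipeline produced for one recording."""

    normalized: NormalizedSequence
    segments: SegmentSeries
    raw_labels: MotionLabels
    smoothed_labels: MotionLabels
    bouts: list[Bout]
    metrics: MobilityMetrics


def analyze_recording(
    rec: RawRecording,
    model: BiLSTMMotionClassifier,
    smoothing: SmoothingConfig | None = None,
    min_bout: float = DEFAULT_MIN_BOUT_S,
) -> AnalysisResult:
    """Run DDR preprocessing, segment classification, smoothing, and bout
    extraction on one raw recording."""
    smoothing = smoothing or SmoothingConfig()
    norm = ddr_pipeline(rec)
    segs = segment(norm, model.segment_width)
    raw_labels = model.predict_labels(segs)
    smoothed = smooth(raw_labels, smoothing)
    bouts = extract_bouts(smoothed, segs, min_bout=min_bout)
    return AnalysisResult(
        normalized=norm,
        segments=segs,
        raw_labels=raw_labels,
        smoothed_labels=smoothed,
        bouts=bouts,
        metrics=compute_metrics(bouts),
    )
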
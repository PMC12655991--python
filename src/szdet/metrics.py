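"""Evaluation metrics: sample-level confusion counts, accuracy, sensitivity,
per-seizure detection latency, and the false-positive rate normalized per hour.

Accuracy and sensitivity are sample-level:

    accuracy    = 100 * (TP + TN) / (TP + TN + FP + FN)
    sensitivity = 100 * TP / (TP + FN)

where the detector's per-window assertion is expanded so each window's N
samples inherit its value. Latency is signed: ``assert_time - onset``, positive
for detections after the annotated onset; assertions slightly before the
annotation (within a configurable pre-onset tolerance) still count as valid
detections, reflecting the uncertainty of expert onset marks. FPR/h is the
false-positive sample percentage rescaled to one hour of recording.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .detector import DetectionResult, SeizureEvent
from .exceptions import ValidationError
from .signals_io import Annotation, SampleLabels, labels_from_annotation

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "latency",
    "fpr_per_hour",
    "evaluate",
]

DEFAULT_MATCH_TOLERANCE_S = 10.0


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def accuracy_pct(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total

    def sensitivity_pct(self) -> float | None:
        pos = self.tp + self.fn
        return None if pos == 0 else 100.0 * self.tp / pos


@dataclass
class MetricsReport:
    counts: ConfusionCounts
    accuracy_pct: float
    sensitivity_pct: float | None
    latency_s: list[float]
    mean_latency_s: float | None
    fpr_pct_per_h: float | None
    n_seizures_detected: int
    n_seizures_total: int

    def to_dict(self) -> dict:
        return {
            "counts": {
                "tp": self.counts.tp,
                "tn": self.counts.tn,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
            },
            "accuracy_pct": self.accuracy_pct,
            "sensitivity_pct": self.sensitivity_pct,
            "latency_s": self.latency_s,
            "mean_latency_s": self.mean_latency_s,
            "fpr_pct_per_h": self.fpr_pct_per_h,
            "n_seizures_detected": self.n_seizures_detected,
            "n_seizures_total": self.n_seizures_total,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def confusion(asserted_samples: np.ndarray, labels: SampleLabels) -> ConfusionCounts:
    """Sample-level confusion counts between the detector timeline and ground truth."""
    a = np.asarray(asserted_samples, dtype=bool)
    y = labels.labels
    if a.shape != y.shape:
        raise ValidationError(
            f"timeline length {a.size} != label length {y.size}"
        )
    tp = int(np.count_nonzero(a & y))
    fp = int(np.count_nonzero(a & ~y))
    fn = int(np.count_nonzero(~a & y))
    tn = a.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def latency(
    events: list[SeizureEvent],
    ann: Annotation,
    match_tolerance_s: float = DEFAULT_MATCH_TOLERANCE_S,
) -> list[float]:
    """Signed per-seizure latency for every matched seizure.

    Each annotated seizure matches the earliest event asserting inside
    ``[onset - tolerance, offset]``; unmatched seizures yield no entry (they
    are missed detections). An event can match at most one seizure.
    """
    times = sorted(e.assert_time_s for e in events)
    used = [False] * len(times)
    out: list[float] = []
    for onset, offset in ann.intervals:
        for i, t in enumerate(times):
            if not used[i] and onset - match_tolerance_s <= t <= offset:
                out.append(t - onset)
                used[i] = True
                break
    return out


def fpr_per_hour(counts: ConfusionCounts, duration_s: float) -> float | None:
    """False-positive sample percentage normalized to a one-hour recording."""
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    neg = counts.fp + counts.tn
    if neg == 0:
        return None
    return 100.0 * counts.fp / neg * (3600.0 / duration_s)


def evaluate(
    result: DetectionResult,
    ann: Annotation,
    fs: float,
    n_samples: int,
    match_tolerance_s: float = DEFAULT_MATCH_TOLERANCE_S,
) -> MetricsReport:
    """Assemble the full report for one recording.

    Confusion counts are taken over the samples covered by complete analysis
    windows (the detector emits no decision for a trailing partial window).
    """
    n_eval = result.n_windows * result.window_len_N
    n_eval = min(n_eval, n_samples)
    timeline = result.asserted_samples(n_eval)
    labels = labels_from_annotation(ann, fs, n_samples)
    counts = confusion(timeline, SampleLabels(labels.labels[:n_eval]))
    lats = latency(result.events, ann, match_tolerance_s)
    duration_s = n_eval / fs
    return MetricsReport(
        counts=counts,
        accuracy_pct=counts.accuracy_pct(),
        sensitivity_pct=counts.sensitivity_pct(),
        latency_s=lats,
        mean_latency_s=(sum(lats) / len(lats)) if lats else None,
        fpr_pct_per_h=fpr_per_hour(counts, duration_s),
        n_seizures_detected=len(lats),
        n_seizures_total=ann.n_seizures,
    )


def report_to_csv_row(
    report: MetricsReport, patient: str, seizure_index: int
) -> dict:
    """One row in the per-seizure results layout (patient, seizure, accuracy,
    sensitivity, delay, FPR)."""
    return {
        "patient": patient,
        "seizure": seizure_index,
        "accuracy_pct": round(report.accuracy_pct, 2),
        "sensitivity_pct": None
        if report.sensitivity_pct is None
        else round(report.sensitivity_pct, 2),
        "delay_s": report.mean_latency_s,
        "fpr_pct_per_h": None
        if report.fpr_pct_per_h is None
        else round(report.fpr_pct_per_h, 2),
    }
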
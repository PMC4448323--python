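"""Segmentation-quality rates and classification metrics.

Segmentation quality is scored against point annotations (one marker per
nucleus): a fragment with no annotation is over-segmentation, a segment
covering more than one annotation is under-segmentation, and

    correct = 1 - over_seg - under_seg     (exactly, by definition)

with both rates normalized by the total number of annotated nuclei. The
definitions can exceed [0, 1] in pathological cases (more spurious fragments
than nuclei); the unclipped values are canonical and clipped companions are
reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_config import PHASE_ORDER, PhaseLabel, PointAnnotation

logger = logging.getLogger("pcnaphase")


@dataclass
class ConfusionMatrix:
    """Counts indexed by (true, predicted) phase, in PHASE_ORDER."""

    counts: np.ndarray
    class_order: tuple[PhaseLabel, ...] = PHASE_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_order)
        if self.counts.shape != (k, k) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be KxK non-negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MatchResult:
    """Annotation-to-segment assignment for one evaluation."""

    n_annotations: int
    segment_counts: dict[int, int]          # label -> number of annotations
    annotation_segments: list[int]          # per annotation: label (0 = background)
    n_background: int                       # annotations on background (missed nuclei)


@dataclass
class SegmentationEval:
    n_annotations: int
    n_fragments_unmatched: int
    n_multimatched_segments: int
    correct: float
    over_seg: float
    under_seg: float
    correct_clipped: float = field(init=False)

    def __post_init__(self) -> None:
        self.correct_clipped = float(np.clip(self.correct, 0.0, 1.0))


def match_annotations(labels: np.ndarray,
                      annotations: list[PointAnnotation]) -> MatchResult:
    """Assign each annotation to the segment whose label covers its pixel.

    Annotations landing on background are recorded as unmatched (a missed
    nucleus) and logged; they are counted separately, not folded into a rate.
    """
    labels = np.asarray(labels)
    h, w = labels.shape
    counts = {label: 0 for label in range(1, int(labels.max()) + 1)
              if (labels == label).any()}
    ann_segments = []
    n_background = 0
    for a in annotations:
        r = int(round(a.y))
        c = int(round(a.x))
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"annotation ({a.x}, {a.y}) outside image bounds")
        label = int(labels[r, c])
        ann_segments.append(label)
        if label == 0:
            n_background += 1
            logger.info("annotation (%.1f, %.1f) falls on background", a.x, a.y)
        else:
            counts[label] += 1
    return MatchResult(n_annotations=len(annotations), segment_counts=counts,
                       annotation_segments=ann_segments,
                       n_background=n_background)


def segmentation_rates(match: MatchResult) -> SegmentationEval:
    """Over-/under-/correct-segmentation rates from a match result.

    over = fragments without any annotation / n_annotations;
    under = segments with more than one annotation / n_annotations;
    correct = 1 - over - under (may go negative in pathological cases;
    a clipped companion value is attached).
    """
    if match.n_annotations < 1:
        raise ValueError("need at least one annotation")
    unmatched = sum(1 for v in match.segment_counts.values() if v == 0)
    multi = sum(1 for v in match.segment_counts.values() if v >= 2)
    over = unmatched / match.n_annotations
    under = multi / match.n_annotations
    return SegmentationEval(
        n_annotations=match.n_annotations,
        n_fragments_unmatched=unmatched,
        n_multimatched_segments=multi,
        correct=1.0 - over - under,
        over_seg=over,
        under_seg=under,
    )


def precision_recall(cm: ConfusionMatrix
                     ) -> tuple[dict[PhaseLabel, float], dict[PhaseLabel, float], float]:
    """Per-class precision tp/(tp+fp) and recall tp/(tp+fn), plus overall
    accuracy trace/total. A class never predicted gets precision 0 (flagged
    in the log)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts
    precision: dict[PhaseLabel, float] = {}
    recall: dict[PhaseLabel, float] = {}
    for k, cls in enumerate(cm.class_order):
        tp = counts[k, k]
        fp = counts[:, k].sum() - tp
        fn = counts[k, :].sum() - tp
        if tp + fp == 0:
            precision[cls] = 0.0
            logger.warning("class %s never predicted: precision undefined, "
                           "reported as 0", cls.name)
        else:
            precision[cls] = float(tp / (tp + fp))
        recall[cls] = float(tp / (tp + fn)) if tp + fn > 0 else 0.0
    accuracy = float(np.trace(counts) / counts.sum())
    return precision, recall, accuracy


@dataclass
class EvaluationReport:
    confusion: ConfusionMatrix
    precision: dict[PhaseLabel, float]
    recall: dict[PhaseLabel, float]
    accuracy: float
    segmentation: SegmentationEval
    n_excluded_multimatched: int
    n_excluded_unpredicted: int
    n_background_annotations: int

    def to_text(self) -> str:
        lines = ["PCNA phase classification report", ""]
        names = [c.name for c in self.confusion.class_order]
        lines.append("confusion matrix (rows true, cols predicted):")
        lines.append("            " + " ".join(f"{n:>8}" for n in names))
        for i, n in enumerate(names):
            row = " ".join(f"{v:8d}" for v in self.confusion.counts[i])
            lines.append(f"{n:>10}  {row}")
        lines.append("")
        for c in self.confusion.class_order:
            lines.append(f"{c.name:>10}  precision={self.precision[c]:.4f}  "
                         f"recall={self.recall[c]:.4f}")
        lines.append(f"\naccuracy: {self.accuracy:.4f}")
        s = self.segmentation
        lines.append(f"segmentation: correct={s.correct:.4f} "
                     f"over={s.over_seg:.4f} under={s.under_seg:.4f}")
        lines.append(f"excluded: multimatched={self.n_excluded_multimatched} "
                     f"unpredicted={self.n_excluded_unpredicted} "
                     f"background_annotations={self.n_background_annotations}")
        return "\n".join(lines) + "\n"


def evaluate_run(predictions: dict[int, PhaseLabel],
                 annotations: list[PointAnnotation],
                 labels: np.ndarray) -> EvaluationReport:
    """Join predicted segment labels to annotation phases and score the run.

    Multi-matched segments (under-segmentation) and segments without a
    prediction are excluded from the confusion matrix and counted
    separately; segmentation rates are computed on the full match.
    """
    match = match_annotations(labels, annotations)
    seg_eval = segmentation_rates(match)
    k = len(PHASE_ORDER)
    index = {c: i for i, c in enumerate(PHASE_ORDER)}
    counts = np.zeros((k, k), dtype=np.int64)
    n_multi = 0
    n_unpred = 0
    for ann, seg in zip(annotations, match.annotation_segments):
        if seg == 0:
            continue
        if match.segment_counts[seg] >= 2:
            n_multi += 1
            continue
        if seg not in predictions:
            n_unpred += 1
            continue
        counts[index[ann.label], index[predictions[seg]]] += 1
    if counts.sum() == 0:
        raise ValueError("no evaluable annotation/prediction pairs")
    cm = ConfusionMatrix(counts)
    precision, recall, accuracy = precision_recall(cm)
    return EvaluationReport(confusion=cm, precision=precision, recall=recall,
                            accuracy=accuracy, segmentation=seg_eval,
                            n_excluded_multimatched=n_multi,
                            n_excluded_unpredicted=n_unpred,
                            n_background_annotations=match.n_background)


def write_report(report: EvaluationReport, out_dir) -> None:
    """Write report.txt, confusion.csv and rates.csv to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.txt").write_text(report.to_text())
    names = [c.name for c in report.confusion.class_order]
    pd.DataFrame(report.confusion.counts, index=names, columns=names
                 ).to_csv(out / "confusion.csv")
    s = report.segmentation
    pd.DataFrame([{
        "correct": s.correct, "over_seg": s.over_seg, "under_seg": s.under_seg,
        "correct_clipped": s.correct_clipped,
        "n_annotations": s.n_annotations,
        "accuracy": report.accuracy,
    }]).to_csv(out / "rates.csv", index=False)
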
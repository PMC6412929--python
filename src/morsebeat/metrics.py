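"""Identification and verification performance metrics.

Identification (who is this?) is scored as the fraction of correctly
classified beats, CC / (CC + WC). Verification (is this person X?) is a
binary problem scored from the confusion counts:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    FPR         = FP / (TN + FP)
    FNR         = FN / (TP + FN)

plus the ROC curve over the classifier's positive-class score and the
equal error rate (EER), the operating point where FPR = FNR, found by
linear interpolation along the ROC polyline — the standard biometric
summary statistic.

The one-against-all dataset builder mirrors the balanced verification
protocol: one enrolled subject provides the positives, and one beat from
each of the same number of other subjects provides the negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts of a binary decision rule."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ValueError("at least one decision is required")

    @classmethod
    def from_decisions(cls, predicted: np.ndarray,
                       actual: np.ndarray) -> "ConfusionCounts":
        predicted = np.asarray(predicted, dtype=bool)
        actual = np.asarray(actual, dtype=bool)
        return cls(tp=int(np.sum(predicted & actual)),
                   tn=int(np.sum(~predicted & ~actual)),
                   fp=int(np.sum(predicted & ~actual)),
                   fn=int(np.sum(~predicted & actual)))


@dataclass
class IdentificationResult:
    """Correct/wrong classification counts and their accuracy."""

    cc: int
    wc: int
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        if self.cc < 0 or self.wc < 0 or self.cc + self.wc < 1:
            raise ValueError("counts must be >= 0 with at least one trial")
        self.accuracy = self.cc / (self.cc + self.wc)


@dataclass
class VerificationReport:
    """Verification ratios, optionally with ROC points and EER."""

    accuracy: float
    sensitivity: float
    specificity: float
    fpr: float
    fnr: float
    eer: float = float("nan")
    roc: np.ndarray | None = None


def identification_accuracy(cc: int, wc: int) -> IdentificationResult:
    """Accuracy = CC / (CC + WC)."""
    return IdentificationResult(cc=int(cc), wc=int(wc))


def verification_metrics(counts: ConfusionCounts) -> VerificationReport:
    """The five verification ratios from confusion counts."""
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    if pos < 1 or neg < 1:
        raise ValueError("need at least one positive and one negative trial")
    total = pos + neg
    return VerificationReport(
        accuracy=(counts.tp + counts.tn) / total,
        sensitivity=counts.tp / pos,
        specificity=counts.tn / neg,
        fpr=counts.fp / neg,
        fnr=counts.fn / pos,
    )


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(FPR, TPR) points over every decision threshold.

    Higher score means more positive; a decision at threshold t is
    "positive" iff score > t (ties count as negative). Returns an
    (n_points, 2) array ordered from the strictest threshold, (0, 0), to
    the laxest, (1, 1).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    if labels.min() == labels.max():
        raise ValueError("need at least one positive and one negative label")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def equal_error_rate(roc: np.ndarray) -> float:
    """FPR at the ROC point where FPR equals FNR (= 1 - TPR).

    The crossing is located by linear interpolation between the adjacent
    ROC points straddling the FPR = FNR diagonal. Invariant under any
    strictly monotone rescaling of the scores (the ROC itself is).
    """
    roc = np.asarray(roc, dtype=np.float64)
    fpr, tpr = roc[:, 0], roc[:, 1]
    diff = fpr - (1.0 - tpr)  # fpr - fnr, nondecreasing along the curve
    if diff[0] >= 0:
        return float(fpr[0])
    if diff[-1] <= 0:
        return float(fpr[-1])
    k = int(np.searchsorted(diff > 0, True))  # first point past the diagonal
    d0, d1 = diff[k - 1], diff[k]
    t = -d0 / (d1 - d0)
    return float(fpr[k - 1] + t * (fpr[k] - fpr[k - 1]))


def verification_report(scores: np.ndarray, labels: np.ndarray,
                        threshold: float = 0.5) -> VerificationReport:
    """Full report: thresholded counts, ROC points and EER.

    Decisions use the strictly-greater rule (score > threshold is a
    positive decision).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    counts = ConfusionCounts.from_decisions(scores > threshold, labels)
    report = verification_metrics(counts)
    report.roc = roc_curve(scores, labels.astype(int))
    report.eer = equal_error_rate(report.roc)
    return report


def build_one_against_all(beats: np.ndarray, labels: np.ndarray,
                          positive_subject,
                          samples_per_person: int = 60
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Balanced binary verification dataset.

    The positive class takes the first ``samples_per_person`` beats of
    ``positive_subject``; the negative class takes the first beat of
    each of ``samples_per_person`` distinct other subjects (in label
    order — deterministic). Returns (items, binary_labels) with 1 for
    the enrolled subject.
    """
    beats = np.asarray(beats)
    labels = np.asarray(labels)
    if beats.shape[0] != labels.shape[0]:
        raise ValueError("beats and labels disagree in length")
    pos_idx = np.flatnonzero(labels == positive_subject)
    if pos_idx.size < samples_per_person:
        raise ValueError(
            f"subject {positive_subject!r} has {pos_idx.size} beats; "
            f"need {samples_per_person}")
    others = [s for s in np.unique(labels) if s != positive_subject]
    if len(others) < samples_per_person:
        raise ValueError(
            f"need {samples_per_person} other subjects, have {len(others)}")
    neg_idx = np.array([np.flatnonzero(labels == s)[0]
                        for s in others[:samples_per_person]])
    idx = np.concatenate([pos_idx[:samples_per_person], neg_idx])
    y = np.concatenate([np.ones(samples_per_person, dtype=np.intp),
                        np.zeros(samples_per_person, dtype=np.intp)])
    return beats[idx], y
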
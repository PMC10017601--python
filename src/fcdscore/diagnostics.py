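"""Diagnostic accuracy of the composite score against the surgical gold standard.

Confusion tables at strict cutoffs, per-cutoff sensitivity/specificity/
Youden rows, ROC points and AUC (trapezoid and tie-corrected rank forms,
cross-checked), optimal-cutoff selection, and predictive values.

Orientation convention: the canonical positive class is *dehiscent* (the
condition sought).  Because published two-by-two summaries of this design
are sometimes labeled with intact as positive, every summary can also be
rendered under the swapped orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import UndefinedMetricError, ValidationError

N_SCORES = 7  # composite scores 0..6


@dataclass(frozen=True)
class GroupScoreDistribution:
    """Counts of composite scores 0..6 within one surgical group."""

    group: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_SCORES,):
            raise ValidationError(
                f"score distribution needs {N_SCORES} counts, got shape {counts.shape}"
            )
        if (counts < 0).any():
            raise ValidationError("score counts must be non-negative")
        if counts.sum() <= 0:
            raise ValidationError("score distribution must contain at least one ear")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_scores(cls, group: str, scores: Sequence[int]) -> "GroupScoreDistribution":
        counts = np.bincount(np.asarray(scores, dtype=np.int64), minlength=N_SCORES)
        if counts.shape[0] > N_SCORES:
            raise ValidationError("composite scores must lie in 0..6")
        return cls(group, counts)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: int
    positive_label: str = "dehiscent"

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def swapped(self) -> "ConfusionCounts":
        """The same table with the positive class reversed."""
        other = "intact" if self.positive_label == "dehiscent" else "dehiscent"
        return ConfusionCounts(
            tp=self.tn, fp=self.fn, tn=self.tp, fn=self.fp,
            cutoff=self.cutoff, positive_label=other,
        )


@dataclass(frozen=True)
class DiagnosticRow:
    cutoff: int
    sensitivity: float
    specificity: float

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class DiagnosticSummary:
    ppv: Optional[float]
    npv: Optional[float]
    fnr: Optional[float]
    fpr: Optional[float]
    accuracy: Optional[float]
    auc: Optional[float]
    positive_label: str = "dehiscent"

    def to_dict(self) -> dict:
        return {
            "ppv": self.ppv, "npv": self.npv, "fnr": self.fnr, "fpr": self.fpr,
            "accuracy": self.accuracy, "auc": self.auc,
            "positive_label": self.positive_label,
        }


def confusion_at_cutoff(
    dist_pos: GroupScoreDistribution,
    dist_neg: GroupScoreDistribution,
    cutoff: int,
) -> ConfusionCounts:
    """Confusion counts for the rule ``score < cutoff => positive (dehiscent)``."""
    if not 0 <= int(cutoff) <= 7:
        raise ValidationError(f"cutoff must be in 0..7, got {cutoff!r}")
    c = int(cutoff)
    tp = int(dist_pos.counts[:c].sum())
    fp = int(dist_neg.counts[:c].sum())
    return ConfusionCounts(
        tp=tp, fp=fp, fn=dist_pos.n - tp, tn=dist_neg.n - fp, cutoff=c
    )


def metrics_table(
    dist_pos: GroupScoreDistribution, dist_neg: GroupScoreDistribution
) -> list[DiagnosticRow]:
    """Sensitivity/specificity/Youden for strict cutoffs 0..6, dehiscent-positive."""
    rows = []
    for c in range(N_SCORES):
        conf = confusion_at_cutoff(dist_pos, dist_neg, c)
        rows.append(
            DiagnosticRow(
                cutoff=c,
                sensitivity=conf.tp / dist_pos.n,
                specificity=conf.tn / dist_neg.n,
            )
        )
    return rows


def swapped_metrics_table(
    dist_pos: GroupScoreDistribution, dist_neg: GroupScoreDistribution
) -> list[DiagnosticRow]:
    """Companion rendering with intact treated as the positive class."""
    return [
        DiagnosticRow(cutoff=r.cutoff, sensitivity=r.specificity, specificity=r.sensitivity)
        for r in metrics_table(dist_pos, dist_neg)
    ]


def roc_points(
    dist_pos: GroupScoreDistribution, dist_neg: GroupScoreDistribution
) -> list[tuple[float, float]]:
    """ROC staircase for cutoffs 0..7, anchored at (0,0) and (1,1)."""
    pts = []
    for c in range(N_SCORES + 1):
        conf = confusion_at_cutoff(dist_pos, dist_neg, c)
        pts.append((conf.fp / dist_neg.n, conf.tp / dist_pos.n))
    return sorted(pts)


def auc(
    dist_pos: GroupScoreDistribution, dist_neg: GroupScoreDistribution
) -> float:
    """AUC of the composite score, lower scores indicating the positive class.

    Computed both as the trapezoidal integral of the ROC staircase and as
    the tie-corrected rank statistic P(S_pos < S_neg) + P(S_pos = S_neg)/2;
    the two must agree to 1e-10.
    """
    if dist_pos.n == 0 or dist_neg.n == 0:
        raise UndefinedMetricError("AUC undefined for an empty group")
    pts = np.asarray(roc_points(dist_pos, dist_neg))
    trap = float(np.trapezoid(pts[:, 1], pts[:, 0]))

    pos = dist_pos.counts.astype(float)
    neg = dist_neg.counts.astype(float)
    wins = float(np.triu(np.outer(pos, neg), k=1).sum())  # S_pos < S_neg
    ties = float(pos @ neg)
    rank = (wins + 0.5 * ties) / (dist_pos.n * dist_neg.n)

    if abs(trap - rank) > 1e-10:
        raise AssertionError(
            f"trapezoid ({trap!r}) and rank ({rank!r}) AUC forms disagree"
        )
    return rank


def optimal_cutoff(rows: Sequence[DiagnosticRow]) -> int:
    """Cutoff maximizing Youden's index; ties prefer higher specificity, then lower cutoff."""
    if not rows:
        raise ValidationError("optimal_cutoff requires at least one row")
    best = min(rows, key=lambda r: (-r.youden, -r.specificity, r.cutoff))
    return best.cutoff


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def diagnostic_summary(
    conf: ConfusionCounts, auc_value: Optional[float] = None
) -> DiagnosticSummary:
    """Predictive values and rates from a confusion table.

    Metrics with a zero denominator are reported as None rather than NaN.
    """
    if conf.total <= 0:
        raise ValidationError("confusion table is empty")
    return DiagnosticSummary(
        ppv=_ratio(conf.tp, conf.tp + conf.fp),
        npv=_ratio(conf.tn, conf.tn + conf.fn),
        fnr=_ratio(conf.fn, conf.fn + conf.tp),
        fpr=_ratio(conf.fp, conf.fp + conf.tn),
        accuracy=(conf.tp + conf.tn) / conf.total,
        auc=auc_value,
        positive_label=conf.positive_label,
    )


def summary_both_orientations(
    dist_pos: GroupScoreDistribution,
    dist_neg: GroupScoreDistribution,
    cutoff: int,
) -> dict[str, DiagnosticSummary]:
    """Dehiscent-positive and intact-positive summaries side by side."""
    conf = confusion_at_cutoff(dist_pos, dist_neg, cutoff)
    a = auc(dist_pos, dist_neg)
    # AUC is direction-adjusted, hence identical under either labeling.
    return {
        "dehiscent_positive": diagnostic_summary(conf, a),
        "intact_positive": diagnostic_summary(conf.swapped(), a),
    }
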
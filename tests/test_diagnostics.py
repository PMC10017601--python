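"""Diagnostic-accuracy operations, with a brute-force pair-enumeration AUC oracle."""

from fractions import Fraction

import numpy as np
import pytest

from fcdscore.diagnostics import (
    ConfusionCounts,
    GroupScoreDistribution,
    auc,
    confusion_at_cutoff,
    diagnostic_summary,
    metrics_table,
    optimal_cutoff,
    roc_points,
    summary_both_orientations,
    swapped_metrics_table,
)
from fcdscore.errors import UndefinedMetricError, ValidationError

from conftest import random_distribution


def brute_force_auc(dist_pos, dist_neg) -> Fraction:
    """Oracle: explicit loop over every (positive, negative) ear pair."""
    pos = [s for s in range(7) for _ in range(int(dist_pos.counts[s]))]
    neg = [s for s in range(7) for _ in range(int(dist_neg.counts[s]))]
    score = Fraction(0)
    for a in pos:
        for b in neg:
            if a < b:
                score += 1
            elif a == b:
                score += Fraction(1, 2)
    return score / (len(pos) * len(neg))


class TestConfusion:
    def test_reconstructed_distributions_at_cutoff_4(self, dist_fcd, dist_control):
        conf = confusion_at_cutoff(dist_fcd, dist_control, 4)
        assert (conf.tp, conf.fn, conf.fp, conf.tn) == (27, 2, 2, 9)

    def test_cutoff_0_nothing_positive(self, dist_fcd, dist_control):
        conf = confusion_at_cutoff(dist_fcd, dist_control, 0)
        assert conf.tp == 0 and conf.fp == 0

    def test_cutoff_7_nothing_negative(self, dist_fcd, dist_control):
        conf = confusion_at_cutoff(dist_fcd, dist_control, 7)
        assert conf.fn == 0 and conf.tn == 0

    def test_margins_preserved(self, dist_fcd, dist_control):
        for c in range(8):
            conf = confusion_at_cutoff(dist_fcd, dist_control, c)
            assert conf.tp + conf.fn == dist_fcd.n
            assert conf.tn + conf.fp == dist_control.n


class TestMetricsTable:
    def test_youden_at_published_cutoffs(self, dist_fcd, dist_control):
        rows = {r.cutoff: r for r in metrics_table(dist_fcd, dist_control)}
        assert rows[4].youden == pytest.approx(0.75, abs=0.005)
        assert rows[3].youden == pytest.approx(0.63, abs=0.005)

    def test_cutoff_0_row(self, dist_fcd, dist_control):
        row = metrics_table(dist_fcd, dist_control)[0]
        assert row.sensitivity == 0.0
        assert row.youden == row.specificity - 1 <= 0

    def test_swapped_rendering_exchanges_columns(self, dist_fcd, dist_control):
        rows = metrics_table(dist_fcd, dist_control)
        swapped = swapped_metrics_table(dist_fcd, dist_control)
        for a, b in zip(rows, swapped):
            assert (a.sensitivity, a.specificity) == (b.specificity, b.sensitivity)

    def test_accuracy_is_weighted_mean_of_sens_spec(self, dist_fcd, dist_control):
        n_pos, n_neg = dist_fcd.n, dist_control.n
        for row in metrics_table(dist_fcd, dist_control):
            conf = confusion_at_cutoff(dist_fcd, dist_control, row.cutoff)
            acc = diagnostic_summary(conf).accuracy
            weighted = (
                row.sensitivity * n_pos / (n_pos + n_neg)
                + row.specificity * n_neg / (n_pos + n_neg)
            )
            assert acc == pytest.approx(weighted, abs=1e-12)


class TestRocAndAuc:
    def test_published_auc_exact_fraction(self, dist_fcd, dist_control):
        value = auc(dist_fcd, dist_control)
        assert value == pytest.approx(296 / 319, abs=1e-12)
        assert round(value, 3) == 0.928
        assert brute_force_auc(dist_fcd, dist_control) == Fraction(296, 319)

    def test_roc_shape_and_anchors(self, dist_fcd, dist_control):
        pts = roc_points(dist_fcd, dist_control)
        assert len(pts) == 8
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    def test_roc_monotone_staircase(self, dist_fcd, dist_control):
        pts = np.asarray(roc_points(dist_fcd, dist_control))
        assert (np.diff(pts[:, 0]) >= 0).all()
        assert (np.diff(pts[:, 1]) >= 0).all()

    def test_perfect_separation(self):
        pos = GroupScoreDistribution("p", np.array([5, 0, 0, 0, 0, 0, 0]))
        neg = GroupScoreDistribution("n", np.array([0, 0, 0, 0, 0, 0, 3]))
        assert auc(pos, neg) == 1.0
        assert (0.0, 1.0) in roc_points(pos, neg)

    def test_identical_distributions_on_diagonal(self):
        d = GroupScoreDistribution("d", np.array([1, 2, 3, 0, 1, 0, 2]))
        assert auc(d, d) == pytest.approx(0.5, abs=1e-12)
        for fpr, tpr in roc_points(d, d):
            assert fpr == pytest.approx(tpr, abs=1e-12)

    def test_empty_group_is_undefined(self, dist_fcd):
        with pytest.raises((UndefinedMetricError, ValidationError)):
            auc(dist_fcd, GroupScoreDistribution("n", np.zeros(7, dtype=int)))

    def test_trapezoid_equals_rank_on_200_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a, b = random_distribution(rng), random_distribution(rng)
            value = auc(a, b)  # raises internally if the two forms disagree
            assert value == pytest.approx(float(brute_force_auc(a, b)), abs=1e-12)

    def test_group_swap_complements_auc(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b = random_distribution(rng), random_distribution(rng)
            assert auc(a, b) + auc(b, a) == pytest.approx(1.0, abs=1e-12)


class TestOptimalCutoff:
    def test_published_optimum_is_4(self, dist_fcd, dist_control):
        assert optimal_cutoff(metrics_table(dist_fcd, dist_control)) == 4

    def test_perfect_separation_toy(self):
        pos = GroupScoreDistribution("p", np.array([2, 3, 0, 0, 0, 0, 0]))
        neg = GroupScoreDistribution("n", np.array([0, 0, 0, 0, 1, 2, 0]))
        assert optimal_cutoff(metrics_table(pos, neg)) in (2, 3, 4)
        # all separating cutoffs have youden 1; tie-break picks the lowest
        assert optimal_cutoff(metrics_table(pos, neg)) == 2

    def test_all_identical_rows_tie_break_lowest(self):
        d = GroupScoreDistribution("d", np.array([0, 0, 0, 7, 0, 0, 0]))
        rows = metrics_table(d, d)
        # every cutoff has youden 0; higher specificity favours cutoff 0
        assert optimal_cutoff(rows) == 0

    def test_empty_rows_rejected(self):
        with pytest.raises(ValidationError):
            optimal_cutoff([])


class TestSummaries:
    def test_accuracy_at_published_confusion(self):
        conf = ConfusionCounts(tp=27, fp=2, tn=9, fn=2, cutoff=4)
        s = diagnostic_summary(conf)
        assert s.accuracy == pytest.approx(0.90, abs=0.005)

    def test_predictive_values_dehiscent_positive(self):
        conf = ConfusionCounts(tp=27, fp=2, tn=9, fn=2, cutoff=4)
        s = diagnostic_summary(conf)
        assert s.ppv == pytest.approx(27 / 29, abs=1e-12)
        assert s.npv == pytest.approx(9 / 11, abs=1e-12)
        assert s.fnr == pytest.approx(2 / 29, abs=1e-12)
        assert s.fpr == pytest.approx(2 / 11, abs=1e-12)

    def test_perfect_confusion(self):
        s = diagnostic_summary(ConfusionCounts(tp=29, fp=0, tn=11, fn=0, cutoff=4))
        assert (s.ppv, s.npv, s.accuracy) == (1.0, 1.0, 1.0)
        assert s.fnr == 0.0 and s.fpr == 0.0

    def test_zero_denominator_flagged_none(self):
        s = diagnostic_summary(ConfusionCounts(tp=0, fp=0, tn=5, fn=3, cutoff=0))
        assert s.ppv is None  # no positive calls
        assert s.npv is not None

    def test_both_orientations(self, dist_fcd, dist_control):
        both = summary_both_orientations(dist_fcd, dist_control, 4)
        d = both["dehiscent_positive"]
        i = both["intact_positive"]
        # accuracy and AUC are orientation-invariant
        assert d.accuracy == i.accuracy == pytest.approx(0.90, abs=0.005)
        assert d.auc == i.auc
        # the printed 0.82/0.93 pairing appears under the intact-positive reading
        assert i.ppv == pytest.approx(9 / 11, abs=1e-12)   # 0.82
        assert i.npv == pytest.approx(27 / 29, abs=1e-12)  # 0.93
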
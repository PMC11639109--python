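"""Tests for the diagnostic-accuracy statistics.

Each estimator is checked against an independent route: Clopper-Pearson
against a direct binomial-tail search, the AUROC against
sklearn's midrank implementation, the DeLong variance against a naive
double-loop placement computation, and Cohen's kappa against both a
hand-computed table and statsmodels.
"""

import math

import numpy as np
import pytest
from scipy import optimize, stats

from camimc.accuracy import (
    ConfusionCounts,
    accuracy_estimates,
    auroc,
    build_confusion,
    clopper_pearson,
    cohen_kappa,
    delong_ci,
    likelihood_ratios,
    roc_points,
    youden_optimal,
)

HEADLINE = ConfusionCounts(tp=52, fp=32, fn=2, tn=538)


def _headline_scores():
    scores = np.r_[np.full(52, 1), np.full(2, 0), np.full(32, 1), np.full(538, 0)]
    labels = np.r_[np.ones(54, dtype=bool), np.zeros(570, dtype=bool)]
    return scores, labels


class TestConfusion:
    def test_single_pair(self):
        c = build_confusion([True], [True])
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 0, 0)

    def test_four_pairs_enumerated(self):
        c = build_confusion([1, 0, 1, 0], [1, 1, 0, 0])
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_headline_counts(self):
        """The study's cut-off-3 dataset: 538/570 true negative, 32 false
        positive, 52/54 true positive, 2 false negative."""
        scores, labels = _headline_scores()
        c = build_confusion(scores == 1, labels)
        assert (c.tp, c.fn, c.fp, c.tn) == (52, 2, 32, 538)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_confusion([], [])

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=5)


def _tail_search_bounds(x, n, alpha=0.05):
    """Independent Clopper-Pearson oracle: invert the binomial tails
    numerically instead of using beta quantiles."""
    lo = 0.0
    if x > 0:
        lo = optimize.brentq(
            lambda p: stats.binom.sf(x - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12
        )
    hi = 1.0
    if x < n:
        hi = optimize.brentq(
            lambda p: stats.binom.cdf(x, n, p) - alpha / 2, 1e-12, 1 - 1e-12
        )
    return lo, hi


class TestClopperPearson:
    @pytest.mark.parametrize("x,n", [(0, 10), (1, 10), (5, 10), (10, 10),
                                     (52, 54), (538, 570), (1, 200), (17, 23)])
    def test_matches_binomial_tail_search(self, x, n):
        est = clopper_pearson(x, n)
        lo, hi = _tail_search_bounds(x, n)
        assert est.ci_low == pytest.approx(lo, abs=1e-9)
        assert est.ci_high == pytest.approx(hi, abs=1e-9)

    def test_study_sensitivity_interval(self):
        est = clopper_pearson(52, 54)
        assert round(est.point, 2) == 0.96
        assert round(est.ci_low, 2) == 0.87
        assert round(est.ci_high, 2) == 1.00

    def test_study_specificity_interval(self):
        est = clopper_pearson(538, 570)
        assert round(est.ci_low, 2) == 0.92
        assert round(est.ci_high, 2) == 0.96

    def test_boundaries(self):
        assert clopper_pearson(0, 10).ci_low == 0.0
        assert clopper_pearson(10, 10).ci_high == 1.0

    def test_contains_point(self):
        for x in range(0, 25):
            est = clopper_pearson(x, 24)
            assert est.ci_low <= est.point <= est.ci_high

    @pytest.mark.parametrize("x,n,alpha", [(-1, 10, 0.05), (11, 10, 0.05),
                                           (5, 0, 0.05), (5, 10, 0.0)])
    def test_invalid_inputs(self, x, n, alpha):
        with pytest.raises(ValueError):
            clopper_pearson(x, n, alpha)


class TestAccuracyEstimates:
    def test_headline_values(self):
        est = accuracy_estimates(HEADLINE)
        assert round(est.sensitivity.point, 2) == 0.96
        assert round(est.specificity.point, 2) == 0.94
        assert round(est.ppv.point, 2) == 0.62
        assert round(est.npv.point, 2) == 1.00

    def test_perfect_test(self):
        est = accuracy_estimates(ConfusionCounts(tp=5, fp=0, fn=0, tn=0))
        assert est.sensitivity.point == 1.0 and est.ppv.point == 1.0
        assert est.specificity is None and est.npv is None  # zero denominators


class TestLikelihoodRatios:
    def test_headline_values(self):
        lr = likelihood_ratios(HEADLINE)
        assert lr.lr_pos.point == pytest.approx(17.15, abs=0.005)
        assert lr.lr_pos.ci_low == pytest.approx(12.20, abs=0.005)
        assert lr.lr_pos.ci_high == pytest.approx(24.11, abs=0.005)
        assert lr.lr_neg.point == pytest.approx(0.04, abs=0.005)
        assert lr.lr_neg.ci_low == pytest.approx(0.01, abs=0.005)
        assert lr.lr_neg.ci_high == pytest.approx(0.15, abs=0.005)

    def test_identities(self):
        """LR+ * (1 - spec) = sens and LR- * spec = 1 - sens."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(1, 60, size=4)
            c = ConfusionCounts(tp=int(tp), fp=int(fp), fn=int(fn), tn=int(tn))
            lr = likelihood_ratios(c)
            sens, spec = tp / (tp + fn), tn / (tn + fp)
            assert lr.lr_pos.point * (1 - spec) == pytest.approx(sens)
            assert lr.lr_neg.point * spec == pytest.approx(1 - sens)

    def test_perfect_test_degenerate(self):
        lr = likelihood_ratios(ConfusionCounts(tp=5, fp=0, fn=0, tn=8))
        assert math.isinf(lr.lr_pos.point) and lr.lr_pos.degenerate
        assert lr.lr_neg.point == 0.0 and lr.lr_neg.degenerate

    def test_ci_contains_point(self):
        lr = likelihood_ratios(HEADLINE)
        assert lr.lr_pos.ci_low <= lr.lr_pos.point <= lr.lr_pos.ci_high
        assert lr.lr_neg.ci_low <= lr.lr_neg.point <= lr.lr_neg.ci_high


class TestRoc:
    def test_perfect_separation_passes_corner(self):
        curve = roc_points([0, 10], [False, True])
        assert (0.0, 1.0) in {(p.fpr, p.sensitivity) for p in curve.points}

    def test_anchors_and_monotonicity(self):
        rng = np.random.default_rng(3)
        s = rng.integers(0, 11, 60)
        y = rng.random(60) < 0.3
        curve = roc_points(s, y)
        _, sens, fpr = curve.to_arrays()
        assert sens[0] == 1.0 and fpr[0] == 1.0
        assert sens[-1] == 0.0 and fpr[-1] == 0.0
        assert (np.diff(sens) <= 0).all() and (np.diff(fpr) <= 0).all()

    def test_headline_interior_point(self):
        scores, labels = _headline_scores()
        curve = roc_points(scores, labels)
        interior = {(round(p.fpr, 6), round(p.sensitivity, 6)) for p in curve.points}
        assert (round(32 / 570, 6), round(52 / 54, 6)) in interior

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points([1, 2, 3], [True, True, True])


class TestAuroc:
    def test_dichotomised_equals_mean_of_sens_and_spec(self):
        scores, labels = _headline_scores()
        a = auroc(scores, labels)
        assert a.auc == pytest.approx((52 / 54 + 538 / 570) / 2, abs=1e-12)
        assert round(a.auc, 2) == 0.95

    def test_perfect_and_tied(self):
        assert auroc([0, 0, 5, 5], [0, 0, 1, 1]).auc == 1.0
        assert auroc([2, 2, 2, 2], [0, 1, 0, 1]).auc == 0.5

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(11)
        s = rng.integers(0, 8, 40)
        y = rng.random(40) < 0.4
        assert auroc(s, y).auc == auroc(3 * s + 2, y).auc

    def test_matches_sklearn_on_random_small_instances(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        checked = 0
        for _ in range(300):
            n = int(rng.integers(4, 13))
            s = rng.integers(0, 6, n)
            y = rng.integers(0, 2, n).astype(bool)
            if y.all() or not y.any():
                continue
            assert auroc(s, y).auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)
            checked += 1
        assert checked > 200


def _delong_brute(scores, labels):
    """Naive double-loop placement-value computation."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos, neg = s[y], s[~y]
    v10 = np.array([np.mean((neg < x) + 0.5 * (neg == x)) for x in pos])
    v01 = np.array([np.mean((pos > x) + 0.5 * (pos == x)) for x in neg])
    auc = v10.mean()
    var = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
    return auc, math.sqrt(var)


class TestDeLong:
    def test_headline_interval(self):
        scores, labels = _headline_scores()
        est = delong_ci(scores, labels)
        assert round(est.ci_low, 2) == 0.93
        assert round(est.ci_high, 2) == 0.98

    def test_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(13)
        checked = 0
        for _ in range(200):
            n = int(rng.integers(6, 14))
            s = rng.integers(0, 4, n)
            y = rng.integers(0, 2, n).astype(bool)
            if y.sum() < 2 or (~y).sum() < 2:
                continue
            est = delong_ci(s, y)
            auc, se = _delong_brute(s, y)
            assert est.auc == pytest.approx(auc, abs=1e-12)
            assert est.se == pytest.approx(se, abs=1e-12)
            checked += 1
        assert checked > 120

    def test_perfect_separation_collapses(self):
        est = delong_ci([0, 0, 9, 9], [False, False, True, True])
        assert est.se == 0.0 and est.ci_low == est.ci_high == est.auc == 1.0

    def test_degenerate_class_sizes_rejected(self):
        with pytest.raises(ValueError):
            delong_ci([0, 1, 2], [True, False, False])

    def test_interval_truncated_to_unit(self):
        est = delong_ci([0, 0, 1, 2, 9, 9], [0, 0, 1, 0, 1, 1])
        assert 0.0 <= est.ci_low <= est.auc <= est.ci_high <= 1.0


class TestYouden:
    def test_study_triples_select_three(self):
        pts = [(3, 0.96, 0.94), (4, 0.89, 0.98), (5, 0.83, 0.99)]
        assert youden_optimal(pts) == 3

    def test_single_candidate(self):
        assert youden_optimal([(7, 0.5, 0.5)]) == 7

    def test_tie_broken_toward_lowest_cutoff(self):
        assert youden_optimal([(1, 0.9, 0.5), (2, 0.5, 0.9)]) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            youden_optimal([])


class TestKappa:
    def test_identical_sequences(self):
        a = np.array([1, 0, 1, 1, 0, 0, 1], dtype=bool)
        k = cohen_kappa(a, a)
        assert k.kappa == 1.0 and k.p_o == 1.0

    def test_hand_computed_table(self):
        """2x2 rating table (40, 5, 5, 150): p_o = 0.95, p_e = 0.65125,
        kappa = 0.29875 / 0.34875."""
        a = np.r_[np.ones(45), np.zeros(155)].astype(bool)
        b = np.r_[np.ones(40), np.zeros(5), np.ones(5), np.zeros(150)].astype(bool)
        k = cohen_kappa(a, b)
        assert k.kappa == pytest.approx(0.29875 / 0.34875, abs=1e-12)
        assert k.p_o == pytest.approx(0.95) and k.p_e == pytest.approx(0.65125)

    def test_matches_statsmodels_kappa_and_se(self):
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(20, 120))
            a = rng.random(n) < 0.3
            b = np.where(rng.random(n) < 0.7, a, rng.random(n) < 0.3)
            if (a == a[0]).all() and (b == b[0]).all():
                continue
            table = np.array([
                [np.sum(~a & ~b), np.sum(~a & b)],
                [np.sum(a & ~b), np.sum(a & b)],
            ])
            ours = cohen_kappa(a, b)
            theirs = sm_kappa(table, return_results=True)
            assert ours.kappa == pytest.approx(theirs.kappa, abs=1e-10)
            assert ours.se == pytest.approx(theirs.std_kappa, abs=1e-10)

    def test_swap_invariance(self):
        rng = np.random.default_rng(19)
        a = rng.random(80) < 0.4
        b = rng.random(80) < 0.4
        assert cohen_kappa(a, b).kappa == pytest.approx(cohen_kappa(b, a).kappa)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(23)
        a = rng.random(4000) < 0.3
        b = rng.random(4000) < 0.3
        k = cohen_kappa(a, b)
        assert abs(k.kappa) < 3 * k.se

    def test_degenerate_agreement_flagged(self):
        k = cohen_kappa([True] * 5, [True] * 5)
        assert not k.defined and math.isnan(k.kappa)
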
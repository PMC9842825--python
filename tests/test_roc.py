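"""ROC construction, Mann-Whitney AUC, the DeLong variance/covariance
machinery, Youden operating points, and the stratified bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom, norm
from sklearn.metrics import roc_auc_score

import fuseroc as fr
from fuseroc.roc import ROCCurve


def brute_force_auc(scores, labels):
    """O(n_pos * n_neg) pair-counting oracle: 1 / 0.5 / 0 per (pos, neg) pair."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_force_components(scores, labels):
    """DeLong structural components straight from the definition (psi matrix)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    psi = np.where(
        pos[:, None] > neg[None, :], 1.0, np.where(pos[:, None] == neg[None, :], 0.5, 0.0)
    )
    return psi.mean(axis=1), psi.mean(axis=0)  # V10 per positive, V01 per negative


def _random_instance(rng, n=40, tie_prob=0.3):
    n_pos = rng.integers(2, n - 2)
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n_pos, replace=False)] = 1
    scores = rng.normal(size=n) + labels
    if rng.random() < tie_prob:
        scores = np.round(scores)  # force ties
    return scores, labels


class TestBinaryLabels:
    def test_only_malignant_is_positive(self):
        t = pd.DataFrame(
            {
                "case_id": ["a", "b", "c"],
                "truth_class": ["malignant", "benign", "normal"],
                "score_dm": [0.0, 0.0, 0.0],
                "score_abus": [0.0, 0.0, 0.0],
            }
        )
        assert fr.binary_labels(t).tolist() == [1, 0, 0]

    def test_default_cohort_counts(self, default_cohort):
        labels = fr.binary_labels(default_cohort)
        assert labels.sum() == 42
        assert (labels == 0).sum() == 388

    def test_unknown_class_rejected(self):
        t = pd.DataFrame(
            {
                "case_id": ["a"],
                "truth_class": ["suspicious"],
                "score_dm": [0.0],
                "score_abus": [0.0],
            }
        )
        with pytest.raises(ValueError, match="suspicious"):
            fr.binary_labels(t)


class TestEmpiricalRoc:
    def test_endpoints_and_monotonicity(self, rng):
        scores, labels = _random_instance(rng, n=80)
        curve = fr.empirical_roc(scores, labels)
        assert (curve.sensitivity[0], curve.specificity[0]) == (1.0, 0.0)
        assert (curve.sensitivity[-1], curve.specificity[-1]) == (0.0, 1.0)
        assert (np.diff(curve.sensitivity) <= 1e-12).all()
        assert (np.diff(curve.specificity) >= -1e-12).all()

    def test_perfect_separation_passes_through_ideal_corner(self):
        curve = fr.empirical_roc(np.array([0.9, 0.1]), np.array([1, 0]))
        pts = set(zip(curve.sensitivity, curve.specificity))
        assert (1.0, 1.0) in pts

    def test_all_tied_scores_collapse_to_three_points(self):
        curve = fr.empirical_roc(np.full(10, 3.3), np.array([1] * 4 + [0] * 6))
        assert len(curve) == 3
        assert (curve.sensitivity[1], curve.specificity[1]) == (1.0, 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_midpoint_thresholding(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = _random_instance(rng, n=20)
        curve = fr.empirical_roc(scores, labels)
        uniq = np.unique(scores)
        cuts = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]])
        oracle = {
            (
                round(float((scores[labels == 1] > c).mean()), 12),
                round(float((scores[labels == 0] <= c).mean()), 12),
            )
            for c in cuts
        }
        ours = {
            (round(float(s), 12), round(float(p), 12))
            for s, p in zip(curve.sensitivity, curve.specificity)
        }
        assert ours == oracle

    def test_single_class_error_names_missing_class(self):
        with pytest.raises(ValueError, match="negative"):
            fr.empirical_roc(np.array([1.0, 2.0]), np.array([1, 1]))
        with pytest.raises(ValueError, match="positive"):
            fr.empirical_roc(np.array([1.0, 2.0]), np.array([0, 0]))


class TestAuc:
    def test_perfect_and_null(self, rng):
        assert fr.auc(np.array([3.0, 1.0]), np.array([1, 0])) == 1.0
        n = 20000
        labels = rng.integers(0, 2, size=n)
        assert abs(fr.auc(rng.normal(size=n), labels) - 0.5) < 0.02

    @pytest.mark.parametrize("seed", range(8))
    def test_exactly_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = _random_instance(rng, n=int(rng.integers(6, 200)))
        assert fr.auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )
        # independent library cross-check
        assert fr.auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_complement_transform_and_trapezoid_identities(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = _random_instance(rng, n=60, tie_prob=0.0)
        a = fr.auc(scores, labels)
        # reversing score orientation flips the AUC (tie-free)
        assert a + fr.auc(-scores, labels) == pytest.approx(1.0, abs=1e-12)
        # invariance under strictly increasing transforms
        assert fr.auc(np.exp(scores / 3), labels) == pytest.approx(a, abs=1e-12)
        # trapezoidal area under the empirical curve equals Mann-Whitney
        assert fr.empirical_roc(scores, labels).trapezoidal_auc() == pytest.approx(
            a, abs=1e-10
        )

    def test_trapezoid_equality_holds_with_ties(self, rng):
        scores, labels = _random_instance(rng, n=100, tie_prob=1.0)
        assert fr.empirical_roc(scores, labels).trapezoidal_auc() == pytest.approx(
            fr.auc(scores, labels), abs=1e-10
        )


class TestDeLong:
    def test_components_match_psi_matrix_definition(self, rng):
        for _ in range(5):
            scores, labels = _random_instance(rng, n=60)
            v10, v01 = brute_force_components(scores, labels)
            m, n = len(v10), len(v01)
            expected_var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
            assert fr.delong_variance(scores, labels) == pytest.approx(
                expected_var, abs=1e-12
            )

    def test_paired_covariance_matches_psi_matrix_definition(self, rng):
        n = 80
        labels = (rng.random(n) < 0.4).astype(int)
        labels[:2] = 1
        labels[-2:] = 0
        a = rng.normal(size=n) + labels
        b = 0.5 * a + rng.normal(size=n)
        res = fr.delong_paired_test(a, b, labels)
        v10a, v01a = brute_force_components(a, labels)
        v10b, v01b = brute_force_components(b, labels)
        m, k = len(v10a), len(v01a)
        cov = np.cov(v10a, v10b, ddof=1)[0, 1] / m + np.cov(v01a, v01b, ddof=1)[0, 1] / k
        assert res.cov_ab == pytest.approx(cov, abs=1e-12)
        assert abs(res.cov_ab) <= np.sqrt(res.var_a * res.var_b) + 1e-12

    def test_matches_frozen_proc_oracle(self):
        """Cross-checked against R pROC's DeLong implementation on this exact
        seeded dataset; the pROC outputs are frozen below."""
        rng = np.random.default_rng(20240917)
        n_pos, n_neg = 25, 55
        labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
        base = rng.normal(size=n_pos + n_neg)
        a = 1.1 * labels + base + 0.5 * rng.normal(size=n_pos + n_neg)
        b = 0.9 * labels + 0.6 * base + 0.8 * rng.normal(size=n_pos + n_neg)
        res = fr.delong_paired_test(a, b, labels)
        assert res.auc_a == pytest.approx(0.743272727273, abs=1e-9)
        assert res.auc_b == pytest.approx(0.740363636364, abs=1e-9)
        assert res.var_a == pytest.approx(4.166043464953e-03, rel=1e-9)
        assert res.var_b == pytest.approx(4.152501989593e-03, rel=1e-9)
        assert res.cov_ab == pytest.approx(2.953613712886e-03, rel=1e-9)
        assert res.z == pytest.approx(0.059242045660, abs=1e-9)
        assert res.p_value == pytest.approx(0.952759320838, abs=1e-9)

    def test_perfect_separation_has_zero_variance(self):
        scores = np.array([2.0, 3.0, 4.0, -1.0, -2.0, -3.0])
        labels = np.array([1, 1, 1, 0, 0, 0])
        assert fr.delong_variance(scores, labels) == 0.0

    def test_too_few_cases_per_class_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            fr.delong_variance(np.array([1.0, 0.0, -1.0]), np.array([1, 0, 0]))

    def test_duplicating_every_case_roughly_halves_variance(self, rng):
        scores, labels = _random_instance(rng, n=100, tie_prob=0.0)
        v1 = fr.delong_variance(scores, labels)
        v2 = fr.delong_variance(np.r_[scores, scores], np.r_[labels, labels])
        assert 0.4 < v2 / v1 < 0.6

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_score_against_itself_gives_z_zero_p_one(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = _random_instance(rng, n=40)
        res = fr.delong_paired_test(scores, scores, labels)
        assert res.z == 0.0 and res.p_value == 1.0

    def test_monotone_transform_of_scores_gives_p_one(self, rng):
        scores, labels = _random_instance(rng, n=60, tie_prob=0.0)
        res = fr.delong_paired_test(scores, 3.0 * scores + 7.0, labels)
        assert res.auc_a == pytest.approx(res.auc_b, abs=1e-12)
        assert res.p_value == 1.0

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            fr.delong_paired_test(np.zeros(5), np.zeros(6), np.r_[1, 1, 0, 0, 0])


class TestMaxYouden:
    def _curve(self, sens, spec, thresholds=None):
        sens = np.asarray(sens, float)
        spec = np.asarray(spec, float)
        t = np.arange(len(sens), dtype=float) if thresholds is None else np.asarray(thresholds)
        return ROCCurve(t, sens, spec, n_pos=10, n_neg=10)

    def test_selects_maximal_j(self):
        curve = self._curve([1.0, 0.9, 0.6, 0.0], [0.0, 0.7, 0.9, 1.0])
        point = fr.max_youden(curve)
        assert point.youden_j == pytest.approx(0.6)
        assert (point.sensitivity, point.specificity) == (0.9, 0.7)
        assert point.youden_j == pytest.approx(
            point.sensitivity + point.specificity - 1, abs=1e-12
        )

    def test_ties_broken_toward_higher_specificity(self):
        curve = self._curve([1.0, 0.8, 0.6, 0.0], [0.0, 0.5, 0.7, 1.0])
        point = fr.max_youden(curve)
        assert point.specificity == 0.7

    def test_uninformative_curve_flags_degenerate_zero_j(self):
        curve = self._curve([1.0, 1.0, 0.0], [0.0, 0.0, 1.0], thresholds=[-np.inf, 0.0, np.inf])
        with pytest.warns(UserWarning, match="uninformative"):
            point = fr.max_youden(curve)
        assert point.youden_j == 0.0
        assert point.degenerate

    def test_on_empirical_curve_from_scores(self, rng):
        scores, labels = _random_instance(rng, n=200, tie_prob=0.0)
        curve = fr.empirical_roc(scores, labels)
        point = fr.max_youden(curve)
        j_all = curve.sensitivity + curve.specificity - 1
        assert point.youden_j == pytest.approx(j_all.max(), abs=1e-12)


class TestBootstrap:
    def test_constant_metric_gives_zero_width_interval(self, small_cohort):
        ci = fr.bootstrap_ci(lambda t: 3.14, small_cohort, n_replicates=50, seed=0)
        assert ci.lower == ci.upper == ci.point == 3.14

    def test_same_seed_reproduces_interval(self, small_cohort):
        metric = lambda t: fr.auc(t["score_dm"].to_numpy(), fr.binary_labels(t))
        a = fr.bootstrap_ci(metric, small_cohort, n_replicates=200, seed=42)
        b = fr.bootstrap_ci(metric, small_cohort, n_replicates=200, seed=42)
        assert (a.lower, a.upper) == (b.lower, b.upper)
        c = fr.bootstrap_ci(metric, small_cohort, n_replicates=200, seed=43)
        assert (a.lower, a.upper) != (c.lower, c.upper)

    def test_stratified_resampling_fixes_class_composition(self, small_cohort):
        # class counts are invariant under stratified resampling, so a
        # count-valued metric has a zero-width interval
        metric = lambda t: float(fr.binary_labels(t).sum())
        ci = fr.bootstrap_ci(metric, small_cohort, n_replicates=100, seed=1)
        assert ci.lower == ci.upper == 12.0

    def test_proportion_interval_width_matches_binomial_oracle(self):
        n, p = 500, 0.3
        table = fr.generate_cohort(fr.CohortConfig(int(n * p), 0, n - int(n * p), seed=3))
        metric = lambda t: float(fr.binary_labels(t).mean())
        ci = fr.bootstrap_ci(
            metric, table, n_replicates=2000, seed=7, stratify=False
        )
        lo, hi = binom.ppf([0.025, 0.975], n, p) / n
        assert (ci.upper - ci.lower) == pytest.approx(hi - lo, rel=0.2)

    def test_auc_interval_coverage_near_nominal(self):
        """Percentile-bootstrap AUC CI coverage on binormal cohorts (n = 200,
        500 cohorts) within 3 binomial SEs of the nominal 95%."""
        true_auc = float(norm.cdf(1 / np.sqrt(2)))
        metric = lambda t: fr.auc(t["score_dm"].to_numpy(), fr.binary_labels(t))
        n_cohorts, hits = 500, 0
        for k in range(n_cohorts):
            table = fr.generate_cohort(
                fr.CohortConfig(50, 0, 150, seed=100_000 + k),
                fr.BinormalModelSpec(
                    malignant=fr.ClassScoreModel(1.0, 1.0, 1.0, 1.0, 0.0),
                    benign=fr.ClassScoreModel(0.0, 1.0, 0.0, 1.0, 0.0),
                    normal=fr.ClassScoreModel(0.0, 1.0, 0.0, 1.0, 0.0),
                ),
            )
            ci = fr.bootstrap_ci(metric, table, n_replicates=600, seed=k)
            hits += ci.lower <= true_auc <= ci.upper
        coverage = hits / n_cohorts
        se = np.sqrt(0.95 * 0.05 / n_cohorts)
        assert abs(coverage - 0.95) < 3 * se
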
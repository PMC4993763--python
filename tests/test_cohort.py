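import math

import numpy as np
import pytest
from scipy import stats as sps

from dyadsync import (
    ClassifierModel,
    bootstrap_classifier,
    fit_classifier,
    mann_whitney,
    predict,
)
from dyadsync.errors import DomainError

PRINTED = dict(a=5.0, b=-23.0, c=0.6)  # reference logistic parameters


def simulate_cohort(n, rng, a=PRINTED["a"], b=PRINTED["b"], c=PRINTED["c"]):
    """Draw (x, y) features and Bernoulli labels from the logistic model."""
    x = rng.normal(0.23, 0.12, size=n)
    y = rng.normal(0.5, 1.0, size=n)
    p = 1.0 / (1.0 + a * np.exp(b * x + c * y))
    labels = np.where(rng.random(n) < p, "B", "A")
    return np.column_stack([x, y]), labels


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.U == 9 and res.r == 1.0
        res_rev = mann_whitney([4, 5, 6], [1, 2, 3])
        assert res_rev.U == 0 and res_rev.r == -1.0

    def test_identical_groups_with_ties(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.r == 0.0
        assert res.p == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_scipy_enumeration(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.random(6), r.random(7)  # tie-free continuous data
        res = mann_whitney(a, b)
        ref = sps.mannwhitneyu(b, a, alternative="two-sided", method="exact")
        assert res.exact
        assert res.U == ref.statistic
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_exact_p_with_ties_matches_permutation_test(self):
        a = [1.0, 2.0, 2.0, 5.0]
        b = [2.0, 3.0, 3.0, 7.0]

        def stat(x, y):
            return ((y[:, None] < x[None, :]).sum()
                    + 0.5 * (y[:, None] == x[None, :]).sum())

        ref = sps.permutation_test(
            (np.array(b), np.array(a)), stat, permutation_type="independent",
            alternative="two-sided", n_resamples=np.inf, vectorized=False)
        res = mann_whitney(a, b)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approximation_for_large_groups(self, rng):
        a, b = rng.random(12), rng.random(15) + 0.2
        res = mann_whitney(a, b)
        ref = sps.mannwhitneyu(b, a, alternative="two-sided", method="asymptotic")
        assert not res.exact
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_one_sided_alternatives(self):
        res = mann_whitney([1, 2], [3, 4], alternative="greater")
        assert res.p == pytest.approx(1 / 6)

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            mann_whitney([], [1.0])


class TestPredict:
    def test_uninformative_model_is_half(self):
        m = ClassifierModel(a=1.0, b=0.0, c=0.0)
        assert predict(m, 0.3, -2.0) == pytest.approx(0.5)

    def test_printed_parameters_boundary_point(self):
        m = ClassifierModel(**PRINTED)
        x_star = math.log(PRINTED["a"]) / -PRINTED["b"]
        assert predict(m, x_star, 0.0) == pytest.approx(0.5)

    def test_monotone_in_synchrony(self):
        m = ClassifierModel(**PRINTED)
        assert predict(m, 0.33, 0.0) > predict(m, 0.14, 0.0)

    def test_probabilities_bounded_under_extreme_inputs(self):
        m = ClassifierModel(a=5.0, b=-23.0, c=0.6)
        p = predict(m, np.array([-1e6, 1e6]), np.array([1e6, -1e6]))
        assert np.all((p >= 0) & (p <= 1))

    def test_decision_boundary_line(self):
        # boundary: b*x + c*y = -ln a
        m = ClassifierModel(**PRINTED)
        for y in (-1.0, 0.0, 2.0):
            x = (-math.log(m.a) - m.c * y) / m.b
            assert predict(m, x, y) == pytest.approx(0.5)


class TestFitClassifier:
    def test_parameter_recovery_from_simulation(self):
        rng = np.random.default_rng(42)
        pts, labels = simulate_cohort(4000, rng)
        m = fit_classifier(pts, labels)
        assert m.b == pytest.approx(PRINTED["b"], rel=0.25)
        assert m.c == pytest.approx(PRINTED["c"], rel=0.35)
        assert m.a > 0

    def test_null_features_give_flat_model(self):
        rng = np.random.default_rng(1)
        pts = rng.random((300, 2))
        labels = np.where(rng.random(300) < 0.5, "A", "B")
        m = fit_classifier(pts, labels)
        assert abs(m.b) < 2 and abs(m.c) < 2

    def test_relabeling_complements_probabilities(self):
        rng = np.random.default_rng(3)
        pts, labels = simulate_cohort(200, rng)
        m1 = fit_classifier(pts, labels)
        swapped = np.where(labels == "A", "B", "A")
        m2 = fit_classifier(pts, swapped)
        p1 = predict(m1, pts[:, 0], pts[:, 1])
        p2 = predict(m2, pts[:, 0], pts[:, 1])
        np.testing.assert_allclose(p1, 1 - p2, atol=1e-4)

    def test_single_label_rejected(self):
        with pytest.raises(DomainError):
            fit_classifier([[0, 0], [1, 1], [0, 1], [1, 0]], ["A"] * 4)

    def test_separation_flagged(self):
        pts = np.array([[0, 0], [0.1, 0], [1, 0], [1.1, 0]] * 3)
        labels = np.array(["A", "A", "B", "B"] * 3)
        m = fit_classifier(pts, labels)
        assert m.separation


class TestBootstrap:
    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        pts, labels = simulate_cohort(40, rng)
        m1 = bootstrap_classifier(pts, labels, n_boot=50, seed=9)
        m2 = bootstrap_classifier(pts, labels, n_boot=50, seed=9)
        assert m1.summary() == m2.summary()
        m3 = bootstrap_classifier(pts, labels, n_boot=50, seed=10)
        assert m3.summary() != m1.summary()

    def test_separable_toy_set_classifies_perfectly(self):
        pts = np.array([[0.0, 0.0]] * 10 + [[1.0, 0.0]] * 10)
        pts += np.random.default_rng(0).normal(0, 0.01, pts.shape)
        labels = np.array(["A"] * 10 + ["B"] * 10)
        m = bootstrap_classifier(pts, labels, n_boot=30, seed=1)
        assert m.summary()["accuracy_mean"] == 1.0

    def test_replicate_count_is_kept(self):
        rng = np.random.default_rng(6)
        pts, labels = simulate_cohort(12, rng)
        m = bootstrap_classifier(pts, labels, n_boot=40, seed=2)
        assert len(m.bootstrap_samples) == 40

    def test_oob_differs_from_in_sample(self):
        rng = np.random.default_rng(7)
        pts, labels = simulate_cohort(60, rng)
        oob = bootstrap_classifier(pts, labels, n_boot=100, seed=3, oob=True)
        ins = bootstrap_classifier(pts, labels, n_boot=100, seed=3, oob=False)
        # in-sample accuracy is optimistic
        assert ins.summary()["accuracy_mean"] >= oob.summary()["accuracy_mean"]
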
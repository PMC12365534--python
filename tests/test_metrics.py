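"""Metric stack vs independent brute-force oracles."""

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

from gastromil.errors import InvalidInputError
from gastromil.metrics import (
    ConfusionMatrix,
    ContingencyTable2x2,
    chi2_2x2,
    compute_report,
    cui,
    cui_band,
    delong_test,
    macro_auc,
    mcnemar_test,
    per_class_auc,
    quadratic_weighted_kappa,
)
from gastromil.model import GradingScheme


# ---------------------------------------------------------------- oracles
def auc_pair_counting(y, s):
    """AUC by exhaustive pair enumeration with half-credit ties."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def kappa_brute(r1, r2, k):
    n = len(r1)
    obs = np.zeros((k, k))
    for a, b in zip(r1, r2):
        obs[a, b] += 1
    exp = np.outer(obs.sum(1), obs.sum(0)) / n
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            w = (i - j) ** 2 / (k - 1) ** 2
            num += w * obs[i, j]
            den += w * exp[i, j]
    return 1 - num / den


def binom_two_sided(k, n):
    """Two-sided exact binomial p by tail enumeration at p0 = 1/2."""
    pk = sps.binom.pmf(np.arange(n + 1), n, 0.5)
    return min(1.0, pk[pk <= pk[k] * (1 + 1e-9)].sum())


# ---------------------------------------------------------------- AUC
class TestAUC:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        p = np.eye(3)[y]
        scheme = GradingScheme.for_task(1)
        rep = compute_report(y, p, scheme)
        assert rep.macro_auc == 1.0 and rep.accuracy == 1.0

    def test_label_independent_scores_auc_half(self, rng):
        n = 2000
        y = rng.integers(0, 3, n)
        p = rng.dirichlet(np.ones(3), size=n)
        assert abs(macro_auc(y, p) - 0.5) < 0.03

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 30))
            y = rng.integers(0, 3, n)
            while len(np.unique(y)) < 2:
                y = rng.integers(0, 3, n)
            p = rng.dirichlet(np.ones(3), size=n)
            aucs = per_class_auc(y, p)
            for c in np.unique(y):
                expect = auc_pair_counting((y == c).astype(int), p[:, c])
                assert aucs[c] == pytest.approx(expect, abs=1e-10)

    def test_absent_class_excluded_with_warning(self):
        y = np.array([0, 0, 1, 1])
        p = np.column_stack([1 - np.linspace(0.1, 0.9, 4), np.linspace(0.1, 0.9, 4), np.zeros(4)])
        with pytest.warns(UserWarning):
            aucs = per_class_auc(y, p)
        assert np.isnan(aucs[2]) and not np.isnan(aucs[0])

    def test_three_class_worked_example(self):
        # n=12 fixture; expectations computed by the pair-counting oracle
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2])
        rng = np.random.default_rng(99)
        p = rng.dirichlet(np.ones(3), size=12)
        aucs = per_class_auc(y, p)
        for c in range(3):
            assert aucs[c] == pytest.approx(
                auc_pair_counting((y == c).astype(int), p[:, c]), abs=1e-12
            )


# ---------------------------------------------------------------- CUI
class TestCUI:
    def test_perfect_classifier_excellent(self):
        cm = ConfusionMatrix(np.diag([20, 30, 10]))
        r = cui(cm, 0)
        assert r.cui_plus == 1.0 and r.band_plus == "excellent"

    def test_hand_computed_example(self):
        cm = ConfusionMatrix(np.array([[45, 5], [10, 40]]))
        r = cui(cm, 0)
        assert r.cui_plus == pytest.approx((45 / 50) * (45 / 55), abs=1e-12)
        assert r.band_plus == "good"

    @pytest.mark.parametrize(
        "value,band",
        [(0.90, "excellent"), (0.810, "excellent"), (0.700, "good"), (0.640, "good"),
         (0.50, "satisfactory"), (0.30, "poor")],
    )
    def test_bands(self, value, band):
        assert cui_band(value) == band

    def test_zero_denominator_flags_undefined(self):
        # class 1 never predicted and never present -> PPV/sens undefined
        cm = ConfusionMatrix(np.array([[50, 0], [0, 0]]))
        r = cui(cm, 1)
        assert r.undefined and np.isnan(r.cui_plus)

    def test_cui_plus_bounded_by_components(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 30, (2, 2))
            counts[0, 0] += 1
            counts[1, 1] += 1
            r = cui(ConfusionMatrix(counts), 0)
            tp, fn, fp, tn = ConfusionMatrix(counts).one_vs_rest(0)
            sens = tp / (tp + fn)
            ppv = tp / (tp + fp) if tp + fp else np.nan
            if not np.isnan(r.cui_plus):
                assert r.cui_plus <= min(sens, ppv) + 1e-12


# ---------------------------------------------------------------- kappa
class TestQuadraticWeightedKappa:
    def test_identical_raters(self, rng):
        r = rng.integers(0, 4, 50)
        assert quadratic_weighted_kappa(r, r, 4) == pytest.approx(1.0)

    def test_reversed_ranks_match_oracle(self):
        r1 = np.array([0, 1, 2, 3])
        r2 = np.array([3, 2, 1, 0])
        assert quadratic_weighted_kappa(r1, r2, 4) == pytest.approx(
            kappa_brute(r1, r2, 4), abs=1e-12
        )

    def test_matches_brute_force_and_sklearn(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 40))
            r1 = rng.integers(0, 4, n)
            r2 = rng.integers(0, 4, n)
            k = quadratic_weighted_kappa(r1, r2, 4)
            assert k == pytest.approx(kappa_brute(r1, r2, 4), abs=1e-10)
            if len(np.unique(np.concatenate([r1, r2]))) == 4:
                assert k == pytest.approx(
                    cohen_kappa_score(r1, r2, weights="quadratic"), abs=1e-10
                )

    def test_bounds_on_random_inputs(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 30))
            k = quadratic_weighted_kappa(rng.integers(0, 3, n), rng.integers(0, 3, n), 3)
            assert -1.0 - 1e-9 <= k <= 1.0 + 1e-9

    def test_constant_vs_uniform_rater_near_zero(self, rng):
        n = 4000
        r1 = np.zeros(n, dtype=int)
        r2 = rng.integers(0, 4, n)
        assert abs(quadratic_weighted_kappa(r1, r2, 4)) < 0.05

    def test_length_mismatch_raises(self):
        with pytest.raises(InvalidInputError):
            quadratic_weighted_kappa([0, 1], [0], 3)


# ---------------------------------------------------------------- McNemar
class TestMcNemar:
    def test_symmetric_discordance(self):
        res = mcnemar_test(20, 20, correction=False, exact=False)
        assert res.statistic == 0 and res.p_value == pytest.approx(1.0)

    def test_exact_binomial_oracle(self):
        res = mcnemar_test(10, 2)  # n=12 < 25 -> exact
        assert res.p_value == pytest.approx(binom_two_sided(2, 12), abs=1e-10)

    def test_correction_raises_p(self, rng):
        for _ in range(30):
            n01, n10 = int(rng.integers(10, 60)), int(rng.integers(10, 60))
            p_c = mcnemar_test(n01, n10, correction=True, exact=False).p_value
            p_u = mcnemar_test(n01, n10, correction=False, exact=False).p_value
            assert p_c >= p_u - 1e-12

    def test_exact_and_chi2_agree_for_large_discordance(self, rng):
        for _ in range(30):
            n01 = int(rng.integers(25, 60))
            n10 = int(rng.integers(25, 60))
            p_e = mcnemar_test(n01, n10, exact=True).p_value
            p_c = mcnemar_test(n01, n10, exact=False).p_value
            assert abs(p_e - p_c) < 0.02

    def test_no_discordance_flagged(self):
        assert mcnemar_test(0, 0).undefined


# ---------------------------------------------------------------- DeLong
class TestDeLong:
    def test_identical_scores(self, rng):
        y = np.array([0, 1] * 20)
        s = rng.standard_normal(40)
        auc1, auc2, z, p = delong_test(y, s, s)
        assert z == 0.0 and p == 1.0 and auc1 == auc2

    def test_auc_matches_pair_counting(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 40))
            y = rng.integers(0, 2, n)
            while y.sum() in (0, n):
                y = rng.integers(0, 2, n)
            s1, s2 = rng.standard_normal(n), rng.standard_normal(n)
            auc1, auc2, _, _ = delong_test(y, s1, s2)
            assert auc1 == pytest.approx(auc_pair_counting(y, s1), abs=1e-10)
            assert auc2 == pytest.approx(auc_pair_counting(y, s2), abs=1e-10)

    def test_detects_known_signal_gap(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            y = np.array([0] * 100 + [1] * 100)
            s1 = y * 1.5 + r.standard_normal(200)  # informative
            s2 = r.standard_normal(200)  # noise
            _, _, _, p = delong_test(y, s1, s2)
            hits += p < 0.05
        assert hits >= 95

    def test_single_class_raises(self):
        with pytest.raises(InvalidInputError):
            delong_test(np.ones(10), np.arange(10.0), np.arange(10.0))


# ---------------------------------------------------------------- chi2 2x2
class TestChi2:
    def test_identical_rows_null(self):
        res = chi2_2x2([[30, 20], [30, 20]])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_textbook_formula_on_random_tables(self, rng):
        for _ in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(1, 80, 4))
            n = a + b + c + d
            det = max(abs(a * d - b * c) - n / 2, 0.0)
            expect = n * det**2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert chi2_2x2([[a, b], [c, d]]).statistic == pytest.approx(expect, rel=1e-12)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(100):
            t = rng.integers(1, 60, (2, 2))
            ours = chi2_2x2(t, yates=True)
            ref_s, ref_p = sps.chi2_contingency(t, correction=True)[:2]
            assert ours.statistic == pytest.approx(ref_s, abs=1e-10)
            assert ours.p_value == pytest.approx(ref_p, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(InvalidInputError):
            ContingencyTable2x2(0, 0, 5, 5)


# ---------------------------------------------------------------- report
class TestReport:
    def test_report_fields_consistent(self, rng):
        scheme = GradingScheme.for_task(3)
        n = 200
        y = rng.integers(0, 4, n)
        p = rng.dirichlet(np.ones(4), size=n)
        rep = compute_report(y, p, scheme)
        assert rep.confusion.n == n
        assert 0 <= rep.accuracy <= 1
        assert rep.accuracy == pytest.approx((p.argmax(1) == y).mean())
        assert len(rep.per_class_npv) == 4

    def test_npv_one_vs_rest_oracle(self, rng):
        scheme = GradingScheme.for_task(1)
        y = rng.integers(0, 3, 100)
        p = rng.dirichlet(np.ones(3), size=100)
        rep = compute_report(y, p, scheme)
        pred = p.argmax(1)
        for c in range(3):
            tn = ((y != c) & (pred != c)).sum()
            fn = ((y == c) & (pred != c)).sum()
            expect = tn / (tn + fn) if tn + fn else np.nan
            assert rep.per_class_npv[c] == pytest.approx(expect, abs=1e-12)

    def test_rows_must_sum_to_one(self):
        with pytest.raises(InvalidInputError):
            compute_report(np.array([0, 1]), np.array([[0.5, 0.4, 0.0], [1, 0, 0]]),
                           GradingScheme.for_task(1))
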
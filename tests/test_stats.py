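"""Agreement, comparison and permutation statistics, with independent
cross-checks against sklearn / statsmodels implementations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mmgdecode.stats import (
    NullDistribution,
    agreement,
    cohens_d_vs_null,
    cohens_kappa,
    consensus_matrix,
    five_by_two_cv_ftest,
    five_by_two_ftest,
    kappa_from_matrix,
    mcnemar,
    percentage_agreement,
    perm_pvalue,
    permutation_null,
)


class TestPercentAgreement:
    def test_identical(self):
        assert percentage_agreement([1, 2, 3], [1, 2, 3]) == 100.0

    def test_fully_discordant(self):
        assert percentage_agreement([1, 1, 1], [2, 2, 2]) == 0.0

    def test_hand_count(self):
        assert percentage_agreement((1, 1, 2, 3), (1, 2, 2, 3)) == 75.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            percentage_agreement([1, 2], [1])


class TestKappa:
    def test_identical_nonconstant(self):
        assert cohens_kappa([0, 1, 2, 0], [0, 1, 2, 0]) == pytest.approx(1.0)

    def test_hand_matrix(self):
        # p_o = 0.7, p_e = 0.5 -> kappa = 0.4
        assert kappa_from_matrix([[20, 5], [10, 15]]) == pytest.approx(0.4)

    def test_independent_uniform_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 10000)
        b = rng.integers(0, 3, 10000)
        assert abs(cohens_kappa(a, b)) < 0.03

    def test_matrix_and_vector_paths_agree(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 500)
        b = rng.integers(0, 3, 500)
        assert cohens_kappa(a, b) == pytest.approx(
            kappa_from_matrix(consensus_matrix(a, b, 3))
        )

    def test_against_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, 400)
        b = np.where(rng.random(400) < 0.6, a, rng.integers(0, 3, 400))
        assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_both_constant_equal_undefined(self):
        with pytest.raises(ValueError):
            cohens_kappa([1, 1, 1], [1, 1, 1])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_relabeling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 3, 60)
        b = rng.integers(0, 3, 60)
        perm = rng.permutation(3)
        if len(np.unique(np.concatenate([a, b]))) < 2:
            return
        assert cohens_kappa(perm[a], perm[b]) == pytest.approx(cohens_kappa(a, b))
        assert percentage_agreement(perm[a], perm[b]) == percentage_agreement(a, b)


class TestMcNemar:
    def _vectors(self, b, c, n_both_ok=30):
        """Construct aligned predictions with given discordant counts."""
        truth = np.zeros(n_both_ok + b + c, dtype=int)
        pa = truth.copy()
        pb = truth.copy()
        pb[n_both_ok : n_both_ok + b] = 1  # A correct, B wrong
        pa[n_both_ok + b :] = 1  # A wrong, B correct
        return pa, pb, truth

    def test_hand_values_b10_c0(self):
        res = mcnemar(*self._vectors(10, 0))
        assert res.b == 10 and res.c == 0
        assert res.chi2 == pytest.approx(8.1)
        assert res.cohens_g == pytest.approx(0.5)

    def test_hand_values_b5_c5(self):
        res = mcnemar(*self._vectors(5, 5))
        assert res.chi2 == pytest.approx(0.1)
        assert res.cohens_g == pytest.approx(0.0)

    def test_no_discordance_undefined(self):
        with pytest.raises(ValueError):
            mcnemar(*self._vectors(0, 0))

    def test_swap_antisymmetry(self):
        pa, pb, truth = self._vectors(7, 3)
        r1 = mcnemar(pa, pb, truth)
        r2 = mcnemar(pb, pa, truth)
        assert (r1.b, r1.c) == (r2.c, r2.b)
        assert r1.chi2 == r2.chi2

    def test_against_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        pa, pb, truth = self._vectors(12, 4)
        res = mcnemar(pa, pb, truth)
        table = [[30, res.b], [res.c, 0]]
        sm = sm_mcnemar(table, exact=False, correction=True)
        assert res.chi2 == pytest.approx(sm.statistic)
        assert res.p_value == pytest.approx(sm.pvalue)


class TestFiveByTwo:
    def test_hand_matrix(self):
        d = np.tile([0.1, 0.0], (5, 1))
        res = five_by_two_ftest(d)
        assert res.f_statistic == pytest.approx(1.0)
        assert res.df == (10, 5)
        assert res.p_value == pytest.approx(sps.f.sf(1.0, 10, 5))

    def test_identical_models_degenerate(self):
        with pytest.raises(ValueError, match="variance"):
            five_by_two_ftest(np.zeros((5, 2)))

    def test_harness_runs_evaluator(self):
        def eval_pair(rep, fold, seed):
            rng = np.random.default_rng(seed)
            return 0.9 + 0.02 * rng.random(), 0.6 + 0.02 * rng.random()

        res = five_by_two_cv_ftest(eval_pair, seed=0)
        assert res.f_statistic > 1.0
        assert res.diffs.shape == (5, 2)

    def test_strictly_better_model_detected(self):
        # accuracy gap well above the fold-to-fold jitter -> significant F
        hits = 0
        for trial in range(5):
            def eval_pair(rep, fold, seed, trial=trial):
                rng = np.random.default_rng(seed + 1000 * trial)
                return 0.95 + 0.01 * rng.random(), 0.70 + 0.01 * rng.random()

            if five_by_two_cv_ftest(eval_pair, seed=trial).p_value < 0.05:
                hits += 1
        assert hits >= 4


class TestPermutation:
    def test_null_distribution_validation(self):
        with pytest.raises(ValueError):
            NullDistribution(values=np.array([]))
        with pytest.raises(ValueError):
            permutation_null(lambda s: 0.5, n_perm=0)

    def test_pipeline_receives_deterministic_seeds(self):
        seen = []
        null1 = permutation_null(lambda s: seen.append(s) or float(s % 97), 10, seed=5)
        null2 = permutation_null(lambda s: float(s % 97), 10, seed=5)
        assert np.array_equal(null1.values, null2.values)
        assert len(set(seen)) == 10

    def test_pvalue_counting_rule(self):
        null = NullDistribution(values=np.linspace(0.2, 0.5, 1000))
        p_hi = perm_pvalue(0.9, null)
        assert p_hi.count == 0 and p_hi.display == "< 0.001"
        assert p_hi.add_one == pytest.approx(1 / 1001)
        p_med = perm_pvalue(float(np.median(null.values)), null)
        assert p_med.value == pytest.approx(0.5, abs=0.01)
        p_lo = perm_pvalue(0.0, null)
        assert p_lo.value == 1.0

    def test_cohens_d_hand_values(self):
        null = NullDistribution(values=np.array([0.30, 0.32, 0.34, 0.36]))
        assert cohens_d_vs_null(np.mean(null.values), null) == pytest.approx(0.0)
        sd = np.std(null.values, ddof=1)
        assert cohens_d_vs_null(0.33 + sd, null) == pytest.approx(1.0)
        assert cohens_d_vs_null(0.90, null) == pytest.approx((0.90 - 0.33) / sd)

    def test_zero_sd_null_rejected(self):
        null = NullDistribution(values=np.full(10, 0.3))
        with pytest.raises(ValueError):
            cohens_d_vs_null(0.5, null)

    def test_pvalues_superuniform_under_null(self):
        """Observations drawn from the null itself give p ~ U(0, 1)."""
        rng = np.random.default_rng(8)
        null = NullDistribution(values=rng.normal(size=500))
        ps = [perm_pvalue(obs, null).value for obs in rng.normal(size=200)]
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestAgreementSummary:
    def test_full_summary_consistency(self):
        rng = np.random.default_rng(9)
        a = rng.integers(0, 3, 300)
        b = np.where(rng.random(300) < 0.7, a, rng.integers(0, 3, 300))
        res = agreement(a, b, n_classes=3)
        assert res.matrix.sum() == 300
        assert res.percentage_agreement == pytest.approx(100 * np.trace(res.matrix) / 300)
        assert res.kappa == pytest.approx(cohens_kappa(a, b))
        assert -1.0 <= res.kappa <= 1.0
        assert 0.0 <= res.p_e <= 1.0
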
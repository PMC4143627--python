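"""Regression scans, FDR, genomic control, and the permutation test."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from admixscan import mapping, simpop
from admixscan.core import GeneticMap, LocalAncestryCallset


def tiny_callset(S_eur, pop_labels=("EUR", "AFR")):
    """Callset from a (n_snps, n) European dosage matrix; rest to pop 2."""
    S = np.asarray(S_eur, dtype=float)
    J, n = S.shape
    dosage = np.stack([S, 1.0 - S], axis=2)
    gmap = GeneticMap(
        snp_ids=np.array([f"s{j}" for j in range(J)], dtype=object),
        positions_bp=np.arange(1, J + 1) * 1000,
        positions_cm=np.arange(J, dtype=float),
    )
    return LocalAncestryCallset(dosage=dosage, gmap=gmap, pop_labels=pop_labels)


class TestResidualize:
    def test_uncorrelated_covariates_center_only(self, rng):
        # log-values constructed orthogonal to [1, age, sex]: residualizing
        # must reproduce plain centering of the log-values
        n = 200
        age = rng.uniform(20, 70, n)
        sex = rng.integers(0, 2, n)
        X = np.column_stack([np.ones(n), age, sex])
        raw = rng.standard_normal(n)
        clean = raw - X @ np.linalg.lstsq(X, raw, rcond=None)[0] + 5.0
        r = mapping.residualize_trait(np.exp(clean), age, sex)
        assert np.abs(r - (clean - clean.mean())).max() < 1e-8

    def test_perfect_linear_fit_zero_residuals(self):
        age = np.array([30.0, 40.0, 50.0, 60.0, 70.0])
        sex = np.array([0, 1, 0, 1, 0])
        vals = 2.0 + 0.5 * age
        r = mapping.residualize_trait(vals, age, sex, log_transform=False)
        assert np.abs(r).max() < 1e-10

    def test_matches_normal_equations_on_toy(self):
        age = np.array([25.0, 35.0, 45.0, 55.0, 65.0])
        sex = np.array([1, 0, 1, 0, 1])
        vals = np.array([110.0, 125.0, 118.0, 140.0, 132.0])
        X = np.column_stack([np.ones(5), age, sex])
        beta = np.linalg.solve(X.T @ X, X.T @ np.log(vals))
        expected = np.log(vals) - X @ beta
        got = mapping.residualize_trait(vals, age, sex)
        assert np.allclose(got, expected, atol=1e-12)
        assert abs(got.mean()) < 1e-10

    def test_nonpositive_value_under_log(self):
        with pytest.raises(ValueError):
            mapping.residualize_trait([1.0, -2.0], [30, 40], [0, 1])


class TestAdmixtureScan:
    def test_matches_statsmodels_oracle(self, rng):
        n, J = 6, 2
        S = rng.integers(0, 3, size=(J, n)) / 2.0
        callset = tiny_callset(S)
        y = rng.standard_normal(n)
        scan = mapping.admixture_scan(y, callset, "EUR")
        sbar = S.mean(axis=0)
        for j in range(J):
            X = np.column_stack([np.ones(n), sbar, S[j] - sbar])
            fit = sm.OLS(y, X).fit()
            assert scan.beta[j] == pytest.approx(fit.params[2], rel=1e-8)
            assert scan.se[j] == pytest.approx(fit.bse[2], rel=1e-8)
            assert scan.t[j] == pytest.approx(fit.tvalues[2], rel=1e-8)
            assert scan.p[j] == pytest.approx(fit.pvalues[2], rel=1e-8)

    def test_perfect_signal_dominates_scan(self, rng):
        n, J = 40, 30
        S = rng.integers(0, 3, size=(J, n)) / 2.0
        callset = tiny_callset(S)
        sbar = S.mean(axis=0)
        y = 2.0 * (S[7] - sbar)  # exact signal at SNP 7, no noise
        scan = mapping.admixture_scan(y, callset, "EUR")
        assert scan.p[7] < 1e-12
        assert scan.q[7] == scan.q.min()

    def test_constant_local_ancestry_flagged(self, rng):
        n = 20
        S = rng.integers(0, 3, size=(3, n)) / 2.0
        S[1] = 0.5  # constant across individuals: collinear with intercept
        callset = tiny_callset(S)
        scan = mapping.admixture_scan(rng.standard_normal(n), callset, "EUR")
        assert scan.flagged[1]
        assert scan.p[1] == 1.0
        assert not scan.flagged[[0, 2]].any()

    def test_too_few_individuals(self):
        callset = tiny_callset(np.array([[0.0, 0.5, 1.0]]))
        with pytest.raises(ValueError):
            mapping.admixture_scan(np.zeros(3), callset, "EUR")


class TestAncestryAdjustedScan:
    def test_matches_statsmodels_oracle_k2(self, rng):
        n, K = 5, 2
        S = rng.integers(0, 3, size=(1, n)) / 2.0
        callset = tiny_callset(S)
        G = rng.integers(0, 3, size=(1, n)) / 2.0
        q = np.array([[0.8, 0.2]])
        y = rng.standard_normal(n)
        scan = mapping.ancestry_adjusted_scan(y, G, callset, q)
        X = np.column_stack(
            [G[0], callset.dosage[0, :, 0] * q[0, 0], callset.dosage[0, :, 1] * q[0, 1]]
        )
        fit = sm.OLS(y, X).fit()
        assert scan.beta[0] == pytest.approx(fit.params[0], rel=1e-8)
        assert scan.se[0] == pytest.approx(fit.bse[0], rel=1e-8)
        assert scan.t[0] == pytest.approx(fit.tvalues[0], rel=1e-8)

    def test_uninformative_freqs_reduce_to_simple_regression(self, rng):
        # a single ancestral population: the lone alpha*q regressor is the
        # constant q, so the adjustment collapses to y ~ 1 + G
        n, J = 30, 4
        S = np.ones((J, n))
        gmap = tiny_callset(np.zeros((J, n))).gmap
        callset = LocalAncestryCallset(
            dosage=S[:, :, None], gmap=gmap, pop_labels=("EUR",)
        )
        G = rng.integers(0, 3, size=(J, n)) / 2.0
        q = np.full((J, 1), 0.5)
        y = rng.standard_normal(n)
        scan = mapping.ancestry_adjusted_scan(y, G, callset, q)
        for j in range(J):
            fit = sm.OLS(y, sm.add_constant(G[j])).fit()
            assert scan.beta[j] == pytest.approx(fit.params[1], rel=1e-6)
            assert scan.t[j] == pytest.approx(fit.tvalues[1], rel=1e-6)

    def test_collinear_genotype_flagged(self, rng):
        # G lies exactly in the span of the ancestry regressors
        n = 15
        S = rng.integers(0, 3, size=(1, n)) / 2.0
        callset = tiny_callset(S)
        q = np.full((1, 2), 0.5)
        G = callset.dosage[0] @ q[0]  # = 0.5 everywhere
        scan = mapping.ancestry_adjusted_scan(
            rng.standard_normal(n), G[None, :], callset, q
        )
        assert scan.flagged[0] and scan.p[0] == 1.0


class TestBhFdr:
    def test_all_equal(self):
        assert np.allclose(mapping.bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_hand_step_up(self):
        q = mapping.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_never_decreases(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=50)
            assert np.all(mapping.bh_fdr(p) >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mapping.bh_fdr([0.0, 0.5])


class TestGenomicControl:
    def test_uniform_null_lambda_near_one(self, rng):
        p = rng.uniform(0.0, 1.0, 10_000)
        p = np.clip(p, 1e-12, 1.0)
        assert mapping.genomic_control(p) == pytest.approx(1.0, abs=0.05)

    def test_doubled_t_scales_lambda_fourfold(self, rng):
        t = rng.standard_normal(20_000)
        p1 = 2 * stats.norm.sf(np.abs(t))
        p2 = 2 * stats.norm.sf(np.abs(2 * t))
        lam1 = mapping.genomic_control(p1)
        lam2 = mapping.genomic_control(p2)
        assert lam2 / lam1 == pytest.approx(4.0, rel=0.05)

    def test_needs_ten_snps(self):
        with pytest.raises(ValueError):
            mapping.genomic_control(np.full(5, 0.5))

    def test_degenerate_all_ones(self):
        with pytest.warns(UserWarning):
            assert mapping.genomic_control(np.ones(20)) == 0.0


class TestPermutationTest:
    def test_observed_zero_gives_p_one(self):
        res = mapping.permutation_excess_test(
            np.arange(8.0), lambda y: np.zeros(5), threshold=3.0, B=19, seed=1
        )
        assert res.observed == 0 and res.p_value == 1.0

    def test_p_never_zero_and_add_one_formula(self, rng, small_cohort):
        engine = mapping.AdmixtureScanEngine(small_cohort.callset, "EUR")
        y = rng.standard_normal(small_cohort.n)
        res = mapping.permutation_excess_test(
            y, engine, threshold=1.0, B=49, seed=3
        )
        expect = (1 + np.sum(res.perm_counts >= res.observed)) / 50.0
        assert res.p_value == pytest.approx(expect)
        assert res.p_value > 0.0

    def test_permutation_invariance_of_t(self, rng, small_cohort):
        # permuting individuals in both y and the design leaves t unchanged
        cs = small_cohort.callset
        y = rng.standard_normal(small_cohort.n)
        perm = rng.permutation(small_cohort.n)
        t1 = mapping.AdmixtureScanEngine(cs, "EUR").t_stats(y)
        cs_perm = LocalAncestryCallset(
            dosage=cs.dosage[:, perm, :], gmap=cs.gmap, pop_labels=cs.pop_labels
        )
        t2 = mapping.AdmixtureScanEngine(cs_perm, "EUR").t_stats(y[perm])
        assert np.allclose(t1, t2, atol=1e-10)

    def test_planted_signal_detected(self):
        panel = simpop.draw_ancestral_freqs(500, seed=61)
        cohort = simpop.simulate_cohort(
            panel,
            n=200,
            seed=62,
            trait=simpop.TraitSpec(
                ancestry_scope="local",
                causal_snp=250,
                ancestry_effect=1.0,
                noise_sd=0.1,
            ),
        )
        y = mapping.prepare_trait(cohort.phenotypes, "sbp")
        engine = mapping.AdmixtureScanEngine(cohort.callset, "EUR")
        res = mapping.permutation_excess_test(
            y, engine, threshold=3.0, B=199, seed=63
        )
        assert res.p_value <= 0.01

    def test_invalid_B(self, small_cohort, rng):
        engine = mapping.AdmixtureScanEngine(small_cohort.callset, "EUR")
        with pytest.raises(ValueError):
            mapping.permutation_excess_test(
                rng.standard_normal(small_cohort.n), engine, B=0
            )
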
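"""Segment counting, generations dating, and call-set comparison metrics."""

import numpy as np
import pytest

from admixscan import ancestry_metrics as am
from admixscan import simpop
from admixscan.core import GeneticMap, LocalAncestryCallset
from admixscan.simpop import HaplotypePath


def path(labels, breaks, span=(0.0, 100.0)):
    return HaplotypePath(np.array(breaks), np.array(labels), span)


def make_callset(dosage, pop_labels=("EUR", "AFR", "NAM")):
    dosage = np.asarray(dosage, dtype=float)
    n = dosage.shape[0]
    gmap = GeneticMap(
        snp_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        positions_bp=np.arange(1, n + 1) * 1000,
        positions_cm=np.arange(n, dtype=float),
    )
    return LocalAncestryCallset(dosage=dosage, gmap=gmap, pop_labels=pop_labels)


class TestCountSegments:
    def test_uniform_ancestry_two_segments(self):
        pairs = [(path([0], []), path([0], []))]
        assert am.count_segments(pairs).counts[0] == 2

    def test_hand_counted_paths(self):
        # haplotypes (EUR, AFR, EUR) and (NAM): 3 + 1 segments, and the
        # same after binarizing to European
        pairs = [(path([0, 1, 0], [30.0, 60.0]), path([2], []))]
        assert am.count_segments(pairs).counts[0] == 4
        assert am.count_segments(pairs, target_pop=0).counts[0] == 4

    def test_snp_density_invariance(self):
        # inserting SNPs inside segments never changes the count
        pairs = [(path([0, 1], [50.0]), path([2, 0], [20.0]))]
        for n_snps in (5, 50, 500):
            cm = np.linspace(0.0, 100.0, n_snps)
            gmap = GeneticMap(
                snp_ids=np.array([f"s{i}" for i in range(n_snps)], dtype=object),
                positions_bp=(cm * 1e4).astype(int) + np.arange(n_snps) + 1,
                positions_cm=cm,
            )
            eye = np.eye(3)
            dosage = 0.5 * (
                eye[pairs[0][0].labels_at(cm)] + eye[pairs[0][1].labels_at(cm)]
            )[:, None, :]
            callset = LocalAncestryCallset(dosage=dosage, gmap=gmap)
            assert am.count_segments(callset).counts[0] == 4

    def test_dosage_counting_matches_paths_at_high_density(self, small_panel):
        cohort = simpop.simulate_cohort(
            simpop.draw_ancestral_freqs(2000, seed=6), n=50, g=10, seed=12
        )
        from_paths = am.count_segments(cohort.hap_paths, target_pop=0)
        from_dosage = am.count_segments(cohort.callset, target_pop=0)
        # dosage-level counting can only miss switches between adjacent SNPs
        assert from_dosage.mean <= from_paths.mean
        assert from_paths.mean - from_dosage.mean < 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            am.count_segments([])


class TestEstimateGenerations:
    def test_identity_case(self):
        assert am.estimate_generations(1.0, 0.5, 1.0) == pytest.approx(1.0)

    def test_segment_means_date_admixture_between_10_and_12(self):
        # the two high-density unphased call sets' mean segment counts
        for A, expected in [(25.49, 11.976582), (22.40, 10.524733)]:
            n = am.estimate_generations(A, 0.6, 2.217)
            assert n == pytest.approx(expected, abs=1e-6)
            assert 10.0 <= n <= 12.0

    @pytest.mark.parametrize("a,L", [(0.0, 1.0), (1.0, 1.0), (0.5, 0.0)])
    def test_degenerate_inputs_rejected(self, a, L):
        with pytest.raises(ValueError):
            am.estimate_generations(10.0, a, L)

    def test_recovery_moderate_cohort(self, small_panel):
        cohort = simpop.simulate_cohort(small_panel, n=200, g=10.0, seed=55)
        seg = am.count_segments(cohort.hap_paths, target_pop=0)
        a_i = np.clip(cohort.global_props[:, 0], 1e-6, 1 - 1e-6)
        n_hat = am.estimate_generations(
            seg.counts, a_i, small_panel.gmap.length_morgans
        ).mean()
        assert 9.0 <= n_hat <= 12.0


class TestCompareToGlobal:
    def test_exact_consistency(self, small_cohort):
        m = small_cohort.local_dosage.mean(axis=0)
        cmp = am.compare_to_global(small_cohort.callset, m)
        assert cmp.pooled_r == pytest.approx(1.0)
        assert cmp.mean_deviation_pct == pytest.approx(0.0)

    def test_hand_deviation_example(self):
        # K=2: |0.7-0.6| + |0.3-0.4| + 0 + 0 over 4 cells = 5%
        dosage = np.array([[[0.5, 0.5], [0.5, 0.5]], [[1.0, 0.0], [0.5, 0.5]]])
        callset = make_callset(dosage, pop_labels=("EUR", "NAM"))
        assert callset.dosage.mean(axis=0)[0, 0] == pytest.approx(0.75)
        cmp = am.compare_to_global(callset, np.array([[0.7, 0.3], [0.5, 0.5]]))
        # local means are (0.75, 0.25) and (0.5, 0.5)
        assert cmp.mean_deviation_pct == pytest.approx(
            100 * (0.05 + 0.05 + 0 + 0) / 4
        )

    def test_deviation_monotone_in_flip_rate(self):
        # deviation is measured against the truth call set's own locus
        # means, so rate 0 gives exactly 0 and each extra flip adds bias
        panel = simpop.draw_ancestral_freqs(500, seed=41)
        cohort = simpop.simulate_cohort(panel, n=100, seed=42)
        m_truth = cohort.callset.dosage.mean(axis=0)
        devs = []
        for rate in (0.0, 0.05, 0.1, 0.2):
            calls = simpop.perturb_ancestry(cohort.callset, rate, seed=7)
            devs.append(am.compare_to_global(calls, m_truth).mean_deviation_pct)
        assert devs[0] == 0.0
        assert all(a < b for a, b in zip(devs, devs[1:]))


class TestDiploidInconsistency:
    def test_identical_and_total(self, small_cohort):
        cs = small_cohort.callset
        assert am.diploid_inconsistency(cs, cs) == 0.0
        flipped = simpop.perturb_ancestry(cs, 1.0, seed=1)
        assert am.diploid_inconsistency(cs, flipped) == pytest.approx(100.0)

    def test_hand_count_quarter(self):
        a = make_callset(
            [
                [[1.0, 0.0, 0.0]],
                [[0.5, 0.5, 0.0]],
                [[0.0, 0.5, 0.5]],
                [[0.0, 0.0, 1.0]],
            ]
        )
        b = make_callset(
            [
                [[1.0, 0.0, 0.0]],
                [[0.5, 0.5, 0.0]],
                [[0.5, 0.0, 0.5]],  # one mismatching state of four
                [[0.0, 0.0, 1.0]],
            ]
        )
        assert am.diploid_inconsistency(a, b) == pytest.approx(25.0)

    def test_symmetric_and_relabel_invariant(self, small_cohort):
        cs = small_cohort.callset
        other = simpop.perturb_ancestry(cs, 0.3, seed=5)
        assert am.diploid_inconsistency(cs, other) == am.diploid_inconsistency(
            other, cs
        )
        perm = [2, 0, 1]
        a2 = make_callset(cs.dosage[:, :, perm])
        b2 = make_callset(other.dosage[:, :, perm])
        assert am.diploid_inconsistency(a2, b2) == pytest.approx(
            am.diploid_inconsistency(cs, other)
        )

    def test_shape_mismatch_rejected(self, small_cohort):
        short = make_callset(small_cohort.callset.dosage[:10])
        with pytest.raises(ValueError):
            am.diploid_inconsistency(small_cohort.callset, short)


class TestHardCall:
    def test_snaps_to_nearest_state(self):
        assert np.array_equal(
            am.hard_call(np.array([0.6, 0.4, 0.0])), [0.5, 0.5, 0.0]
        )
        assert np.array_equal(
            am.hard_call(np.array([0.9, 0.05, 0.05])), [1.0, 0.0, 0.0]
        )

    def test_tie_broken_in_population_order(self):
        # equidistant from the three heterozygous states: lexicographically
        # first state (pop 0 + pop 1) wins
        snapped = am.hard_call(np.array([1 / 3, 1 / 3, 1 / 3]))
        assert np.array_equal(snapped, [0.5, 0.5, 0.0])
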
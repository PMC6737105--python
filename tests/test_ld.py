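import itertools

import numpy as np
import pytest

from popgenpipe import (
    MISSING,
    bin_ld_decay,
    high_ld_pairs,
    make_two_locus_sample,
    pairwise_r2,
)
from .conftest import make_matrix


def brute_force_haplotype_r2(calls):
    """Oracle for phase-unambiguous two-locus samples: no double
    heterozygotes, so haplotypes can be counted directly."""
    a, b = calls[:, 0], calls[:, 1]
    assert not np.any((a == 1) & (b == 1)), "sample must be phase-unambiguous"
    haps = []
    for ga, gb in zip(a, b):
        # split each genotype into two haplotypes; with at most one het
        # locus per individual the assignment is unique
        ga, gb = int(ga), int(gb)
        ha = [1, 1] * (ga == 2) + [1, 0] * (ga == 1) + [0, 0] * (ga == 0)
        hb = [1, 1] * (gb == 2) + [1, 0] * (gb == 1) + [0, 0] * (gb == 0)
        haps += list(zip(ha, hb))
    haps = np.array(haps, dtype=float)
    pA, pB = haps.mean(axis=0)
    pAB = (haps[:, 0] * haps[:, 1]).mean()
    D = pAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    return D * D / denom


class TestEstimators:
    def test_em_equals_counting_oracle_phase_unambiguous(self, rng):
        # build many random phase-unambiguous samples and compare exactly
        for trial in range(25):
            while True:
                calls = rng.integers(0, 3, size=(40, 2)).astype(np.int8)
                both_het = (calls[:, 0] == 1) & (calls[:, 1] == 1)
                calls[both_het, 1] = rng.choice([0, 2], size=both_het.sum())
                f = calls.mean(axis=0) / 2
                if np.all((f > 0.05) & (f < 0.95)):
                    break
            m = make_matrix(calls)
            em = pairwise_r2(m, estimator="em_haplotype").table["r2"].iloc[0]
            oracle = brute_force_haplotype_r2(calls)
            assert em == pytest.approx(oracle, abs=1e-8), trial

    def test_em_and_composite_agree_under_hwe(self):
        diffs = []
        for s in range(30):
            m = make_two_locus_sample(0.3, 0.5, 0.05, 55, seed=s)
            em = pairwise_r2(m, estimator="em_haplotype").table["r2"].iloc[0]
            comp = pairwise_r2(m, estimator="composite").table["r2"].iloc[0]
            diffs.append(abs(em - comp))
        assert np.mean(diffs) < 0.02

    def test_composite_handles_missing_pairwise_complete(self):
        calls = np.array(
            [[0, 0], [1, 1], [2, 2], [0, 0], [2, 2], [1, MISSING], [MISSING, 1]],
            dtype=np.int8,
        )
        m = make_matrix(calls)
        r2 = pairwise_r2(m, estimator="composite").table["r2"].iloc[0]
        # complete rows are perfectly correlated
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_unknown_estimator_rejected(self, small_wf):
        m, _ = small_wf
        with pytest.raises(ValueError):
            pairwise_r2(m, estimator="nope")

    def test_r2_in_unit_interval(self, small_wf):
        m, _ = small_wf
        pairs = pairwise_r2(m, window_bp=2_000_000)
        r2 = pairs.table["r2"].to_numpy()
        assert np.all((r2 >= 0) & (r2 <= 1))


class TestWindowing:
    def test_only_within_chromosome_within_window(self, small_wf):
        m, _ = small_wf
        pairs = pairwise_r2(m, window_bp=1_000_000).table
        assert (pairs["distance_bp"] <= 1_000_000).all()
        assert (pairs["distance_bp"] > 0).all()
        # positions on the same chromosome only
        assert set(pairs["chrom"]) <= set(m.chromosomes)

    def test_single_chromosome_selection(self, small_wf):
        m, _ = small_wf
        chrom = m.chromosomes[0]
        pairs = pairwise_r2(m, chromosome=chrom, window_bp=2_000_000).table
        assert set(pairs["chrom"]) == {chrom}

    def test_pair_count_matches_combinatorics(self):
        # 5 markers 10kb apart, window 25kb: pairs at lag 1 (4) + lag 2 (3)
        calls = np.array(
            [[0, 1, 2, 0, 1], [1, 2, 0, 1, 2], [2, 0, 1, 2, 0], [0, 1, 1, 0, 1]],
            dtype=np.int8,
        )
        m = make_matrix(calls, positions=[10_000 * (i + 1) for i in range(5)])
        pairs = pairwise_r2(m, window_bp=25_000).table
        assert len(pairs) == 7

    def test_chunking_invariant(self, small_wf):
        m, _ = small_wf
        a = pairwise_r2(m, window_bp=3_000_000, chunk_size=7).table
        b = pairwise_r2(m, window_bp=3_000_000, chunk_size=4096).table
        assert np.allclose(
            a.sort_values(["chrom", "i", "j"])["r2"].to_numpy(),
            b.sort_values(["chrom", "i", "j"])["r2"].to_numpy(),
        )


class TestDecayAndThreshold:
    def test_bins_cover_range_and_counts_sum(self, small_wf):
        m, _ = small_wf
        pairs = pairwise_r2(m, window_bp=10_000_000)
        curve = bin_ld_decay(pairs, bin_width=100_000, max_dist=10_000_000)
        assert len(curve.bin_lo) == 100
        assert curve.n_pairs.sum() == len(pairs.table)
        assert curve.overall_mean == pytest.approx(pairs.table["r2"].mean())

    def test_decay_monotone_on_average(self, small_wf):
        m, _ = small_wf
        pairs = pairwise_r2(m, window_bp=10_000_000)
        curve = bin_ld_decay(pairs, bin_width=2_000_000, max_dist=10_000_000)
        vals = curve.mean_r2[~np.isnan(curve.mean_r2)]
        assert vals[0] > vals[-1]

    def test_empty_bin_is_nan(self):
        # the two loci sit 100 kb apart, so exactly one 10 kb bin is occupied
        m = make_two_locus_sample(0.5, 0.5, 0.1, 50, seed=0)
        pairs = pairwise_r2(m)
        curve = bin_ld_decay(pairs, bin_width=10_000, max_dist=1_000_000)
        assert np.isnan(curve.mean_r2).sum() == len(curve.mean_r2) - 1

    def test_high_ld_strict_threshold(self, small_wf):
        m, _ = small_wf
        pairs = pairwise_r2(m, window_bp=2_000_000)
        top = high_ld_pairs(pairs, threshold=0.8)
        assert (top.table["r2"] > 0.8).all()
        with pytest.raises(ValueError):
            high_ld_pairs(pairs, threshold=1.5)
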
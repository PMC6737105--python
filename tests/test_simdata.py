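import numpy as np
import pytest

from popgenpipe import (
    MISSING,
    SimConfig,
    make_two_locus_sample,
    pairwise_r2,
    simulate_admixed_genotypes,
    simulate_wf_population,
)


class TestWrightFisher:
    def test_seed_determinism(self):
        cfg = SimConfig(
            n_individuals=20, n_chromosomes=2, chrom_length_bp=10_000_000,
            marker_density=5, ne_trajectory=[(0, 30)], n_generations=20, seed=42,
        )
        a, _ = simulate_wf_population(cfg)
        b, _ = simulate_wf_population(cfg)
        assert np.array_equal(a.calls, b.calls)
        assert a.variants.equals(b.variants)

    def test_genotypes_in_range_and_truth(self, small_wf):
        m, truth = small_wf
        assert set(np.unique(m.calls)) <= {0, 1, 2}
        assert truth.true_ne_trajectory == [(0, 60)]
        assert truth.parents is not None and truth.parents.shape == (30, 2)

    def test_no_recombination_keeps_chromosome_blocks(self):
        # with zero recombination every chromosome descends as one block:
        # loci fixed together, so any two polymorphic loci that started in
        # complete association on a founder haplotype stay perfectly
        # correlated in haplotype terms; at the genotype level duplicated
        # founder columns remain duplicated
        cfg = SimConfig(
            n_individuals=25, n_chromosomes=1, chrom_length_bp=5_000_000,
            marker_density=4, recomb_rate=0.0, ne_trajectory=[(0, 25)],
            n_generations=30, seed=9,
        )
        m, _ = simulate_wf_population(cfg)
        pairs = pairwise_r2(m, estimator="composite")
        # haplotype blocks drift together -> substantial residual LD remains
        assert len(pairs) == 0 or pairs.table["r2"].mean() > 0.3

    def test_population_size_below_two_rejected(self):
        cfg = SimConfig(ne_trajectory=[(0, 1)])
        with pytest.raises(ValueError):
            simulate_wf_population(cfg)

    def test_missing_rate_injected(self):
        cfg = SimConfig(
            n_individuals=40, n_chromosomes=1, chrom_length_bp=10_000_000,
            marker_density=10, ne_trajectory=[(0, 40)], n_generations=3,
            missing_rate=0.2, seed=5,
        )
        m, _ = simulate_wf_population(cfg)
        frac = (m.calls == MISSING).mean()
        assert 0.15 < frac < 0.25

    def test_allele_frequency_conserved_in_expectation(self):
        # neutral drift: mean final frequency over replicates matches the
        # founder frequency within Monte-Carlo error
        diffs = []
        for s in range(10):
            cfg = SimConfig(
                n_individuals=50, n_chromosomes=1, chrom_length_bp=10_000_000,
                marker_density=10, ne_trajectory=[(0, 50)], n_generations=10,
                seed=300 + s,
            )
            m, _ = simulate_wf_population(cfg)
            rng = np.random.default_rng(300 + s)
            # founder frequencies are the first draws after positions
            # (re-derive by re-running the generator's own stream is fragile;
            #  instead compare generation-0 to final via a fresh 0-generation run)
            cfg0 = SimConfig(**{**cfg.__dict__, "n_generations": 1})
            m0, _ = simulate_wf_population(cfg0)
            diffs.append(
                m.allele_frequencies().mean() - m0.allele_frequencies().mean()
            )
        assert abs(np.mean(diffs)) < 0.02

    def test_heterozygosity_decays_at_drift_rate(self):
        # expected heterozygosity declines ~(1 - 1/2N) per generation
        from popgenpipe import heterozygosity

        n_gen, N = 40, 30
        ratios = []
        for s in range(8):
            base = dict(
                n_individuals=N, n_chromosomes=1, chrom_length_bp=10_000_000,
                marker_density=15, ne_trajectory=[(0, N)], seed=800 + s,
                monogamy=False,
            )
            early, _ = simulate_wf_population(SimConfig(**base, n_generations=1))
            late, _ = simulate_wf_population(SimConfig(**base, n_generations=n_gen))
            he = lambda m: (2 * m.allele_frequencies() * (1 - m.allele_frequencies())).mean()
            ratios.append(he(late) / he(early))
        expected = (1 - 1 / (2 * N)) ** (n_gen - 1)
        assert abs(np.log(np.mean(ratios)) - np.log(expected)) < 0.25


class TestAdmixed:
    def test_truth_invariants(self):
        m, truth = simulate_admixed_genotypes(K=3, F=0.1, alpha=0.5, n=40, m=200, seed=1)
        assert np.allclose(truth.true_Q.sum(axis=1), 1.0, atol=1e-12)
        assert truth.true_P.shape == (3, 200)
        assert np.all((truth.true_F >= 0) & (truth.true_F < 1))
        assert set(np.unique(m.calls)) <= {0, 1, 2}

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            simulate_admixed_genotypes(K=2, F=0.1, alpha=0.0, n=10, m=10, seed=0)

    def test_k1_is_panmictic(self):
        from popgenpipe import weir_cockerham_fst

        m, _ = simulate_admixed_genotypes(K=1, F=0.1, alpha=1.0, n=80, m=3000, seed=2)
        half1 = m.subset_samples(np.arange(40))
        half2 = m.subset_samples(np.arange(40, 80))
        fst = weir_cockerham_fst(half1, half2).mean_theta
        assert abs(fst) < 0.01

    def test_explicit_q_matrix(self):
        Q = np.zeros((10, 2))
        Q[:5, 0] = 1
        Q[5:, 1] = 1
        _, truth = simulate_admixed_genotypes(K=2, F=0.2, alpha=1.0, n=10, m=50, seed=3, Q=Q)
        assert np.array_equal(truth.true_Q, Q)


class TestTwoLocus:
    def test_infeasible_d_reports_range(self):
        with pytest.raises(ValueError, match="feasible range"):
            make_two_locus_sample(0.1, 0.1, 0.5, 100, seed=0)

    def test_equilibrium_r2_near_zero(self):
        m = make_two_locus_sample(0.4, 0.6, 0.0, 20_000, seed=1)
        r2 = pairwise_r2(m, estimator="em_haplotype").table["r2"].iloc[0]
        assert r2 < 0.002

    def test_complete_association_r2_one(self):
        # pA=pB=0.5, D=0.25: only AB and ab haplotypes exist
        m = make_two_locus_sample(0.5, 0.5, 0.25, 500, seed=2)
        r2 = pairwise_r2(m, estimator="em_haplotype").table["r2"].iloc[0]
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_population_r2_closed_form(self):
        # r2 = D^2 / (pA qA pB qB) = 0.01 / 0.0625 = 0.16
        vals = [
            pairwise_r2(
                make_two_locus_sample(0.5, 0.5, 0.1, 20_000, seed=s),
                estimator="em_haplotype",
            ).table["r2"].iloc[0]
            for s in range(5)
        ]
        assert np.mean(vals) == pytest.approx(0.16, abs=0.01)
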
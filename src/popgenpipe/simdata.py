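"""Synthetic genotype data with known demographic truth.

Three generators cover the needs of the downstream stages:

* :func:`simulate_wf_population` — a discrete-generation forward-in-time
  Wright–Fisher simulation of diploids with recombination and an arbitrary
  piecewise-constant Ne trajectory.  It is the ground-truth source for the
  LD-decay and effective-population-size recovery experiments.
* :func:`simulate_admixed_genotypes` — the Balding–Nichols / Dirichlet
  admixture model, the ground truth for Fst calibration and ancestry
  (admixture) recovery.
* :func:`make_two_locus_sample` — exact two-locus haplotype draws for the
  r-squared estimator oracles.

Every generator takes an explicit seed and is bit-for-bit reproducible.
Founder haplotypes are drawn site-independently (minor-allele frequency
Uniform(0.05, 0.5) by default), so linkage disequilibrium builds up through
drift alone; recovery experiments therefore run a burn-in of at least 2N
generations before sampling.  There is no mutation, no selection and no
overlapping generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_wf_population",
    "simulate_admixed_genotypes",
    "make_two_locus_sample",
]


@dataclass
class SimConfig:
    """Parameters of a Wright–Fisher forward simulation.

    Attributes
    ----------
    n_individuals
        Diploids sampled from the final generation.
    n_chromosomes, chrom_length_bp
        Genome layout; every chromosome has the same physical length.
    marker_density
        Markers per megabase; positions are drawn uniformly.
    recomb_rate
        Morgans per megabase (default 0.01, i.e. 1 cM/Mb).
    ne_trajectory
        Piecewise-constant census size as ``[(generation, N), ...]``
        breakpoints; the size at generation g is that of the latest
        breakpoint <= g.  Single entry ``[(0, N)]`` means constant N.
    n_generations
        Number of discrete generations simulated after the founders.
    init_maf_dist
        ``("uniform", low, high)`` for founder minor-allele frequencies.
    monogamy
        Pair parents into exclusive couples each generation (the
        non-random-mating regime assumed by the contemporary-Ne estimator);
        otherwise each offspring draws two distinct parents at random.
    missing_rate
        Per-call missing probability injected into the sampled genotypes.
    seed
        Fixes the full output bit-for-bit.
    """

    n_individuals: int = 50
    n_chromosomes: int = 4
    chrom_length_bp: int = 40_000_000
    marker_density: float = 12.5
    recomb_rate: float = 0.01
    ne_trajectory: list = field(default_factory=lambda: [(0, 100)])
    n_generations: int = 200
    init_maf_dist: tuple = ("uniform", 0.05, 0.5)
    monogamy: bool = True
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_individuals, self.n_chromosomes, self.chrom_length_bp) <= 0:
            raise ValueError("counts and lengths must be positive")
        if self.marker_density <= 0:
            raise ValueError("marker_density must be positive")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be non-negative")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not self.ne_trajectory:
            raise ValueError("ne_trajectory must have at least one breakpoint")
        for _, n in self.ne_trajectory:
            if n < 2:
                raise ValueError("population sizes must be >= 2 for sexual reproduction")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth emitted alongside every synthetic dataset."""

    true_ne_trajectory: list | None = None
    true_Q: np.ndarray | None = None
    true_P: np.ndarray | None = None
    true_F: np.ndarray | None = None
    #: couple index of each sampled individual's (mother, father), WF only
    parents: np.ndarray | None = None

    def validate(self) -> None:
        if self.true_Q is not None:
            if not np.allclose(self.true_Q.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError("true_Q rows must sum to 1")
        if self.true_F is not None:
            f = np.asarray(self.true_F, dtype=float)
            if np.any((f < 0) | (f >= 1)):
                raise ValueError("true_F must lie in [0, 1)")


def _size_at(trajectory, g: int) -> int:
    n = trajectory[0][1]
    for gen, size in trajectory:
        if gen <= g:
            n = size
        else:
            break
    return int(n)


def _draw_positions(rng, length_bp: int, n_markers: int) -> np.ndarray:
    pos = np.sort(rng.choice(np.arange(1, length_bp + 1), size=n_markers, replace=False))
    return pos.astype(np.int64)


def _gametes(rng, hap_a, hap_b, morgans, pos_morgans):
    """One recombinant gamete per row of the parental haplotype pair.

    ``hap_a``/``hap_b`` are (n, m) int8 haplotypes of each parent;
    crossover counts are Poisson(``morgans``) with breakpoints uniform on
    the genetic map.
    """
    n, m = hap_a.shape
    start = rng.integers(0, 2, size=n)
    k = rng.poisson(morgans, size=n) if morgans > 0 else np.zeros(n, dtype=int)
    out = np.where(start[:, None] == 0, hap_a, hap_b).copy()
    for i in np.flatnonzero(k > 0):
        breaks = np.sort(rng.uniform(0.0, morgans, size=k[i]))
        parity = (start[i] + np.searchsorted(breaks, pos_morgans, side="right")) % 2
        out[i] = np.where(parity == 0, hap_a[i], hap_b[i])
    return out


def simulate_wf_population(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Forward-in-time Wright–Fisher simulation of diploid genotypes.

    Founder haplotypes are drawn site-independently from ``init_maf_dist``;
    each subsequent generation draws offspring by sampling parents
    (monogamous couples by default), forming gametes by recombination with
    Poisson crossover counts per chromosome.  The final generation is
    sampled down to ``n_individuals``.  Monomorphic loci are retained — QC
    removes them downstream.

    Returns the genotypes and a :class:`SimTruth` carrying the Ne
    trajectory and the sampled individuals' parental couple indices.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    m_per_chrom = max(2, int(round(config.marker_density * config.chrom_length_bp / 1e6)))
    chrom_len_morgans = config.recomb_rate * config.chrom_length_bp / 1e6

    positions, pos_morgans = [], []
    for _ in range(config.n_chromosomes):
        pos = _draw_positions(rng, config.chrom_length_bp, m_per_chrom)
        positions.append(pos)
        pos_morgans.append((pos - 1) / 1e6 * config.recomb_rate)
    m_total = m_per_chrom * config.n_chromosomes
    if m_total == 0:
        raise ValueError("simulation would contain zero markers")

    # founders
    name, lo, hi = config.init_maf_dist
    if name != "uniform":
        raise ValueError(f"unknown init_maf_dist {name!r}")
    founder_p = rng.uniform(lo, hi, size=m_total)
    n0 = _size_at(config.ne_trajectory, 0)
    haps = (rng.random((2 * n0, m_total)) < founder_p).astype(np.int8)

    parents_of = None
    for g in range(1, config.n_generations + 1):
        n_parents = haps.shape[0] // 2
        n_off = _size_at(config.ne_trajectory, g)
        if config.monogamy:
            if n_parents < 2:
                raise ValueError("cannot pair fewer than two parents")
            perm = rng.permutation(n_parents)
            n_pairs = n_parents // 2
            couples = perm[: 2 * n_pairs].reshape(n_pairs, 2)
            pick = rng.integers(0, n_pairs, size=n_off)
            mothers = couples[pick, 0]
            fathers = couples[pick, 1]
            parents_of = np.column_stack([pick, pick])  # couple index
        else:
            mothers = rng.integers(0, n_parents, size=n_off)
            shift = rng.integers(1, n_parents, size=n_off)
            fathers = (mothers + shift) % n_parents  # distinct from mother
            parents_of = np.column_stack([mothers, fathers])

        new = np.empty((2 * n_off, m_total), dtype=np.int8)
        for c in range(config.n_chromosomes):
            lo_i = c * m_per_chrom
            sl = slice(lo_i, lo_i + m_per_chrom)
            new[0::2, sl] = _gametes(
                rng, haps[2 * mothers, sl], haps[2 * mothers + 1, sl],
                chrom_len_morgans, pos_morgans[c],
            )
            new[1::2, sl] = _gametes(
                rng, haps[2 * fathers, sl], haps[2 * fathers + 1, sl],
                chrom_len_morgans, pos_morgans[c],
            )
        haps = new

    n_final = haps.shape[0] // 2
    if config.n_individuals > n_final:
        raise ValueError(
            f"cannot sample {config.n_individuals} from final generation of {n_final}"
        )
    keep = np.sort(rng.choice(n_final, size=config.n_individuals, replace=False))
    calls = (haps[2 * keep] + haps[2 * keep + 1]).astype(np.int8)

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING

    records = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        for j, p in enumerate(positions[c]):
            records.append((chrom, int(p), f"{chrom}_{p}", "A", "C"))
    variants = pd.DataFrame(records, columns=["chrom", "pos", "id", "ref", "alt"])
    samples = pd.DataFrame(
        {"id": [f"ind{i + 1}" for i in range(config.n_individuals)], "population": "sim"}
    )
    truth = SimTruth(
        true_ne_trajectory=list(config.ne_trajectory),
        parents=parents_of[keep] if parents_of is not None else None,
    )
    truth.validate()
    return GenotypeMatrix(calls, variants, samples), truth


def simulate_admixed_genotypes(
    K: int,
    F,
    alpha: float,
    n: int,
    m: int,
    seed: int,
    ancestral_maf: tuple = (0.1, 0.9),
    population: str = "admix",
    Q: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Balding–Nichols admixture model with Dirichlet ancestry fractions.

    Ancestral population k's allele frequency at each locus is Beta
    distributed around a common ancestral frequency with dispersion set by
    the divergence parameter ``F[k]``; each sample's ancestry vector is
    Dirichlet(``alpha``), or taken from an explicit ``Q`` (n x K, rows on
    the simplex — e.g. vertex rows for discrete subpopulations); genotypes
    are Binomial(2, q_i . p_j).
    """
    if K < 1 or m < 1 or n < 1:
        raise ValueError("K, n, m must be positive")
    if np.isscalar(alpha):
        alpha_vec = np.full(K, float(alpha))
    else:
        alpha_vec = np.asarray(alpha, dtype=float)
    if np.any(alpha_vec <= 0):
        raise ValueError("alpha must be positive")
    f = np.full(K, float(F)) if np.isscalar(F) else np.asarray(F, dtype=float)
    if f.shape != (K,):
        raise ValueError("F must be scalar or length K")
    if np.any((f < 0) | (f >= 1)):
        raise ValueError("F must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(*ancestral_maf, size=m)
    P = np.empty((K, m))
    for k in range(K):
        if f[k] == 0:
            P[k] = p_anc
        else:
            shape = (1.0 - f[k]) / f[k]
            P[k] = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
    if Q is None:
        Q = rng.dirichlet(alpha_vec, size=n)
    else:
        Q = np.asarray(Q, dtype=float)
        if Q.shape != (n, K):
            raise ValueError("explicit Q must be n x K")
        if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("explicit Q rows must sum to 1")
    dose_p = Q @ P
    calls = rng.binomial(2, dose_p).astype(np.int8)

    step = 10_000
    records = [
        ("chr1", (j + 1) * step, f"snp{j + 1}", "A", "C") for j in range(m)
    ]
    variants = pd.DataFrame(records, columns=["chrom", "pos", "id", "ref", "alt"])
    samples = pd.DataFrame(
        {"id": [f"ind{i + 1}" for i in range(n)], "population": population}
    )
    truth = SimTruth(true_Q=Q, true_P=P, true_F=f)
    truth.validate()
    return GenotypeMatrix(calls, variants, samples), truth


def make_two_locus_sample(
    pA: float, pB: float, D: float, n: int, seed: int
) -> GenotypeMatrix:
    """Draw n diploids from an exact two-locus haplotype distribution.

    Haplotype frequencies are ``(pA pB + D, pA qB - D, qA pB - D,
    qA qB + D)``; an infeasible D raises with the feasible range.  Both loci
    sit on one chromosome at 100 kb spacing.
    """
    qA, qB = 1.0 - pA, 1.0 - pB
    h = np.array([pA * pB + D, pA * qB - D, qA * pB - D, qA * qB + D])
    if np.any(h < -1e-12) or np.any(h > 1 + 1e-12):
        d_min = max(-pA * pB, -qA * qB)
        d_max = min(pA * qB, qA * pB)
        raise ValueError(
            f"D={D} infeasible for pA={pA}, pB={pB}; feasible range "
            f"[{d_min:.6g}, {d_max:.6g}]"
        )
    h = np.clip(h, 0, 1)
    h = h / h.sum()
    rng = np.random.default_rng(seed)
    # haplotypes: 0=AB, 1=Ab, 2=aB, 3=ab with A/B the alt alleles
    draws = rng.choice(4, size=2 * n, p=h)
    alt1 = np.isin(draws, (0, 1)).astype(np.int8)
    alt2 = np.isin(draws, (0, 2)).astype(np.int8)
    calls = np.column_stack(
        [
            alt1[0::2] + alt1[1::2],
            alt2[0::2] + alt2[1::2],
        ]
    ).astype(np.int8)
    variants = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "pos": [100_000, 200_000],
            "id": ["locusA", "locusB"],
            "ref": ["A", "A"],
            "alt": ["C", "C"],
        }
    )
    samples = pd.DataFrame(
        {"id": [f"ind{i + 1}" for i in range(n)], "population": "twolocus"}
    )
    return GenotypeMatrix(calls, variants, samples)
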
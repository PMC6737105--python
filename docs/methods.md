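# Methods

This note records the statistical models implemented in `popgenpipe`, every
analysis default and why it was chosen, what the synthetic-data generators
do and do not model, and the numerical decisions that affect results.

## Genotype model

Genotypes are alt-allele dosages in {0, 1, 2} with −1 for missing, stored as
`int8` in a samples × variants matrix. Only biallelic SNPs are supported;
the VCF reader skips multiallelic and non-SNP records (logged), and
half-calls become missing. Positions must be strictly increasing within a
chromosome. PLINK text output writes a 6-column MAP (chrom, id, cM, pos,
ref, alt) by default: the two extra columns preserve dosage orientation
when the alt allele happens to be the major one, which a strict 4-column
MAP cannot encode.

## Quality control

Defaults follow common SNP-array practice for breeding populations:

| filter | default | applied to |
|---|---|---|
| sample call rate | ≥ 0.95 | samples, first |
| marker missingness | ≤ 0.70 | markers |
| minor allele frequency | ≥ 0.05 | markers |
| Hardy–Weinberg exact test | p ≥ 10⁻⁶ | markers |

Samples are filtered before markers so a badly genotyped individual cannot
drag markers below the missingness or MAF thresholds. Each removed marker
is attributed to the *first* criterion it fails (missingness → MAF → HWE),
so the report's counts partition the removed set and `apply_qc` is
idempotent. The HWE test is the exact conditional test (the plain, not
mid-p, variant): the distribution of heterozygote counts given the allele
counts is enumerated with exact integer weights 2^h·n!/(n_AA! n_Aa! n_aa!),
so p-values carry no floating-point accumulation error.

## Relatedness

Pairwise IBD follows the PLINK `--genome` method of moments: expected
IBS-class counts under IBD 0/1/2 are computed from allele frequencies with
the finite-sample (falling-factorial) bias corrections, and solved for
P(IBD = 0, 1, 2). Raw estimates are reported alongside versions clipped to
[0, 1] and renormalized; π̂ = Z1/2 + Z2. Pruning to a target sample size is
greedy: repeatedly drop the individual with the largest summed π̂ (ties
broken by sample id) until the target is reached — the same heuristic used
in practice to reduce family structure before Ne estimation.

## Population structure

- **PCA**: dosages centred by 2p̂ and scaled by √(2p̂(1−p̂)); missing values
  mean-imputed (flagged when missingness exceeds 1%, as imputation then
  shrinks coordinates noticeably); SVD; explained fraction = eigenvalue /
  total variance.
- **Heterozygosity**: observed and expected (2p̂(1−p̂), optionally with the
  2n/(2n−1) small-sample factor) over polymorphic loci.
- **F<sub>ST</sub>**: Weir & Cockerham (1984) variance components a, b, c
  for two populations, reported both as the ratio of sums (the estimator
  recommended by the authors, used as the headline value) and as the mean
  of per-locus ratios ± SD (often quoted in surveys; biased but shown for
  comparability).
- **Admixture**: the binomial-likelihood model L = Σ g log(QP) +
  (2−g) log(1−QP) maximized by EM (frappe-style updates). The
  log-likelihood is non-decreasing by construction and checked in tests.
  K = 1 has a closed form. K is selected by masked-genotype
  cross-validation: a random fraction (default 5%) of called genotypes is
  hidden per fold, the model is fit without them, and the squared error of
  the predicted dosage is compared across K.

## Linkage disequilibrium

Two r² estimators over within-chromosome pairs (default window 10 Mb):

- **composite** (default for Ne): squared Pearson correlation of dosages —
  the Burrows composite measure normalized by observed variances. It is
  phase-free, robust to Hardy–Weinberg departures, and tolerates missing
  data through pairwise-complete computation.
- **em_haplotype**: Hill (1974) EM haplotype frequencies for each pair,
  then r² = D²/(pq·pq). On phase-unambiguous samples this reduces exactly
  to haplotype counting (tested against that oracle).

Decay curves bin pairs into half-open 100 kb distance classes up to 10 Mb;
empty bins are NaN, and the overall mean/SD accompany the curve.

## Historical Ne (SNeP-style)

Per chromosome, pairs are binned into 30 × 50 kb distance bins. Each bin's
mean r² is sample-size corrected (r²adj = r² − 1/S by default; 1/(2S)
available) and inverted through Sved's relation

  E[r²adj] = 1 / (α + 4·f(c)·Ne),  t = 1/(2c),

with c from the physical midpoint at 10⁻⁸ Morgans/bp (1 cM/Mb) by default
and f(c) selectable among identity, Haldane and Sved–Feldman mappings.
Bins with fewer than 50 pairs are dropped. Per-chromosome estimates at the
same t are combined by harmonic mean (Ne is a rate-of-drift parameter;
harmonic means dominate in that scale).

**α semantics.** The package default is α = 2, the setting used in
SNeP-style analyses of real data where mutation contributes to observed LD.
The bundled Wright–Fisher simulator deliberately has no mutation, and on
mutation-free data E[r²adj] tracks 1/(β + 4Nc) with β ≈ 1 (measured at
β ≈ 1.0–1.4 over 8 seeds and both mating designs) — Sved's original
mutation-free form. Recovery experiments and the acceptance script
therefore set α = 1; using α = 2 there would bias every bin's Ne low by
≈ (2−β)/(4c). This is a statement about model semantics, not tuning: the
correct α follows from whether the data-generating process includes
mutation.

## Contemporary Ne (bias-corrected LD method)

The Waples (2006) / Waples & Do (2008) estimator. Loci are screened at
Pcrit = 0.05 (MAF), mean composite r² is taken over **between-chromosome
pairs** when at least two chromosomes are present — the method assumes
independently segregating loci, and between-chromosome pairs satisfy that
assumption by construction; within-chromosome pairs are used only for
single-chromosome panels, with a logged warning. The sampling expectation

  E[r²_sample] = 1/S + 3.19/S²   (S ≥ 30)

is subtracted, and the drift component r²′ inverted by

  Ne = (a + √(a² − 4b·r²′)) / (2·r²′)

with (a, 4b) = (1/3, 2.76) for random mating and (2/3, 7.2) for monogamy
(small-S variants included). When r²′ ≤ 0 there is no detectable drift
signal and the estimate is +∞ (reported as such, as NeEstimator does).
The CI is a leave-one-chromosome-out jackknife; it needs ≥ 3 chromosomes
(with 2, removing one leaves no between-chromosome pairs → NaN).

**Sampling design caveat.** The monogamy constants assume the sample's
family composition reflects the population's. Genotyping a random subset
of a monogamous population dilutes sibling pairs and biases the monogamy
inversion upward (measured: implied drift constant 0.643 ≈ 2/3 at full
census vs 0.566 when sampling 50 of 100). Prefer census or family-aware
sampling when using `mating="monogamy"`.

For very large panels the mean r² is computed on a seeded random subset of
4,000 post-screen loci (≈ 8M pairs), which changes the mean only within
Monte-Carlo error.

`regress_contemporary` fits OLS of Ne_t on t over the recent trajectory
(t ≤ 100 by default) and predicts t = 1, the paper-style "current" Ne from
the historical curve.

**Marker arithmetic**: Me = 4NeL effective segments; 10NeL markers and
2NeL training individuals for genomic selection, rounded to the nearest
hundred (halves up). With the published contemporary Ne values 159/128/78
and L = 14.8 Morgans this reproduces Me = 9,400/7,600/4,600 and the
10NeL range 11,500–23,500 exactly.

## Synthetic data generators

- **Wright–Fisher forward simulator**: diploid, discrete generations,
  piecewise-constant census size, founder allele frequencies ~
  Uniform(0.05, 0.5) at independent sites, Poisson(L Morgans) crossovers
  per gamete (default 1 cM/Mb), optional genotype missingness. Mating is
  monogamous by default (individuals pair into couples; offspring sample
  parents from one couple) or random with distinct parents. The truth
  object records the Ne trajectory and final-generation parental couples
  (a pedigree oracle for relatedness tests). *Scope*: no mutation (LD and
  diversity decay from standing variation — hence α = 1 above), no
  selection, no sex chromosomes, no overlapping generations.
- **Balding–Nichols admixture**: subpopulation frequencies ~
  Beta(p(1−F)/F, (1−p)(1−F)/F) around a shared ancestral p; individual
  ancestry Q ~ Dirichlet(α) or an explicit Q matrix (e.g. pure groups);
  genotypes ~ Binomial(2, QᵀP). Truth carries Q, P and F.
- **Two-locus sampler**: exact haplotype frequencies from (pA, pB, D)
  (validated against the feasible D range), random pairing into diploids —
  closed-form r² oracles for the LD estimators.

## Numerical choices

- All stochastic code uses `numpy.random.default_rng` with explicit seeds;
  reruns are bit-for-bit reproducible.
- HWE p-values use exact integer enumeration (no floating-point sums).
- r² values are clipped to [0, 1] after floating-point round-off.
- Monomorphic and all-missing loci are excluded from estimators that are
  undefined there (logged), rather than silently producing NaN.
- Harmonic means are computed in double precision on reciprocals; empty
  inputs raise.

## Limitations

- Two-population F<sub>ST</sub> only (pairwise); no hierarchical variants.
- The admixture EM is unaccelerated; it is intended for the thousands of
  markers typical after LD pruning, not full arrays.
- Contemporary-Ne CIs are chromosome jackknives, not the locus-pair
  jackknives of NeEstimator; with few chromosomes they are wide or
  undefined.
- The simulator's marker density and chromosome count should be scaled to
  the compute budget; defaults target seconds, not realism.
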
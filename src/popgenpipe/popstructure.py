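"""Population structure: PCA, heterozygosity, Fst and ML admixture.

* PCA standardises dosages per locus by the binomial mean 2p and scale
  sqrt(2p(1-p)), mean-imputes missing calls, and eigendecomposes the sample
  covariance; explained fractions are eigenvalues over the trace.
* Heterozygosity reports the mean observed heterozygote fraction (Ho) and
  the mean expected heterozygosity 2p(1-p) (He), with an optional
  small-sample (2n/(2n-1)) correction.
* Differentiation uses the Weir & Cockerham (1984) variance-components
  estimator of theta (Fst) with unequal sample sizes; the headline number
  is the ratio-of-sums across loci, with the per-locus mean +/- SD also
  reported.
* Ancestry proportions come from the maximum-likelihood admixture model
  (binomial likelihood of dosages given Q P) fitted by EM, with model order
  chosen by masked-genotype cross-validation.  Results are labelled
  "admixture (ML)": this is a likelihood analogue of Bayesian MCMC
  clustering, not a posterior sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "PCAResult",
    "HetResult",
    "FstResult",
    "AdmixtureFit",
    "pca",
    "heterozygosity",
    "weir_cockerham_fst",
    "admixture_em",
    "select_k",
    "align_q_to_truth",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    coordinates: np.ndarray  # n_samples x k
    explained_fraction: np.ndarray  # length k
    high_missingness: bool = False


def _standardized_dosages(matrix: GenotypeMatrix) -> np.ndarray:
    calls = matrix.calls.astype(float)
    calls[matrix.calls == MISSING] = np.nan
    p = matrix.allele_frequencies()
    poly = (p > 0) & (p < 1)
    calls = calls[:, poly]
    p = p[poly]
    z = (calls - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return np.nan_to_num(z, nan=0.0)  # mean imputation after standardisation


def pca(matrix: GenotypeMatrix, k: int) -> PCAResult:
    """Principal components of standardised genotypes.

    Monomorphic loci are dropped; missing calls are mean-imputed (i.e. zero
    after standardisation) for the projection only.
    """
    n, m = matrix.n_samples, matrix.n_variants
    if k >= min(n, m):
        raise ValueError(f"k={k} must be < min(n_samples, n_variants)={min(n, m)}")
    z = _standardized_dosages(matrix)
    zc = z - z.mean(axis=0, keepdims=True)
    # eigendecomposition of the sample covariance via SVD of the data
    u, s, _ = linalg.svd(zc, full_matrices=False)
    eigvals = s**2 / (n - 1)
    trace = (zc**2).sum() / (n - 1)
    coords = u[:, :k] * s[:k]
    return PCAResult(
        coordinates=coords,
        explained_fraction=eigvals[:k] / trace,
        high_missingness=bool((matrix.calls == MISSING).mean() > 0.01),
    )


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------

@dataclass
class HetResult:
    Ho: float
    He: float


def heterozygosity(matrix: GenotypeMatrix, unbiased: bool = False) -> HetResult:
    """Observed and expected heterozygosity averaged over polymorphic loci.

    ``unbiased`` applies the 2n/(2n-1) small-sample correction to He.
    """
    called = matrix.calls != MISSING
    n_called = called.sum(axis=0)
    p = matrix.allele_frequencies()
    poly = (p > 0) & (p < 1) & (n_called > 0)
    if not poly.any():
        raise ValueError("no polymorphic loci")
    het = ((matrix.calls == 1) & called).sum(axis=0)
    ho = het[poly] / n_called[poly]
    he = 2.0 * p[poly] * (1.0 - p[poly])
    if unbiased:
        he = he * (2.0 * n_called[poly]) / (2.0 * n_called[poly] - 1.0)
    return HetResult(Ho=float(ho.mean()), He=float(he.mean()))


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    per_locus_a: np.ndarray
    per_locus_b: np.ndarray
    per_locus_c: np.ndarray
    per_locus_theta: np.ndarray  # nan where the denominator is undefined
    mean_theta: float  # ratio of sums
    mean_of_ratios: float
    sd_theta: float


def weir_cockerham_fst(pop1: GenotypeMatrix, pop2: GenotypeMatrix) -> FstResult:
    """Pairwise Weir–Cockerham theta for two populations on a shared map.

    Implements the two-level (among populations / among individuals within /
    within individuals) variance components a, b, c per locus with unequal
    sample sizes; ``mean_theta`` is sum(a)/sum(a+b+c) over loci with a
    defined denominator.
    """
    if pop1.n_variants != pop2.n_variants:
        raise ValueError("populations must share a variant map")
    mats = (pop1, pop2)
    for m in mats:
        if m.n_samples < 2:
            raise ValueError("each population needs >= 2 samples")
        if not (m.calls != MISSING).any():
            raise ValueError("a population is entirely missing")
    r = 2.0

    ni = np.stack([(m.calls != MISSING).sum(axis=0).astype(float) for m in mats])
    pi = np.stack(
        [
            np.where(
                (m.calls != MISSING).sum(axis=0) > 0,
                np.where(m.calls != MISSING, m.calls, 0).sum(axis=0)
                / np.maximum(2.0 * (m.calls != MISSING).sum(axis=0), 1.0),
                np.nan,
            )
            for m in mats
        ]
    )
    hi = np.stack(
        [
            ((m.calls == 1).sum(axis=0))
            / np.maximum((m.calls != MISSING).sum(axis=0), 1.0)
            for m in mats
        ]
    )

    nbar = ni.sum(axis=0) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (ni**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (ni * pi).sum(axis=0) / (r * nbar)
        s2 = (ni * (pi - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (ni * hi).sum(axis=0) / (r * nbar)

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)

    usable = np.isfinite(denom) & (denom != 0)
    if not usable.any():
        raise ValueError("no locus has a defined Fst denominator")
    mean_theta = float(a[usable].sum() / denom[usable].sum())
    finite = np.isfinite(theta)
    return FstResult(
        per_locus_a=a,
        per_locus_b=b,
        per_locus_c=c,
        per_locus_theta=theta,
        mean_theta=mean_theta,
        mean_of_ratios=float(np.nanmean(theta[finite])),
        sd_theta=float(np.nanstd(theta[finite], ddof=1)),
    )


# ---------------------------------------------------------------------------
# Admixture (maximum likelihood, EM)
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureFit:
    Q: np.ndarray  # n x K, rows on the simplex
    P: np.ndarray  # K x m ancestral alt-allele frequencies
    loglik_trace: list = field(default_factory=list)
    cv_error: float | None = None


_P_EPS = 1e-6


def _admixture_loglik(g, mask, Q, P) -> float:
    f = np.clip(Q @ P, _P_EPS, 1 - _P_EPS)
    ll = np.where(mask, g * np.log(f) + (2.0 - g) * np.log(1.0 - f), 0.0)
    return float(ll.sum())


def admixture_em(
    matrix: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> AdmixtureFit:
    """EM fit of the ML admixture model (binomial dosage likelihood).

    The log-likelihood is non-decreasing across iterations; the fit stops
    when its increase drops below ``tol`` or at ``max_iter``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > matrix.n_samples:
        raise ValueError("K cannot exceed the number of samples")
    g = matrix.calls.astype(float)
    mask = matrix.calls != MISSING
    g[~mask] = 0.0
    n, m = g.shape

    rng = np.random.default_rng(seed)
    if K == 1:
        p_hat = matrix.allele_frequencies()[None, :]
        Q = np.ones((n, 1))
        P = np.clip(np.nan_to_num(p_hat, nan=0.5), _P_EPS, 1 - _P_EPS)
        return AdmixtureFit(Q=Q, P=P, loglik_trace=[_admixture_loglik(g, mask, Q, P)])

    Q = rng.dirichlet(np.ones(K), size=n)
    P = np.clip(
        matrix.allele_frequencies()[None, :] + rng.normal(0, 0.05, size=(K, m)),
        0.05,
        0.95,
    )
    trace = []
    prev = -np.inf
    two_minus_g = np.where(mask, 2.0 - g, 0.0)
    for _ in range(max_iter):
        f = np.clip(Q @ P, _P_EPS, 1 - _P_EPS)
        r_alt = g / f  # n x m
        r_ref = two_minus_g / (1.0 - f)
        # E-step responsibilities folded directly into the M-step sums
        A = np.empty((n, K))  # expected alt-allele contributions per sample
        B = np.empty((n, K))
        Pa = np.empty((K, m))
        Pb = np.empty((K, m))
        for k in range(K):
            wk_alt = Q[:, k : k + 1] * P[k][None, :] * r_alt
            wk_ref = Q[:, k : k + 1] * (1.0 - P[k])[None, :] * r_ref
            A[:, k] = wk_alt.sum(axis=1)
            B[:, k] = wk_ref.sum(axis=1)
            Pa[k] = wk_alt.sum(axis=0)
            Pb[k] = wk_ref.sum(axis=0)
        denom_q = 2.0 * mask.sum(axis=1, keepdims=True)
        Q = (A + B) / np.maximum(denom_q, 1.0)
        Q = Q / Q.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(Pa + Pb > 0, Pa / np.maximum(Pa + Pb, 1e-300), P)
        P = np.clip(P, _P_EPS, 1 - _P_EPS)
        ll = _admixture_loglik(g, mask, Q, P)
        trace.append(ll)
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
    return AdmixtureFit(Q=Q, P=P, loglik_trace=trace)


def align_q_to_truth(Q: np.ndarray, Q_true: np.ndarray) -> np.ndarray:
    """Permute columns of Q to best match a reference (label switching)."""
    from itertools import permutations

    K = Q.shape[1]
    best, best_err = Q, np.inf
    for perm in permutations(range(K)):
        err = np.abs(Q[:, perm] - Q_true).mean()
        if err < best_err:
            best, best_err = Q[:, perm], err
    return best


def select_k(
    matrix: GenotypeMatrix,
    k_range,
    folds: int = 5,
    seed: int = 0,
    mask_fraction: float = 0.05,
    **em_kwargs,
) -> dict[int, float]:
    """Masked-genotype cross-validation error for each candidate K.

    For every fold a random ``mask_fraction`` of the non-missing calls is
    hidden, the model is fitted on the rest, and the mean squared dosage
    error on the hidden calls is recorded; returns the per-K mean over
    folds.  Lower is better.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    if folds < 2:
        raise ValueError("need at least two folds")
    if not 0 < mask_fraction < 1:
        raise ValueError("mask_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    observed = np.argwhere(matrix.calls != MISSING)
    errors = {k: [] for k in k_range}
    for fold in range(folds):
        pick = rng.random(len(observed)) < mask_fraction
        if not pick.any():
            pick[rng.integers(0, len(observed))] = True
        held = observed[pick]
        masked = matrix.copy()
        masked.calls[held[:, 0], held[:, 1]] = MISSING
        truth = matrix.calls[held[:, 0], held[:, 1]].astype(float)
        for k in k_range:
            fit = admixture_em(masked, k, seed=seed * 1009 + fold, **em_kwargs)
            pred = 2.0 * (fit.Q @ fit.P)[held[:, 0], held[:, 1]]
            errors[k].append(float(np.mean((pred - truth) ** 2)))
    return {k: float(np.mean(v)) for k, v in errors.items()}
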
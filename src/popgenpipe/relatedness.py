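"""Pairwise identity-by-descent estimation and relatedness pruning.

The estimator is the classical genome-wide method of moments used for
sample QC in GWAS tooling: per pair, observed counts of loci at each
identity-by-state (IBS) class are combined with the expected IBS-class
probabilities given IBD state.  Expectations use in-sample allele
frequencies with the standard unbiased product corrections (falling
factorials of allele counts), so the estimator is well behaved at modest
sample sizes.  Raw IBD probabilities can fall outside [0, 1]; they are
retained, then clipped and renormalised for reporting, and
``pi_hat = Z1/2 + Z2``.

Pruning to a target sample size is greedy: repeatedly drop the sample with
the largest summed pi_hat to the remaining samples (ties broken by sample
id).  This is a heuristic, not an optimal subset search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = ["IBDEstimate", "ibd_estimates", "ibd_table", "prune_related"]


@dataclass
class IBDEstimate:
    sample_i: str
    sample_j: str
    Z0: float
    Z1: float
    Z2: float
    pi_hat: float
    raw_Z0: float
    raw_Z1: float
    raw_Z2: float


def _expected_class_terms(matrix: GenotypeMatrix) -> tuple[np.ndarray, ...]:
    """Per-locus P(IBS class | IBD state) with small-sample corrections.

    Returns arrays (e00, e10, e11, e20, e21): e<ibs><ibd>.  Loci that are
    monomorphic or have < 4 called alleles contribute zero (they carry no
    information for the moments estimator and their corrections degenerate).
    """
    called = matrix.calls != MISSING
    x = np.where(called, matrix.calls, 0).sum(axis=0).astype(float)  # alt count
    t = 2.0 * called.sum(axis=0)  # total alleles
    y = t - x
    ok = (t >= 4) & (x >= 1) & (y >= 1)

    def ff(a, k):  # falling factorial a(a-1)...(a-k+1)
        out = np.ones_like(a)
        for i in range(k):
            out = out * (a - i)
        return out

    t4 = ff(t, 4)
    t3 = ff(t, 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        p2q2 = ff(x, 2) * ff(y, 2) / t4
        p3q = ff(x, 3) * y / t4
        pq3 = x * ff(y, 3) / t4
        p4 = ff(x, 4) / t4
        q4 = ff(y, 4) / t4
        p2q = ff(x, 2) * y / t3
        pq2 = x * ff(y, 2) / t3
        p3 = ff(x, 3) / t3
        q3 = ff(y, 3) / t3

    e00 = np.where(ok, 2.0 * p2q2, 0.0)
    e10 = np.where(ok, 4.0 * p3q + 4.0 * pq3, 0.0)
    e20 = np.where(ok, p4 + q4 + 4.0 * p2q2, 0.0)
    e11 = np.where(ok, 2.0 * p2q + 2.0 * pq2, 0.0)
    e21 = np.where(ok, p3 + q3 + p2q + pq2, 0.0)
    return e00, e10, e11, e20, e21, ok


def ibd_table(matrix: GenotypeMatrix) -> pd.DataFrame:
    """All-pairs IBD estimates as a tidy DataFrame.

    Columns mirror a PLINK ``.genome`` table: IID1, IID2, Z0, Z1, Z2,
    PI_HAT, plus the unconstrained raw probabilities.
    """
    ests = ibd_estimates(matrix)
    return pd.DataFrame(
        {
            "IID1": [e.sample_i for e in ests],
            "IID2": [e.sample_j for e in ests],
            "Z0": [e.Z0 for e in ests],
            "Z1": [e.Z1 for e in ests],
            "Z2": [e.Z2 for e in ests],
            "PI_HAT": [e.pi_hat for e in ests],
            "RAW_Z0": [e.raw_Z0 for e in ests],
            "RAW_Z1": [e.raw_Z1 for e in ests],
            "RAW_Z2": [e.raw_Z2 for e in ests],
        }
    )


def ibd_estimates(matrix: GenotypeMatrix) -> list[IBDEstimate]:
    """Method-of-moments IBD sharing (Z0, Z1, Z2, pi_hat) for every pair."""
    n = matrix.n_samples
    if n < 2:
        raise ValueError("need at least two samples")
    maf = matrix.minor_allele_frequencies()
    if not np.any(maf > 0):
        raise ValueError("panel is entirely monomorphic; IBD is undefined")

    e00, e10, e11, e20, e21, ok = _expected_class_terms(matrix)
    calls = matrix.calls
    informative = ok
    usable = (calls != MISSING) & informative[None, :]

    _, z0m, z1m, z2m, pim, raw = _pairwise_ibd_arrays(
        calls, usable, e00, e10, e11, e20, e21
    )
    ids = matrix.samples["id"].astype(str).to_numpy()
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            out.append(
                IBDEstimate(
                    ids[i], ids[j],
                    float(z0m[i, j]), float(z1m[i, j]), float(z2m[i, j]),
                    float(pim[i, j]),
                    float(raw[0][i, j]), float(raw[1][i, j]), float(raw[2][i, j]),
                )
            )
    return out


def pi_hat_matrix(matrix: GenotypeMatrix) -> np.ndarray:
    """Symmetric n x n pi_hat matrix (diagonal zero)."""
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    maf = matrix.minor_allele_frequencies()
    if not np.any(maf > 0):
        raise ValueError("panel is entirely monomorphic; IBD is undefined")
    e00, e10, e11, e20, e21, ok = _expected_class_terms(matrix)
    usable = (matrix.calls != MISSING) & ok[None, :]
    pim = _pairwise_ibd_arrays(matrix.calls, usable, e00, e10, e11, e20, e21)[4]
    return pim


def _pairwise_ibd_arrays(calls, usable, e00, e10, e11, e20, e21):
    """Dense all-pairs IBD computation; returns (N_pairs, Z0, Z1, Z2, pi)."""
    n = calls.shape[0]
    u = usable.astype(np.float64)
    # per-pair sums of expectations over pair-complete loci
    s00 = (u * e00) @ u.T
    s10 = (u * e10) @ u.T
    s11 = (u * e11) @ u.T
    s20 = (u * e20) @ u.T
    s21 = (u * e21) @ u.T
    s22 = u @ u.T  # count of pair-complete informative loci

    # IBS class counts per pair via indicator matrix products
    i0 = (usable & (calls == 0)).astype(np.float64)
    i1 = (usable & (calls == 1)).astype(np.float64)
    i2 = (usable & (calls == 2)).astype(np.float64)
    n0 = i0 @ i2.T + i2 @ i0.T
    n1 = i0 @ i1.T + i1 @ i0.T + i1 @ i2.T + i2 @ i1.T
    n2 = i0 @ i0.T + i1 @ i1.T + i2 @ i2.T

    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = np.where(s00 > 0, n0 / s00, 0.0)
        p1 = np.where(s11 > 0, (n1 - p0 * s10) / s11, 0.0)
        denom2 = s22
        p2 = np.where(denom2 > 0, (n2 - p0 * s20 - p1 * s21) / denom2, 0.0)
    # raw values retained; constrained version clipped then renormalised
    raw = (p0.copy(), p1.copy(), p2.copy())
    z0 = np.clip(p0, 0.0, 1.0)
    z1 = np.clip(p1, 0.0, 1.0)
    z2 = np.clip(p2, 0.0, 1.0)
    tot = z0 + z1 + z2
    tot = np.where(tot > 0, tot, 1.0)
    z0, z1, z2 = z0 / tot, z1 / tot, z2 / tot
    pi = z1 / 2.0 + z2
    np.fill_diagonal(pi, 0.0)
    return s22, z0, z1, z2, pi, raw


def prune_related(matrix: GenotypeMatrix, target_n: int) -> GenotypeMatrix:
    """Greedily drop the most-related samples until ``target_n`` remain.

    At each step the sample with the largest summed pi_hat to the remaining
    samples is removed; ties break on sample id (lexicographic, keeping the
    smaller id).
    """
    if target_n <= 0:
        raise ValueError("target_n must be positive")
    if target_n > matrix.n_samples:
        raise ValueError("target_n exceeds the number of samples")
    if target_n == matrix.n_samples:
        return matrix
    pim = pi_hat_matrix(matrix)
    ids = matrix.samples["id"].astype(str).to_numpy()
    active = np.ones(matrix.n_samples, dtype=bool)
    while active.sum() > target_n:
        sums = np.where(active, (pim * active[None, :]).sum(axis=1), -np.inf)
        best = np.max(sums)
        cand = np.flatnonzero(active & (sums >= best - 1e-12))
        drop = cand[np.argsort(ids[cand], kind="stable")[-1]]
        active[drop] = False
    return matrix.subset_samples(active)
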
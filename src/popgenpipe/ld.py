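"""Within-chromosome pairwise linkage disequilibrium and decay curves.

Two r-squared estimators are available:

``composite``
    Squared Pearson correlation of dosage vectors (the Burrows composite
    basis).  Phase-free, fast, and the default input to effective-size
    estimation.
``em_haplotype``
    Two-locus haplotype frequencies estimated from unphased genotypes by EM
    (the classical Hill likelihood, resolving double heterozygotes), with
    r2 = D^2 / (p1 q1 p2 q2).  Default for decay curves.

Pairs are restricted to a physical window (default 10 Mb) within one
chromosome; no r-squared threshold is applied when collecting pairs.  Decay
curves are arithmetic means of r2 in half-open distance bins (default
100 kb, spanning 0-10 Mb).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = ["LDPairSet", "LDDecayCurve", "pairwise_r2", "bin_ld_decay", "high_ld_pairs"]

logger = logging.getLogger(__name__)


@dataclass
class LDPairSet:
    """Tidy per-pair r2 records (one chromosome per row set)."""

    table: pd.DataFrame  # columns: chrom, i, j, pos_i, pos_j, distance_bp, r2
    estimator: str = "composite"

    def __len__(self) -> int:
        return len(self.table)

    @staticmethod
    def concat(parts: list["LDPairSet"]) -> "LDPairSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        est = {p.estimator for p in parts}
        if len(est) != 1:
            raise ValueError("cannot mix estimators")
        return LDPairSet(
            pd.concat([p.table for p in parts], ignore_index=True), est.pop()
        )


@dataclass
class LDDecayCurve:
    bin_lo: np.ndarray
    bin_hi: np.ndarray
    mean_r2: np.ndarray  # nan for empty bins
    n_pairs: np.ndarray
    overall_mean: float = np.nan
    overall_sd: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_lo,
                "bin_hi": self.bin_hi,
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs,
            }
        )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _composite_r2(calls: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns.

    Missing calls are handled pairwise-complete.  Returns an m x m matrix
    with nan where a locus is monomorphic over the pair-complete samples.
    """
    mask = (calls != MISSING).astype(float)
    g = np.where(calls != MISSING, calls, 0).astype(float)
    n = mask.T @ mask
    sx = g.T @ mask
    sy = sx.T
    sxx = (g * g).T @ mask
    syy = sxx.T
    sxy = g.T @ g
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r2 = cov**2 / (vx * vy)
    r2[~np.isfinite(r2)] = np.nan
    return r2


def _em_haplotype_freqs(n_tab: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """Vectorised EM for two-locus haplotype frequency pAB.

    ``n_tab`` has shape (npairs, 3, 3): genotype counts with dosage at locus
    1 indexing rows and locus 2 columns.  Returns (pAB, pA, pB, n_hap).
    """
    n = n_tab.sum(axis=(1, 2)).astype(float)
    n_hap = 2.0 * n
    dose1 = n_tab.sum(axis=2) @ np.array([0.0, 1.0, 2.0])
    dose2 = n_tab.sum(axis=1) @ np.array([0.0, 1.0, 2.0])
    pA = dose1 / n_hap
    pB = dose2 / n_hap
    # haplotype counts fixed by genotypes, except the double heterozygotes
    ndh = n_tab[:, 1, 1].astype(float)
    fixed_AB = (
        2.0 * n_tab[:, 2, 2] + n_tab[:, 2, 1] + n_tab[:, 1, 2]
    ).astype(float)
    fixed_Ab = (
        2.0 * n_tab[:, 2, 0] + n_tab[:, 2, 1] + n_tab[:, 1, 0]
    ).astype(float)
    fixed_aB = (
        2.0 * n_tab[:, 0, 2] + n_tab[:, 0, 1] + n_tab[:, 1, 2]
    ).astype(float)
    fixed_ab = (
        2.0 * n_tab[:, 0, 0] + n_tab[:, 0, 1] + n_tab[:, 1, 0]
    ).astype(float)

    pAB = pA * pB
    for _ in range(max_iter):
        pAb = np.clip(pA - pAB, 1e-12, None)
        paB = np.clip(pB - pAB, 1e-12, None)
        pab = np.clip(1.0 - pA - pB + pAB, 1e-12, None)
        num = np.clip(pAB, 1e-12, None) * pab
        w = num / (num + pAb * paB)
        new = (fixed_AB + w * ndh) / n_hap
        if np.all(np.abs(new - pAB) < tol):
            pAB = new
            break
        pAB = new
    return pAB, pA, pB, n_hap


def _em_r2(calls: np.ndarray, idx_i: np.ndarray, idx_j: np.ndarray) -> np.ndarray:
    """EM-haplotype r2 for the requested locus pairs (complete-case)."""
    out = np.empty(len(idx_i))
    gi = calls[:, idx_i]
    gj = calls[:, idx_j]
    ok = (gi != MISSING) & (gj != MISSING)
    n_tab = np.zeros((len(idx_i), 3, 3), dtype=np.int64)
    for a in range(3):
        for b in range(3):
            n_tab[:, a, b] = ((gi == a) & (gj == b) & ok).sum(axis=0)
    pAB, pA, pB, _ = _em_haplotype_freqs(n_tab)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = pAB - pA * pB
        denom = pA * (1 - pA) * pB * (1 - pB)
        out = np.where(denom > 0, d**2 / denom, np.nan)
    return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def pairwise_r2(
    matrix: GenotypeMatrix,
    chromosome=None,
    window_bp: int = 10_000_000,
    estimator: str = "composite",
    chunk_size: int = 2048,
) -> LDPairSet:
    """All within-chromosome marker pairs closer than ``window_bp``.

    ``chromosome=None`` processes every chromosome.  Pairs involving a
    monomorphic locus are skipped (count logged).  The result is
    independent of ``chunk_size``.
    """
    if estimator not in ("composite", "em_haplotype"):
        raise ValueError(f"unknown estimator {estimator!r}")
    chroms = (
        matrix.chromosomes if chromosome is None else [str(chromosome)]
    )
    parts = []
    skipped = 0
    for chrom in chroms:
        idx = matrix.variant_indices(chrom)
        if idx.size == 0:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if idx.size < 2:
            continue
        pos = matrix.variants["pos"].to_numpy()[idx].astype(np.int64)
        calls = matrix.calls[:, idx]
        p = matrix.allele_frequencies()[idx]
        poly = (p > 0) & (p < 1)

        if estimator == "composite":
            r2_mat = _composite_r2(calls)

        ii_all, jj_all = np.triu_indices(idx.size, k=1)
        dist_all = pos[jj_all] - pos[ii_all]
        keep = dist_all <= window_bp
        both_poly = poly[ii_all] & poly[jj_all]
        skipped += int((keep & ~both_poly).sum())
        keep &= both_poly
        ii_all, jj_all, dist_all = ii_all[keep], jj_all[keep], dist_all[keep]

        rows = []
        for start in range(0, ii_all.size, chunk_size * chunk_size):
            stop = min(start + chunk_size * chunk_size, ii_all.size)
            ii = ii_all[start:stop]
            jj = jj_all[start:stop]
            dist = dist_all[start:stop]
            if ii.size == 0:
                continue
            if estimator == "composite":
                r2 = r2_mat[ii, jj]
            else:
                r2 = _em_r2(calls, ii, jj)
            good = np.isfinite(r2)
            skipped += int((~good).sum())
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "i": idx[ii[good]],
                        "j": idx[jj[good]],
                        "pos_i": pos[ii[good]],
                        "pos_j": pos[jj[good]],
                        "distance_bp": dist[good],
                        "r2": np.clip(r2[good], 0.0, 1.0),
                    }
                )
            )
        if rows:
            parts.append(pd.concat(rows, ignore_index=True))
    if skipped:
        logger.info("pairwise_r2 skipped %d pairs with a monomorphic locus", skipped)
    if not parts:
        table = pd.DataFrame(
            columns=["chrom", "i", "j", "pos_i", "pos_j", "distance_bp", "r2"]
        )
    else:
        table = pd.concat(parts, ignore_index=True)
    return LDPairSet(table=table, estimator=estimator)


def bin_ld_decay(
    pairs: LDPairSet,
    bin_width: int = 100_000,
    max_dist: int = 10_000_000,
) -> LDDecayCurve:
    """Mean r2 per half-open distance bin [lo, hi), plus overall mean +/- SD."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(pairs) == 0:
        raise ValueError("empty pair set")
    edges = np.arange(0, max_dist + bin_width, bin_width)
    d = pairs.table["distance_bp"].to_numpy()
    r2 = pairs.table["r2"].to_numpy()
    inside = d < max_dist
    which = np.digitize(d[inside], edges) - 1
    nbins = len(edges) - 1
    sums = np.bincount(which, weights=r2[inside], minlength=nbins)
    counts = np.bincount(which, minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    return LDDecayCurve(
        bin_lo=edges[:-1],
        bin_hi=edges[1:],
        mean_r2=means,
        n_pairs=counts,
        overall_mean=float(r2.mean()),
        overall_sd=float(r2.std(ddof=1)) if len(r2) > 1 else np.nan,
    )


def high_ld_pairs(pairs: LDPairSet, threshold: float = 0.80) -> LDPairSet:
    """Pairs with r2 strictly above ``threshold``, sorted by chrom, position."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    sub = pairs.table[pairs.table["r2"] > threshold]
    sub = sub.sort_values(["chrom", "pos_i", "pos_j"], kind="stable")
    return LDPairSet(sub.reset_index(drop=True), pairs.estimator)
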
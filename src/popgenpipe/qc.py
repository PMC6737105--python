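"""Marker and sample quality control.

Filters follow common SNP-array practice for breeding populations: minor
allele frequency (default >= 0.05), Hardy–Weinberg exact test (default
p >= 1e-6), per-marker missingness (default <= 0.70) and per-sample call
rate (default >= 0.95).  Filters are applied in a documented, configurable
order — samples first, then marker missingness, MAF and HWE — and every
removed marker is attributed to the first criterion it fails, so the
removal counts partition the removed set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "allele_frequency",
    "hwe_exact_test",
    "apply_qc",
    "maf_spectrum",
    "DEFAULT_MAF_BINS",
]

#: MAF classes used for reporting the folded frequency spectrum.
DEFAULT_MAF_BINS = [(0.05, 0.10), (0.10, 0.20), (0.20, 0.30), (0.30, 0.40), (0.40, 0.50)]


@dataclass
class QCThresholds:
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    marker_missing_max: float = 0.70
    sample_callrate_min: float = 0.95

    def validate(self) -> None:
        for name in ("maf_min", "hwe_p_min", "marker_missing_max", "sample_callrate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    removed_by_callrate: int = 0  # markers failing missingness
    removed_by_maf: int = 0
    removed_by_hwe: int = 0
    removed_other: int = 0
    samples_removed: int = 0
    final_marker_count: int = 0
    filter_order: tuple = ("missingness", "maf", "hwe")

    def to_dict(self) -> dict:
        return {
            "samples_removed": self.samples_removed,
            "removed_by_callrate": self.removed_by_callrate,
            "removed_by_maf": self.removed_by_maf,
            "removed_by_hwe": self.removed_by_hwe,
            "removed_other": self.removed_other,
            "final_marker_count": self.final_marker_count,
        }


def allele_frequency(calls) -> tuple[float, float, int]:
    """Alt-allele frequency, MAF and call count for one variant.

    ``calls`` is a 1-D dosage vector; raises on an all-missing variant.
    """
    calls = np.asarray(calls)
    called = calls != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError("all calls missing at this variant")
    p_alt = float(calls[called].sum()) / (2.0 * n_called)
    return p_alt, min(p_alt, 1.0 - p_alt), n_called


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Sums, over all heterozygote counts feasible given the observed allele
    counts, the hypergeometric probabilities no larger than that of the
    observed table (plain, not mid-p).  Probabilities are computed in exact
    rational arithmetic so the p-value is reproducible to machine precision.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_Aa  # minor-side allele count (either side works)
    rare = min(n_a, 2 * n - n_a)
    # P(het = h | allele counts) proportional to
    #   2**h * n! / (n_AA! n_Aa! n_aa!); enumerate exactly with integers.
    hets = range(rare % 2, rare + 1, 2)
    weights = {}
    for h in hets:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        w = (
            2**h
            * math.factorial(n)
            // (
                math.factorial(hom_rare)
                * math.factorial(h)
                * math.factorial(hom_common)
            )
        )
        weights[h] = w
    total = sum(weights.values())
    obs = weights[n_Aa]
    p_num = sum(w for w in weights.values() if w <= obs)
    return p_num / total


def _hwe_pvalues(matrix: GenotypeMatrix, variant_index) -> np.ndarray:
    out = np.empty(len(variant_index))
    for k, j in enumerate(variant_index):
        col = matrix.calls[:, j]
        col = col[col != MISSING]
        if col.size == 0:  # fully-missing marker: HWE undefined, keep
            out[k] = 1.0
            continue
        out[k] = hwe_exact_test(
            int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2))
        )
    return out


def apply_qc(
    matrix: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter a genotype matrix, attributing each removal to one criterion.

    Order: sample call rate, then marker missingness, then MAF, then the
    Hardy–Weinberg exact test.  Monomorphic markers fail the MAF criterion
    whenever ``maf_min > 0``.
    """
    if matrix.n_variants == 0 or matrix.n_samples == 0:
        raise ValueError("empty genotype matrix")
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    report = QCReport()

    keep_samples = matrix.call_rate_per_sample() >= thresholds.sample_callrate_min
    report.samples_removed = int((~keep_samples).sum())
    if report.samples_removed:
        matrix = matrix.subset_samples(keep_samples)
    if matrix.n_samples == 0:
        raise ValueError("all samples removed by call-rate filter")

    removed = np.zeros(matrix.n_variants, dtype=bool)

    miss = matrix.missing_rate_per_variant()
    fail_miss = miss > thresholds.marker_missing_max
    report.removed_by_callrate = int(fail_miss.sum())
    removed |= fail_miss

    with np.errstate(invalid="ignore"):
        maf = matrix.minor_allele_frequencies()
    fail_maf = ~removed & (maf < thresholds.maf_min)
    report.removed_by_maf = int(fail_maf.sum())
    removed |= fail_maf

    candidates = np.flatnonzero(~removed)
    if thresholds.hwe_p_min > 0 and candidates.size:
        pvals = _hwe_pvalues(matrix, candidates)
        fail_hwe = candidates[pvals < thresholds.hwe_p_min]
        report.removed_by_hwe = int(fail_hwe.size)
        removed[fail_hwe] = True

    out = matrix.subset_variants(~removed)
    report.final_marker_count = out.n_variants
    return out, report


def maf_spectrum(matrix: GenotypeMatrix, bin_edges=None) -> list[tuple]:
    """Proportion of SNPs per minor-allele-frequency class.

    ``bin_edges`` is a list of half-open ``(lo, hi)`` intervals (the last
    bin includes its upper edge so MAF = 0.5 is counted).  Returns
    ``[(lo, hi, proportion), ...]``; proportions over markers falling in any
    bin sum to 1.
    """
    bins = bin_edges if bin_edges is not None else DEFAULT_MAF_BINS
    for (lo1, hi1), (lo2, hi2) in zip(bins, bins[1:]):
        if hi1 > lo2:
            raise ValueError("MAF bins overlap")
    maf = matrix.minor_allele_frequencies()
    maf = maf[~np.isnan(maf)]
    counts = []
    for i, (lo, hi) in enumerate(bins):
        last = i == len(bins) - 1
        inb = (maf >= lo) & ((maf <= hi) if last else (maf < hi))
        counts.append(int(inb.sum()))
    total = sum(counts)
    if total == 0:
        raise ValueError("no markers fall in the requested MAF bins")
    return [(lo, hi, c / total) for (lo, hi), c in zip(bins, counts)]
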
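"""Effective population size from linkage disequilibrium.

Historical Ne comes from inverting the Sved relation

    E[r2_adj | c] = 1 / (alpha + 4 Ne f(c))

per distance bin: pairwise r2 is averaged in bins of physical distance
(default 30 bins of 50 kb), corrected for sample size (r2 - 1/S by
default), distances are converted to Morgans (default 1 cM/Mb) and to a
recombination fraction c by a selectable mapping (identity by default,
Haldane or Sved-Feldman optional), and the bin at recombination fraction c
probes Ne at t = 1/(2c) generations ago.  alpha defaults to 2, the value
that accounts for mutation.

Contemporary Ne uses the bias-corrected LD (Burrows composite) method of
Waples (2006) / Waples & Do (2008): the mean composite r2 over pairs of
unlinked loci (between-chromosome pairs when several chromosomes are
present) minus the expected sampling contribution, inverted to Ne with the
published second-order constants; a monogamous ("non-random mating")
variant is the default.  Confidence intervals are chromosome-level
jackknives.

Derived quantities: the effective number of chromosome segments
Me = 4 Ne L (L = genome length in Morgans) and the marker / individual
requirements for genomic prediction with unrelated animals, 10 Ne L markers
and 2 Ne L individuals, reported raw and rounded to the nearest hundred.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .ld import LDPairSet

__all__ = [
    "NeSettings",
    "NeTrajectory",
    "NeSummary",
    "MAPPINGS",
    "adjust_r2",
    "sved_ne",
    "historical_ne",
    "contemporary_ne_ld",
    "regress_contemporary",
    "harmonic_mean_ne",
    "effective_segments",
    "marker_requirements",
    "round_hundred",
]

logger = logging.getLogger(__name__)

#: distance (Morgans) -> recombination fraction mappings
MAPPINGS = {
    "identity": lambda d: d,
    "haldane": lambda d: 0.5 * (1.0 - np.exp(-2.0 * d)),
    "sved_feldman": lambda d: d / (1.0 + 2.0 * d),
}


@dataclass
class NeSettings:
    n_bins: int = 30
    bin_size: int = 50_000
    alpha: float = 2.0
    mapping: str = "identity"
    morgans_per_bp: float = 1e-8  # 1 cM/Mb
    min_pairs_per_bin: int = 50
    correction: str = "1/S"  # or "1/(2S)"

    def map_fn(self):
        try:
            return MAPPINGS[self.mapping]
        except KeyError:
            raise ValueError(f"unknown mapping {self.mapping!r}") from None


@dataclass
class NeTrajectory:
    """(generations ago, Ne) points, most recent first."""

    points: pd.DataFrame  # columns: t, ne, c, mean_r2_adj, n_pairs
    settings: NeSettings = field(default_factory=NeSettings)
    sample_size: int = 0
    per_chromosome: dict = field(default_factory=dict)  # chrom -> harmonic Ne

    @property
    def t(self) -> np.ndarray:
        return self.points["t"].to_numpy()

    @property
    def ne(self) -> np.ndarray:
        return self.points["ne"].to_numpy()


@dataclass
class NeSummary:
    contemporary_ld: float = np.nan
    contemporary_ld_ci: tuple = (np.nan, np.nan)
    contemporary_regression: float = np.nan
    harmonic_per_chromosome: dict = field(default_factory=dict)
    harmonic_overall: float = np.nan
    Me: float = np.nan
    Me_rounded: int = 0
    markers_10NeL: float = np.nan
    markers_10NeL_rounded: int = 0
    individuals_2NeL: float = np.nan
    individuals_2NeL_rounded: int = 0
    L_morgans: float = np.nan


def round_hundred(x: float) -> int:
    """Report-style rounding to the nearest hundred (halves round up)."""
    return int(math.floor(x / 100.0 + 0.5) * 100)


def adjust_r2(r2, S: int, correction: str = "1/S"):
    """Sample-size correction of raw r2 (default the literal r2 - 1/S).

    Negative adjusted values are passed through; downstream binning treats
    them as unusable.
    """
    if S < 2:
        raise ValueError("sample size must be >= 2")
    if correction == "1/S":
        return np.asarray(r2, dtype=float) - 1.0 / S
    if correction == "1/(2S)":
        return np.asarray(r2, dtype=float) - 1.0 / (2.0 * S)
    raise ValueError(f"unknown correction {correction!r}")


def sved_ne(mean_r2_adj: float, c_t: float, alpha: float = 2.0, mapping: str = "identity") -> float:
    """Invert the Sved relation for one distance bin.

    Ne_t = (1/mean_r2_adj - alpha) / (4 f(c_t)).  Raises ``ValueError`` when
    the bin is unusable (non-positive adjusted LD, or LD at/below the
    mutation-adjustment floor 1/alpha, which would give non-positive Ne).
    """
    if mean_r2_adj <= 0:
        raise ValueError("non-positive adjusted r2: bin rejected")
    if not 0 < c_t <= 0.5:
        raise ValueError("recombination fraction must be in (0, 0.5]")
    if 1.0 / mean_r2_adj <= alpha:
        raise ValueError("adjusted r2 too large for alpha: non-positive Ne, bin rejected")
    f = MAPPINGS[mapping](c_t)
    return (1.0 / mean_r2_adj - alpha) / (4.0 * f)


def historical_ne(
    pairs: LDPairSet, S: int, settings: NeSettings | None = None
) -> NeTrajectory:
    """Historical Ne trajectory from distance-binned LD.

    Pairs are binned per chromosome into ``n_bins`` bins of ``bin_size``;
    each bin's mean r2 is sample-size corrected, mapped to a recombination
    fraction at the bin midpoint, assigned the generation t = 1/(2c)
    (rounded), and inverted with the Sved relation.  Bins with fewer than
    ``min_pairs_per_bin`` pairs, or with unusable LD, are dropped (logged).
    Per-chromosome trajectories are combined per-t by harmonic mean.
    """
    settings = settings or NeSettings()
    if len(pairs) == 0:
        raise ValueError("empty pair set")
    map_fn = settings.map_fn()
    tbl = pairs.table
    records = []  # (chrom, t, ne, c, r2_adj, n)
    for chrom, grp in tbl.groupby("chrom", sort=False):
        d = grp["distance_bp"].to_numpy()
        r2 = grp["r2"].to_numpy()
        for b in range(settings.n_bins):
            lo = b * settings.bin_size
            hi = lo + settings.bin_size
            sel = (d >= lo) & (d < hi)
            n = int(sel.sum())
            if n < settings.min_pairs_per_bin:
                logger.debug("bin [%d,%d) on %s dropped: %d pairs", lo, hi, chrom, n)
                continue
            r2_adj = float(adjust_r2(r2[sel].mean(), S, settings.correction))
            mid = (lo + hi) / 2.0
            c = float(map_fn(mid * settings.morgans_per_bp))
            if c <= 0:
                continue
            t = max(1, int(round(1.0 / (2.0 * c))))
            try:
                ne = sved_ne(r2_adj, c, settings.alpha)
            except ValueError as exc:
                logger.debug("bin [%d,%d) on %s rejected: %s", lo, hi, chrom, exc)
                continue
            records.append((chrom, t, ne, c, r2_adj, n))
    if not records:
        raise ValueError("no usable distance bins")
    df = pd.DataFrame(records, columns=["chrom", "t", "ne", "c", "r2_adj", "n_pairs"])

    per_chrom = {
        chrom: harmonic_mean_ne(g["ne"].to_numpy())
        for chrom, g in df.groupby("chrom", sort=False)
    }
    combined = (
        df.groupby("t")
        .apply(
            lambda g: pd.Series(
                {
                    "ne": harmonic_mean_ne(g["ne"].to_numpy()),
                    "c": g["c"].iloc[0],
                    "mean_r2_adj": np.average(g["r2_adj"], weights=g["n_pairs"]),
                    "n_pairs": g["n_pairs"].sum(),
                }
            ),
            include_groups=False,
        )
        .reset_index()
        .sort_values("t")
        .reset_index(drop=True)
    )
    combined["t"] = combined["t"].astype(int)
    combined["n_pairs"] = combined["n_pairs"].astype(int)
    combined = combined[["t", "ne", "c", "mean_r2_adj", "n_pairs"]]
    return NeTrajectory(
        points=combined, settings=settings, sample_size=S, per_chromosome=per_chrom
    )


# ---------------------------------------------------------------------------
# contemporary Ne (bias-corrected LD method)
# ---------------------------------------------------------------------------

def _waples_expected_sample_r2(S: int) -> float:
    if S >= 30:
        return 1.0 / S + 3.19 / S**2
    return 0.0018 + 0.907 / S + 4.44 / S**2


def _waples_invert(r2_drift: float, S: int, mating: str) -> float:
    """Drift r2 -> Ne with the published second-order constants."""
    if r2_drift <= 0:
        return float("inf")
    if mating == "random":
        a, b = (1.0 / 3.0, 2.76) if S >= 30 else (0.308, 2.08)
    elif mating == "monogamy":
        a, b = (2.0 / 3.0, 7.2) if S >= 30 else (0.618, 5.24)
    else:
        raise ValueError(f"unknown mating model {mating!r}")
    disc = max(a * a - b * r2_drift, 0.0)
    return (a + np.sqrt(disc)) / (2.0 * r2_drift)


def _composite_mean_r2_unlinked(matrix: GenotypeMatrix, pcrit: float):
    """Mean composite r2 over between-chromosome locus pairs.

    Returns (mean_r2, n_pairs, per-chromosome leave-one-out means) after
    excluding loci with minor-allele frequency < pcrit.  With a single
    chromosome all within-chromosome pairs are used (logged), which biases
    Ne downward through physical linkage.
    """
    maf = matrix.minor_allele_frequencies()
    keep = np.flatnonzero(maf >= pcrit)
    if keep.size < 2:
        raise ValueError("no locus pairs survive the pcrit screen")
    sub = matrix.subset_variants(keep)
    calls = sub.calls.astype(float)
    calls[sub.calls == MISSING] = np.nan
    col_mean = np.nanmean(calls, axis=0)
    z = np.nan_to_num(calls - col_mean, nan=0.0)
    denom = np.sqrt(np.nansum(z**2, axis=0))
    ok = denom > 0
    z = z[:, ok] / denom[ok]
    chroms = sub.variants["chrom"].astype(str).to_numpy()[ok]
    r = z.T @ z
    r2 = r**2
    labels = sorted(set(chroms))
    m = r2.shape[0]
    iu = np.triu_indices(m, k=1)
    same = chroms[iu[0]] == chroms[iu[1]]
    if len(labels) >= 2:
        vals = r2[iu][~same]
        pair_chrom_a = chroms[iu[0]][~same]
        pair_chrom_b = chroms[iu[1]][~same]
    else:
        logger.warning("single chromosome: using linked pairs for contemporary Ne")
        vals = r2[iu]
        pair_chrom_a = chroms[iu[0]]
        pair_chrom_b = chroms[iu[1]]
    if vals.size == 0:
        raise ValueError("no locus pairs survive the pcrit screen")
    loo = {}
    for lab in labels:
        out = ~((pair_chrom_a == lab) | (pair_chrom_b == lab))
        if out.any():
            loo[lab] = float(vals[out].mean())
    return float(vals.mean()), int(vals.size), loo


def contemporary_ne_ld(
    matrix: GenotypeMatrix,
    mating: str = "monogamy",
    pcrit: float = 0.05,
    max_loci: int | None = 4000,
    seed: int = 0,
) -> tuple[float, tuple]:
    """Bias-corrected LD estimate of contemporary Ne with a jackknife CI.

    Loci with minor-allele frequency below ``pcrit`` are excluded; the mean
    composite r2 over (preferably between-chromosome) locus pairs, minus
    the expected sampling contribution for S genotyped individuals, is
    inverted to Ne with the Waples & Do constants for the requested mating
    model.  The CI is a delete-one-chromosome jackknife.
    """
    S = matrix.n_samples
    if S < 10:
        raise ValueError("need at least 10 samples")
    if max_loci is not None and matrix.n_variants > max_loci:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(matrix.n_variants, size=max_loci, replace=False))
        matrix = matrix.subset_variants(keep)
    mean_r2, n_pairs, loo = _composite_mean_r2_unlinked(matrix, pcrit)
    exp_r2 = _waples_expected_sample_r2(S)
    ne = _waples_invert(mean_r2 - exp_r2, S, mating)
    if len(loo) >= 2:
        ests = np.array(
            [_waples_invert(v - exp_r2, S, mating) for v in loo.values()]
        )
        finite = np.isfinite(ests)
        if finite.sum() >= 2:
            k = finite.sum()
            mean_j = ests[finite].mean()
            se = np.sqrt((k - 1) / k * ((ests[finite] - mean_j) ** 2).sum())
            ci = (ne - 1.96 * se, ne + 1.96 * se)
        else:
            ci = (np.nan, np.nan)
    else:
        ci = (np.nan, np.nan)
    return ne, ci


def regress_contemporary(trajectory: NeTrajectory, t_window: int | None = None) -> float:
    """Extrapolate contemporary Ne by OLS of Ne_t on t, predicted at t = 1.

    Uses the most recent points: all with t <= 100 by default, or the
    ``t_window`` most recent points when given.
    """
    pts = trajectory.points.sort_values("t")
    if t_window is not None:
        pts = pts.head(int(t_window))
    else:
        pts = pts[pts["t"] <= 100]
    if len(pts) < 2:
        raise ValueError("need at least two trajectory points to regress")
    t = pts["t"].to_numpy(dtype=float)
    ne = pts["ne"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(t, ne, 1)
    pred = intercept + slope * 1.0
    if pred <= 0:
        raise ValueError("regression predicts a non-positive contemporary Ne")
    return float(pred)


def harmonic_mean_ne(values) -> float:
    """Harmonic mean k / sum(1/Ne_i)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values")
    if np.any(values <= 0):
        raise ValueError("harmonic mean requires positive values")
    return float(values.size / np.sum(1.0 / values))


def effective_segments(Ne: float, L: float) -> tuple[float, int]:
    """Effective number of chromosome segments Me = 4 Ne L (raw, rounded)."""
    if Ne <= 0 or L <= 0:
        raise ValueError("Ne and L must be positive")
    me = 4.0 * Ne * L
    return me, round_hundred(me)


@dataclass
class MarkerRequirements:
    markers_10NeL: float
    markers_10NeL_rounded: int
    individuals_2NeL: float
    individuals_2NeL_rounded: int
    Me: float
    Me_rounded: int


def marker_requirements(Ne: float, L: float) -> MarkerRequirements:
    """Marker and sample counts for genomic prediction in unrelated animals.

    10 Ne L markers and 2 Ne L individuals, plus Me = 4 Ne L, raw and
    rounded to the nearest hundred for reporting.
    """
    if Ne <= 0 or L <= 0:
        raise ValueError("Ne and L must be positive")
    me, me_r = effective_segments(Ne, L)
    markers = 10.0 * Ne * L
    inds = 2.0 * Ne * L
    return MarkerRequirements(
        markers_10NeL=markers,
        markers_10NeL_rounded=round_hundred(markers),
        individuals_2NeL=inds,
        individuals_2NeL_rounded=round_hundred(inds),
        Me=me,
        Me_rounded=me_r,
    )
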
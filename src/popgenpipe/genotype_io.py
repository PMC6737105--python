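"""Genotype containers and standard-format input/output.

The central object is :class:`GenotypeMatrix`, a samples x variants table of
diploid alternate-allele dosages (0, 1, 2) with ``-1`` marking missing calls,
carrying a variant map (chromosome, 1-based position, id, ref/alt alleles)
and per-sample population labels.  Every analysis stage consumes and returns
this object.

Supported formats: VCF v4.2 (read via cyvcf2, write as plain text) and
PLINK text PED/MAP.  Only biallelic SNPs are retained; multiallelic or
non-SNP records are skipped with a logged count.  Half-calls and ``./.`` map
to missing.  No strand handling is attempted: dosage always counts the alt
allele as written.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid call, distinct from any dosage.
MISSING: int = -1

_VARIANT_COLS = ["chrom", "pos", "id", "ref", "alt"]
_SAMPLE_COLS = ["id", "population"]

_NUCLEOTIDES = {"A", "C", "G", "T"}


def _natural_key(label: str):
    return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", str(label))]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic SNP genotypes for one labelled population.

    Parameters
    ----------
    calls
        ``(n_samples, n_variants)`` int8 array of alt-allele dosages in
        ``{0, 1, 2}`` with :data:`MISSING` (-1) for no-calls.
    variants
        DataFrame with columns ``chrom, pos, id, ref, alt``; positions are
        1-based and strictly increasing within each chromosome.
    samples
        DataFrame with columns ``id, population``.
    """

    calls: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D samples x variants array")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        if list(self.variants.columns) != _VARIANT_COLS:
            self.variants = self.variants[_VARIANT_COLS]
        if list(self.samples.columns) != _SAMPLE_COLS:
            self.samples = self.samples[_SAMPLE_COLS]
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        self.validate()

    # -- basic protocol ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    @property
    def chromosomes(self) -> list[str]:
        """Unique chromosome labels in natural-sort order."""
        return sorted({str(c) for c in self.variants["chrom"]}, key=_natural_key)

    def validate(self) -> None:
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain values outside {0, 1, 2, missing}")
        if self.variants["id"].duplicated().any():
            raise ValueError("variant ids must be unique")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls.copy(), self.variants.copy(), self.samples.copy()
        )

    # -- subsetting --------------------------------------------------------

    def subset_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.calls[:, index],
            self.variants.iloc[index],
            self.samples,
        )

    def subset_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.calls[index, :],
            self.variants,
            self.samples.iloc[index],
        )

    def variant_indices(self, chromosome) -> np.ndarray:
        return np.flatnonzero(
            self.variants["chrom"].astype(str).to_numpy() == str(chromosome)
        )

    # -- summaries ---------------------------------------------------------

    def allele_frequencies(self) -> np.ndarray:
        """Per-variant alt-allele frequency over non-missing calls.

        Variants with no calls at all get frequency ``nan``.
        """
        called = self.calls != MISSING
        n_called = called.sum(axis=0)
        dosage_sum = np.where(called, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = dosage_sum / (2.0 * n_called)
        return np.where(n_called > 0, p, np.nan)

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def missing_rate_per_variant(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def call_rate_per_sample(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)


@dataclass
class PopulationSet:
    """Several populations restricted to a shared variant map."""

    populations: list[GenotypeMatrix] = field(default_factory=list)
    n_common_markers: int = 0

    def __post_init__(self) -> None:
        if self.populations:
            self.n_common_markers = self.populations[0].n_variants
            ref = _variant_keys(self.populations[0].variants)
            for m in self.populations[1:]:
                if _variant_keys(m.variants) != ref:
                    raise ValueError("populations do not share a variant map")

    def __len__(self) -> int:
        return len(self.populations)

    def __iter__(self):
        return iter(self.populations)

    def __getitem__(self, i) -> GenotypeMatrix:
        return self.populations[i]

    @property
    def labels(self) -> list[str]:
        return [str(m.samples["population"].iloc[0]) for m in self.populations]


def _variant_keys(variants: pd.DataFrame) -> list[tuple]:
    return list(
        zip(
            variants["chrom"].astype(str),
            variants["pos"].astype(int),
            variants["ref"].astype(str),
            variants["alt"].astype(str),
        )
    )


def intersect_markers(populations: list[GenotypeMatrix]) -> PopulationSet:
    """Restrict every population to the markers common to all of them.

    Markers are matched on (chromosome, position, ref, alt); each matrix is
    subset and reordered identically (chromosome natural order, then
    position).  Raises ``ValueError`` when the intersection is empty.
    """
    if not populations:
        raise ValueError("need at least one population")
    key_sets = [set(_variant_keys(m.variants)) for m in populations]
    common = set.intersection(*key_sets)
    if not common:
        raise ValueError("no markers are shared across the populations")
    ordered = sorted(common, key=lambda k: (_natural_key(k[0]), k[1]))
    logger.info("marker intersection retained %d markers", len(ordered))
    out = []
    for m in populations:
        lookup = {k: i for i, k in enumerate(_variant_keys(m.variants))}
        idx = np.array([lookup[k] for k in ordered], dtype=int)
        out.append(m.subset_variants(idx))
    return PopulationSet(out)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, population: str = "pop") -> GenotypeMatrix:
    """Load biallelic SNP genotypes from a VCF file.

    Multiallelic and non-SNP records are skipped (count logged); half-calls
    and ``./.`` become missing.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise ValueError(f"malformed VCF: {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise ValueError(f"VCF has no sample columns: {path}")

    rows, records = [], []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            skipped += 1
            continue
        gts = v.genotypes  # [a0, a1, phased] per sample
        dosages = np.empty(len(sample_ids), dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                dosages[i] = MISSING
            else:
                dosages[i] = a0 + a1
        rows.append(dosages)
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        records.append((str(v.CHROM), int(v.POS), vid, v.REF, v.ALT[0]))
    if skipped:
        logger.info("read_vcf skipped %d multiallelic/non-SNP records", skipped)
    calls = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    variants = pd.DataFrame(records, columns=_VARIANT_COLS)
    samples = pd.DataFrame({"id": sample_ids, "population": population})
    return GenotypeMatrix(calls, variants, samples)


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT fields and contig headers."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popgenpipe\n")
        for chrom in matrix.chromosomes:
            idx = matrix.variant_indices(chrom)
            length = int(matrix.variants["pos"].iloc[idx].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
        fh.write("\t".join(header[:-1]) + "\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.samples["id"].astype(str)) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(matrix.n_variants):
            v = matrix.variants.iloc[j]
            fields = [
                str(v["chrom"]),
                str(int(v["pos"])),
                str(v["id"]),
                str(v["ref"]),
                str(v["alt"]),
                ".",
                "PASS",
                ".",
                "GT",
            ]
            fields += [gt_map[int(c)] for c in matrix.calls[:, j]]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PLINK text (PED/MAP)
# ---------------------------------------------------------------------------

def write_plink_text(
    matrix: GenotypeMatrix, ped_path, map_path, extended_map: bool = True
) -> None:
    """Write PLINK text PED/MAP (alleles spelled as ref/alt, 0 = missing).

    With ``extended_map`` (default) two extra MAP columns record ref and alt
    so dosage orientation survives a round trip even when the alt allele is
    the major one; set False for the strict 4-column MAP.
    """
    with Path(map_path).open("w") as fh:
        for _, v in matrix.variants.iterrows():
            line = f"{v['chrom']}\t{v['id']}\t0\t{int(v['pos'])}"
            if extended_map:
                line += f"\t{v['ref']}\t{v['alt']}"
            fh.write(line + "\n")
    ref = matrix.variants["ref"].to_numpy()
    alt = matrix.variants["alt"].to_numpy()
    pairs = {
        0: lambda j: (ref[j], ref[j]),
        1: lambda j: (ref[j], alt[j]),
        2: lambda j: (alt[j], alt[j]),
        MISSING: lambda j: ("0", "0"),
    }
    with Path(ped_path).open("w") as fh:
        for i in range(matrix.n_samples):
            s = matrix.samples.iloc[i]
            row = [str(s["population"]), str(s["id"]), "0", "0", "0", "-9"]
            for j in range(matrix.n_variants):
                a, b = pairs[int(matrix.calls[i, j])](j)
                row.extend((a, b))
            fh.write(" ".join(row) + "\n")


def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK text PED/MAP into a :class:`GenotypeMatrix`.

    The alt allele at each marker is taken from the MAP file when it carries
    a 5th/6th column (ref/alt), otherwise inferred: the first non-ref allele
    seen, with ref = the most frequent allele.  ``0`` allele codes map to
    missing.
    """
    map_rows = []
    with Path(map_path).open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            map_rows.append(parts)
    m = len(map_rows)

    sample_rows = []
    geno_tokens = []
    with Path(ped_path).open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"PED line has {len(parts)} fields, expected {6 + 2 * m} "
                    "(PED/MAP variant count mismatch)"
                )
            sample_rows.append((parts[1], parts[0]))
            geno_tokens.append(parts[6:])
    alleles = np.array(geno_tokens, dtype="U8").reshape(len(sample_rows), m, 2)

    records = []
    calls = np.empty((len(sample_rows), m), dtype=np.int8)
    for j, row in enumerate(map_rows):
        chrom, vid, pos = row[0], row[1], int(row[3])
        a = alleles[:, j, :]
        if len(row) >= 6:
            ref_a, alt_a = row[4], row[5]
        else:
            obs, counts = np.unique(a[a != "0"], return_counts=True)
            if obs.size == 0:
                ref_a, alt_a = "A", "C"
            elif obs.size == 1:
                ref_a, alt_a = obs[0], _other_allele(obs[0])
            else:
                order = np.argsort(-counts, kind="stable")
                ref_a, alt_a = obs[order[0]], obs[order[1]]
        miss = (a == "0").any(axis=1)
        calls[:, j] = np.where(miss, MISSING, (a == alt_a).sum(axis=1))
        records.append((chrom, pos, vid, ref_a, alt_a))

    variants = pd.DataFrame(records, columns=_VARIANT_COLS)
    samples = pd.DataFrame(sample_rows, columns=_SAMPLE_COLS)
    return GenotypeMatrix(calls, variants, samples)


def _other_allele(a: str) -> str:
    for b in "ACGT":
        if b != a:
            return b
    return "N"
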
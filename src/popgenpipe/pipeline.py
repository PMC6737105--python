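"""End-to-end analysis: QC -> intersect -> prune -> structure -> LD -> Ne.

The stage order mirrors how SNP-array population surveys are normally run:
per-population genotype QC, restriction to the markers shared by every
population, relatedness pruning to a common sample size, population
structure (PCA, heterozygosity, pairwise Fst, ML admixture), per-chromosome
LD decay, and effective-population-size inference with the derived
marker-requirement arithmetic.  Every stage is a pure function of
(inputs, config, seed), so a rerun with the same config reproduces every
number bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ld as ld_mod
from . import ne_inference as ne_mod
from . import popstructure as ps
from . import qc as qc_mod
from . import relatedness as rel_mod
from .genotype_io import GenotypeMatrix, intersect_markers, read_plink_text, read_vcf

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_full_analysis", "load_config"]


@dataclass
class AnalysisConfig:
    """Every analysis parameter, with field-standard defaults.

    ``inputs`` maps a population label to a VCF path or a (PED, MAP) pair;
    populations may instead be passed in memory to
    :func:`run_full_analysis`.
    """

    inputs: dict = field(default_factory=dict)
    qc: qc_mod.QCThresholds = field(default_factory=qc_mod.QCThresholds)
    target_n: int | None = 55
    ld_window_bp: int = 10_000_000
    ld_bin_width: int = 100_000
    ld_max_dist: int = 10_000_000
    ld_estimator: str = "em_haplotype"
    high_ld_threshold: float = 0.80
    ne: ne_mod.NeSettings = field(default_factory=ne_mod.NeSettings)
    pcrit: float = 0.05
    mating: str = "monogamy"
    regression_t_window: int | None = None
    admixture_k: tuple = ()
    pca_components: int = 2
    L_morgans: float = 14.8
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "qc.maf_min": self.qc.maf_min,
            "qc.hwe_p_min": self.qc.hwe_p_min,
            "qc.marker_missing_max": self.qc.marker_missing_max,
            "qc.sample_callrate_min": self.qc.sample_callrate_min,
            "target_n": self.target_n,
            "ld_window_bp": self.ld_window_bp,
            "ld_bin_width": self.ld_bin_width,
            "ld_estimator": self.ld_estimator,
            "ne.n_bins": self.ne.n_bins,
            "ne.bin_size": self.ne.bin_size,
            "ne.alpha": self.ne.alpha,
            "ne.mapping": self.ne.mapping,
            "ne.morgans_per_bp": self.ne.morgans_per_bp,
            "pcrit": self.pcrit,
            "mating": self.mating,
            "L_morgans": self.L_morgans,
            "seed": self.seed,
        }


def load_config(path) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a flat TOML key-value file."""
    import tomllib

    with Path(path).open("rb") as fh:
        raw = tomllib.load(fh)
    cfg = AnalysisConfig()
    cfg.inputs = dict(raw.get("inputs", {}))
    q = raw.get("qc", {})
    cfg.qc = qc_mod.QCThresholds(
        maf_min=q.get("maf_min", 0.05),
        hwe_p_min=q.get("hwe_p_min", 1e-6),
        marker_missing_max=q.get("marker_missing_max", 0.70),
        sample_callrate_min=q.get("sample_callrate_min", 0.95),
    )
    n = raw.get("ne", {})
    cfg.ne = ne_mod.NeSettings(
        n_bins=n.get("n_bins", 30),
        bin_size=n.get("bin_size", 50_000),
        alpha=n.get("alpha", 2.0),
        mapping=n.get("mapping", "identity"),
        morgans_per_bp=n.get("morgans_per_bp", 1e-8),
        min_pairs_per_bin=n.get("min_pairs_per_bin", 50),
    )
    for key in (
        "target_n", "ld_window_bp", "ld_bin_width", "ld_max_dist", "ld_estimator",
        "high_ld_threshold", "pcrit", "mating", "regression_t_window",
        "pca_components", "L_morgans", "seed",
    ):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "admixture_k" in raw:
        cfg.admixture_k = tuple(raw["admixture_k"])
    return cfg


def _load_population(label: str, source) -> GenotypeMatrix:
    if isinstance(source, (tuple, list)):
        mat = read_plink_text(*source)
    else:
        mat = read_vcf(source, population=label)
    mat.samples["population"] = label
    return mat


def _merge_populations(pops: list[GenotypeMatrix]) -> GenotypeMatrix:
    calls = np.vstack([m.calls for m in pops])
    samples = pd.concat([m.samples for m in pops], ignore_index=True)
    return GenotypeMatrix(calls, pops[0].variants.copy(), samples)


def run_full_analysis(
    config: AnalysisConfig,
    out_dir=None,
    populations: list[GenotypeMatrix] | None = None,
) -> dict:
    """Run the whole pipeline; returns a report bundle of DataFrames.

    ``populations`` bypasses file loading (labels come from the matrices'
    population columns).  When ``out_dir`` is given every table is also
    written as TSV, with the full parameter set echoed to
    ``parameters.json``.
    """
    if populations is None:
        if not config.inputs:
            raise ValueError("config lists no inputs and no populations were passed")
        populations = [
            _load_population(label, src) for label, src in config.inputs.items()
        ]
    labels = [str(m.samples["population"].iloc[0]) for m in populations]
    report: dict = {"labels": labels, "parameters": config.to_dict()}

    # --- stage 1: per-population QC -------------------------------------
    try:
        qc_rows, clean = [], []
        for label, mat in zip(labels, populations):
            filtered, rep = qc_mod.apply_qc(mat, config.qc)
            clean.append(filtered)
            qc_rows.append({"population": label, **rep.to_dict()})
        report["qc"] = pd.DataFrame(qc_rows)
    except Exception as exc:
        raise RuntimeError(f"stage qc failed: {exc}") from exc

    # --- stage 2: marker intersection ------------------------------------
    try:
        popset = intersect_markers(clean)
        report["n_common_markers"] = popset.n_common_markers
    except Exception as exc:
        raise RuntimeError(f"stage intersect failed: {exc}") from exc

    # --- stage 3: relatedness pruning ------------------------------------
    try:
        pruned = []
        rel_rows = []
        for label, mat in zip(labels, popset):
            target = config.target_n
            if target is not None and mat.n_samples > target:
                mat = rel_mod.prune_related(mat, target)
            pim = rel_mod.pi_hat_matrix(mat)
            iu = np.triu_indices(mat.n_samples, k=1)
            rel_rows.append(
                {
                    "population": label,
                    "n_samples": mat.n_samples,
                    "mean_pi_hat": float(pim[iu].mean()),
                    "sd_pi_hat": float(pim[iu].std(ddof=1)),
                }
            )
            pruned.append(mat)
        report["relatedness"] = pd.DataFrame(rel_rows)
    except Exception as exc:
        raise RuntimeError(f"stage relatedness failed: {exc}") from exc

    # --- stage 4: population structure -----------------------------------
    try:
        merged = _merge_populations(pruned)
        pca_res = ps.pca(merged, config.pca_components)
        scores = pd.DataFrame(
            pca_res.coordinates,
            columns=[f"PC{i + 1}" for i in range(config.pca_components)],
        )
        scores.insert(0, "population", merged.samples["population"].to_numpy())
        scores.insert(0, "id", merged.samples["id"].to_numpy())
        report["pca_scores"] = scores
        report["pca_explained"] = pd.DataFrame(
            {
                "component": np.arange(1, config.pca_components + 1),
                "explained_fraction": pca_res.explained_fraction,
            }
        )

        het_rows = []
        for label, mat in zip(labels, pruned):
            h = ps.heterozygosity(mat)
            het_rows.append({"population": label, "Ho": h.Ho, "He": h.He})
        report["heterozygosity"] = pd.DataFrame(het_rows)

        fst_rows = []
        for i in range(len(pruned)):
            for j in range(i + 1, len(pruned)):
                res = ps.weir_cockerham_fst(pruned[i], pruned[j])
                fst_rows.append(
                    {
                        "pop1": labels[i],
                        "pop2": labels[j],
                        "fst_ratio_of_sums": res.mean_theta,
                        "fst_mean_of_ratios": res.mean_of_ratios,
                        "fst_sd": res.sd_theta,
                    }
                )
        report["fst"] = pd.DataFrame(fst_rows)

        if config.admixture_k:
            cv = ps.select_k(merged, config.admixture_k, seed=config.seed)
            best_k = min(cv, key=cv.get)
            fit = ps.admixture_em(merged, best_k, seed=config.seed)
            qdf = pd.DataFrame(
                fit.Q, columns=[f"Q{k + 1}" for k in range(best_k)]
            )
            qdf.insert(0, "population", merged.samples["population"].to_numpy())
            qdf.insert(0, "id", merged.samples["id"].to_numpy())
            report["admixture_cv"] = pd.DataFrame(
                {"K": list(cv), "cv_error": list(cv.values())}
            )
            report["admixture_q"] = qdf
            report["admixture_best_k"] = best_k
    except Exception as exc:
        raise RuntimeError(f"stage structure failed: {exc}") from exc

    # --- stage 5 + 6: LD and Ne per population ---------------------------
    try:
        table2_rows, decay_frames, traj_frames, summary_rows = [], [], [], []
        for label, mat in zip(labels, pruned):
            decay_pairs = ld_mod.pairwise_r2(
                mat, window_bp=config.ld_window_bp, estimator=config.ld_estimator
            )
            curve = ld_mod.bin_ld_decay(
                decay_pairs, config.ld_bin_width, config.ld_max_dist
            )
            dframe = curve.to_frame()
            dframe.insert(0, "population", label)
            decay_frames.append(dframe)

            ne_pairs = (
                decay_pairs
                if config.ld_estimator == "composite"
                else ld_mod.pairwise_r2(
                    mat, window_bp=config.ld_window_bp, estimator="composite"
                )
            )
            traj = ne_mod.historical_ne(ne_pairs, mat.n_samples, config.ne)
            tframe = traj.points.copy()
            tframe.insert(0, "population", label)
            traj_frames.append(tframe)

            for chrom in mat.chromosomes:
                sel = ne_pairs.table["chrom"] == chrom
                sub = ne_pairs.table[sel]
                pos = mat.variants["pos"][mat.variant_indices(chrom)]
                table2_rows.append(
                    {
                        "population": label,
                        "chrom": chrom,
                        "n_snps": int(mat.variant_indices(chrom).size),
                        "size_mb": float(pos.max() / 1e6),
                        "mean_r2": float(sub["r2"].mean()) if len(sub) else np.nan,
                        "sd_r2": float(sub["r2"].std(ddof=1)) if len(sub) > 1 else np.nan,
                        "ne_harmonic": traj.per_chromosome.get(chrom, np.nan),
                    }
                )

            ne_hat, ci = ne_mod.contemporary_ne_ld(
                mat, mating=config.mating, pcrit=config.pcrit, seed=config.seed
            )
            try:
                ne_reg = ne_mod.regress_contemporary(traj, config.regression_t_window)
            except ValueError:
                ne_reg = np.nan
            harm_overall = ne_mod.harmonic_mean_ne(traj.ne)
            req_basis = ne_hat if np.isfinite(ne_hat) else harm_overall
            req = ne_mod.marker_requirements(req_basis, config.L_morgans)
            summary_rows.append(
                {
                    "population": label,
                    "contemporary_ne_ld": ne_hat,
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                    "contemporary_ne_regression": ne_reg,
                    "historical_ne_harmonic": harm_overall,
                    "Me": req.Me,
                    "Me_rounded": req.Me_rounded,
                    "markers_10NeL": req.markers_10NeL,
                    "markers_10NeL_rounded": req.markers_10NeL_rounded,
                    "individuals_2NeL": req.individuals_2NeL,
                    "individuals_2NeL_rounded": req.individuals_2NeL_rounded,
                }
            )
        report["ld_decay"] = pd.concat(decay_frames, ignore_index=True)
        report["ne_trajectory"] = pd.concat(traj_frames, ignore_index=True)
        report["per_chromosome"] = pd.DataFrame(table2_rows)
        report["ne_summary"] = pd.DataFrame(summary_rows)
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage ld/ne failed: {exc}") from exc

    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for key, value in report.items():
        if isinstance(value, pd.DataFrame):
            value.to_csv(out_dir / f"{key}.tsv", sep="\t", index=False)
    meta = {
        k: v
        for k, v in report.items()
        if not isinstance(v, pd.DataFrame)
    }
    with (out_dir / "parameters.json").open("w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    logger.info("report written to %s", out_dir)
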
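"""End-to-end pipeline driver over a synthetic (or loaded) study.

Stage order: morphometrics -> phenotypic trajectories -> population
genetics -> RDA association -> expression -> integration.  Every
stochastic stage consumes a seed derived deterministically from the
global seed and the stage name, so a rerun with the same configuration
is byte-reproducible (verified by the output manifest's content hashes).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, expr, integrate, io, morpho, popgen, traj
from .synth import StudyBundle, SynthConfig, simulate_study, sympatric_pairs

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0
    outdir: str = "pipeline_out"
    n_perm_traj: int = 499
    n_perm_fst: int = 200
    n_perm_rda: int = 499
    n_perm_mantel: int = 999
    n_resample_sharing: int = 10000
    outlier_quantile: float = 0.95
    rda_z: float = 2.0
    de_fdr: float = 0.05
    eqtl_fdr: float = 0.1
    eqtl_window: int = 1_000_000
    gene_min_per_lake: int = 20
    module_min_size: int = 25
    module_cut_height: float = 0.992
    module_merge_dist: float = 0.25
    variance_filter_threshold: float = 0.10
    run_permuted_outliers: bool = True
    stages: tuple[str, ...] = ("morpho", "traj", "popgen", "assoc", "expr", "integrate")


@dataclass
class PipelineResult:
    bundle: StudyBundle
    corrected: morpho.CorrectedTraits | None = None
    trait_pca: morpho.PcaResult | None = None
    eta2: pd.DataFrame | None = None
    traj_pheno: traj.TrajectorySet | None = None
    qc_dataset: popgen.GenotypeDataset | None = None
    qc_removed: dict | None = None
    fst_scans: dict | None = None           # pair label -> FstScan
    diversity: popgen.DiversityResult | None = None
    traj_neutral: traj.TrajectorySet | None = None
    rda: dict | None = None                 # lineage -> RdaResult
    traj_assoc: traj.TrajectorySet | None = None
    expr_matrix: expr.ExpressionMatrix | None = None
    de_results: dict | None = None
    eco_genes: list | None = None
    modules: expr.ModuleSet | None = None
    module_trait: pd.DataFrame | None = None
    eqtl: expr.EqtlResult | None = None
    traj_expr: traj.TrajectorySet | None = None
    traj_assoc_expr: traj.TrajectorySet | None = None
    ecosystem: integrate.EcosystemPC | None = None
    report: pd.DataFrame | None = None
    manifest: dict | None = None


def _freq_matrix(dataset: popgen.GenotypeDataset, samples: pd.DataFrame,
                 loci_mask: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(lake, ecotype) alternate-allele frequencies at the masked loci.

    Returns the frequency matrix (groups x loci) and a matching pseudo
    sample table (one row per group) for trajectory analysis.
    """
    rows, meta = [], []
    for (lake, eco), idx in samples.groupby(["lake", "ecotype"]).indices.items():
        sub = dataset.dosages[np.asarray(idx)][:, loci_mask]
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(sub, axis=0) / 2.0
        freq = np.where(np.isfinite(freq), freq, np.nanmean(freq))
        rows.append(freq)
        lineage = samples.iloc[idx[0]]["lineage"]
        meta.append({"id": f"{lake}|{eco}", "lake": lake,
                     "lineage": lineage, "ecotype": eco})
    return pd.DataFrame(rows), pd.DataFrame(meta)


def _group_score_trajectories(scores: pd.DataFrame, samples: pd.DataFrame,
                              pair_spec, k50: int) -> traj.TrajectorySet:
    """Trajectories over group-level rows (>=1 row per group).

    Group-level feature matrices (e.g. allele frequencies) have a single
    row per (lake, ecotype); centroids are those rows themselves, so the
    minimum-two-individuals rule is relaxed by duplicating rows.
    """
    dup_scores = pd.concat([scores, scores])
    dup_samples = pd.concat([samples, samples], ignore_index=True)
    ts = traj.compute_trajectories(dup_scores.iloc[:, :k50], dup_samples, pair_spec)
    return ts


def run_pipeline(config: PipelineConfig, bundle: StudyBundle | None = None,
                 write_outputs: bool = True) -> PipelineResult:
    """Run all requested stages; returns every intermediate result.

    Raises with the failing stage's name on error.  When
    ``write_outputs`` is set, per-stage tables and a manifest of content
    hashes are written under ``config.outdir``.
    """
    t0 = time.time()
    if bundle is None:
        bundle = simulate_study(config.synth)
    res = PipelineResult(bundle=bundle)
    outdir = Path(config.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_bundle(bundle, outdir / "inputs")
    pairs = sympatric_pairs(bundle)
    samples = bundle.samples
    stage = "setup"
    try:
        if "morpho" in config.stages:
            stage = "morpho"
            res.corrected = morpho.size_correct_traits(
                bundle.traits, samples.set_index("id")["fork_length"],
                samples.set_index("id")["lake"], samples.set_index("id")["ecotype"],
                samples.set_index("id")["lineage"])
            res.trait_pca = morpho.pca(res.corrected.Y, center=True, scale=True)
            responses = pd.concat(
                [res.corrected.Y.reset_index(drop=True),
                 res.trait_pca.scores.iloc[:, :4].reset_index(drop=True)], axis=1)
            res.eta2 = morpho.eta2_table(responses, samples)
            logger.info("morpho done (%.1fs)", time.time() - t0)

        if "traj" in config.stages:
            stage = "traj"
            ts = traj.compute_trajectories(res.trait_pca, samples, pairs)
            res.traj_pheno = traj.permutation_test(
                ts, res.trait_pca, samples, pairs,
                n_perm=config.n_perm_traj, seed=stage_seed(config.seed, "traj"))

        if "popgen" in config.stages:
            stage = "popgen"
            raw = popgen.GenotypeDataset(bundle.genotypes, bundle.loci,
                                         list(samples["id"]))
            res.qc_dataset, res.qc_removed = popgen.genotype_qc(
                raw, samples["lake"], one_snp_per_locus=False)
            scans = {}
            for lake, eco_a, eco_b in pairs:
                ids_a = samples.loc[(samples["lake"] == lake) & (samples["ecotype"] == eco_a), "id"]
                ids_b = samples.loc[(samples["lake"] == lake) & (samples["ecotype"] == eco_b), "id"]
                scan = popgen.wc_fst(res.qc_dataset, list(ids_a), list(ids_b))
                scan = popgen.outliers_empirical(scan, quantile=config.outlier_quantile)
                if config.run_permuted_outliers:
                    scan = popgen.outliers_permuted(
                        res.qc_dataset, samples, lake, eco_a, eco_b,
                        n_perm=config.n_perm_fst,
                        seed=stage_seed(config.seed, f"fst:{lake}:{eco_b}"),
                        scan=scan)
                scans[f"{lake}:{eco_a}>{eco_b}"] = scan
            res.fst_scans = scans
            pops = {f"{lake}|{eco}": list(samples.loc[(samples["lake"] == lake)
                                                      & (samples["ecotype"] == eco), "id"])
                    for lake, eco in samples.groupby(["lake", "ecotype"]).groups}
            res.diversity = popgen.nucleotide_diversity(res.qc_dataset, pops)
            # neutral-SNP trajectories: per-group allele frequencies, PCA, k50
            neutral = np.ones(len(res.qc_dataset.loci), dtype=bool)
            for scan in scans.values():
                neutral &= ~scan.empirical_outliers
            freqs, meta = _freq_matrix(res.qc_dataset, samples, neutral)
            fp = morpho.pca(freqs, center=True, scale=False)
            res.traj_neutral = _group_score_trajectories(fp.scores, meta, pairs, fp.k50)
            logger.info("popgen done (%.1fs)", time.time() - t0)

        if "assoc" in config.stages:
            stage = "assoc"
            imputed, _ = popgen.impute_missing(res.qc_dataset, samples["lake"])
            rda_by_lineage = {}
            cand_union = set()
            for lineage in pd.unique(samples["lineage"]):
                rows = samples.index[samples["lineage"] == lineage].to_numpy()
                response = pd.DataFrame(imputed.dosages[rows],
                                        index=samples.loc[rows, "id"],
                                        columns=range(imputed.dosages.shape[1]))
                r = assoc.partial_rda(
                    response, samples.loc[rows, "ecotype"].set_axis(response.index),
                    samples.loc[rows, ["lake"]].set_axis(response.index),
                    n_perm=config.n_perm_rda,
                    seed=stage_seed(config.seed, f"rda:{lineage}"),
                    z_threshold=config.rda_z)
                rda_by_lineage[lineage] = r
                cand_union |= set(r.candidates)
            res.rda = rda_by_lineage
            if cand_union:
                mask = np.zeros(imputed.dosages.shape[1], dtype=bool)
                mask[sorted(cand_union)] = True
                freqs, meta = _freq_matrix(imputed, samples, mask)
                fp = morpho.pca(freqs, center=True, scale=False)
                res.traj_assoc = _group_score_trajectories(fp.scores, meta, pairs, fp.k50)

        if "expr" in config.stages:
            stage = "expr"
            filtered = expr.filter_genes(bundle.counts, samples["lake"],
                                         min_per_lake=config.gene_min_per_lake)
            res.expr_matrix = expr.normalize(filtered, genes=bundle.genes)
            de = {}
            for lake, eco_a, eco_b in pairs:
                de[f"{lake}:{eco_a}>{eco_b}"] = expr.differential_expression(
                    res.expr_matrix, samples, lake, eco_a, eco_b)
            res.de_results = de
            res.eco_genes = expr.ecotype_variance_filter(
                res.expr_matrix, samples, threshold=config.variance_filter_threshold)
            if len(res.eco_genes) >= config.module_min_size:
                res.modules = expr.coexpression_modules(
                    res.expr_matrix, gene_subset=res.eco_genes,
                    cut_height=config.module_cut_height,
                    min_size=config.module_min_size,
                    merge_dist=config.module_merge_dist)
                if len(res.modules.module_sizes):
                    res.module_trait = expr.module_trait_correlation(res.modules, samples)
            imputed, _ = popgen.impute_missing(res.qc_dataset, samples["lake"]) \
                if res.qc_dataset is not None else (None, None)
            if imputed is not None:
                res.eqtl = expr.cis_eqtl(res.expr_matrix, imputed, imputed.loci,
                                         samples, genes=bundle.genes,
                                         window=config.eqtl_window)
            # expression trajectories (all genes, and ecotype-associated genes)
            ep = morpho.pca(res.expr_matrix.log2.T, center=True, scale=False)
            res.traj_expr = traj.compute_trajectories(
                ep.scores.iloc[:, :ep.k50],
                samples.set_index("id").loc[res.expr_matrix.log2.columns].reset_index(),
                pairs)
            if res.eco_genes and len(res.eco_genes) >= 2:
                cp = morpho.pca(res.expr_matrix.log2.loc[res.eco_genes].T,
                                center=True, scale=False)
                res.traj_assoc_expr = traj.compute_trajectories(
                    cp.scores.iloc[:, :cp.k50],
                    samples.set_index("id").loc[res.expr_matrix.log2.columns].reset_index(),
                    pairs)
            logger.info("expr done (%.1fs)", time.time() - t0)

        if "integrate" in config.stages:
            stage = "integrate"
            res.ecosystem = integrate.ecosystem_pc(bundle.environment)
            fst_by_pair = None
            pi_by_lake = None
            if res.fst_scans is not None:
                fst_by_pair = {}
                for label, scan in res.fst_scans.items():
                    neutral = scan.neutral_mask()
                    a, b, c = scan.components
                    denom = (a + b + c)[neutral]
                    fst_by_pair[label] = float(np.nansum(a[neutral]) / np.nansum(denom))
            if res.diversity is not None:
                pi_by_lake = {}
                by_lake: dict[str, list] = {}
                for label, val in res.diversity.pi.items():
                    by_lake.setdefault(label.split("|")[0], []).append(val)
                pi_by_lake = {k: float(np.mean(v)) for k, v in by_lake.items()}
            tv = None
            if res.corrected is not None:
                tv = integrate.mean_trait_variance_by_lake(
                    res.corrected.Y, samples.set_index("id")["lake"])
            res.report = integrate.predictability_report(
                traj_pheno=res.traj_pheno, traj_neutral=res.traj_neutral,
                traj_assoc=res.traj_assoc, traj_expr=res.traj_expr,
                traj_assoc_expr=res.traj_assoc_expr,
                fst_neutral_by_pair=fst_by_pair, pi_by_lake=pi_by_lake,
                trait_variance_by_lake=tv, ecosystem=res.ecosystem,
                n_perm=config.n_perm_mantel,
                seed=stage_seed(config.seed, "integrate"))
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    if write_outputs:
        res.manifest = _write_outputs(config, res, outdir)
    logger.info("pipeline complete in %.1fs", time.time() - t0)
    return res


def _write_outputs(config: PipelineConfig, res: PipelineResult, outdir: Path) -> dict:
    files = {}

    def save_df(name: str, df: pd.DataFrame):
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        files[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    if res.corrected is not None:
        save_df("corrected_traits.csv", res.corrected.Y.reset_index(names="id"))
        save_df("allometry_slopes.csv", res.corrected.b)
    if res.eta2 is not None:
        save_df("eta2.csv", res.eta2)
    if res.traj_pheno is not None:
        save_df("trajectories_phenotype.csv", res.traj_pheno.comparisons())
    if res.fst_scans is not None:
        rows = []
        for label, scan in res.fst_scans.items():
            loci = res.qc_dataset.loci
            rows.append(pd.DataFrame({
                "pair": label, "chrom": loci["chrom"], "pos": loci["pos"],
                "fst": scan.per_locus, "zfst": scan.zfst,
                "empirical_outlier": scan.empirical_outliers,
                "permuted_outlier": (scan.permuted_outliers
                                     if scan.permuted_outliers is not None else False),
            }))
        save_df("fst_scan.csv", pd.concat(rows, ignore_index=True))
    if res.rda is not None:
        rows = []
        for lineage, r in res.rda.items():
            z = r.z.reset_index(names="feature")
            z.insert(0, "lineage", lineage)
            rows.append(z)
        save_df("rda_z.csv", pd.concat(rows, ignore_index=True))
    if res.de_results is not None:
        save_df("differential_expression.csv",
                pd.concat([d.table for d in res.de_results.values()], ignore_index=True))
    if res.modules is not None:
        save_df("modules.csv",
                res.modules.assignment.rename("module").rename_axis("gene").reset_index())
    if res.eqtl is not None:
        save_df("eqtl.csv", res.eqtl.table)
    if res.report is not None:
        save_df("integration_report.csv", res.report)

    manifest = {
        "seed": config.seed,
        "synth_seed": config.synth.seed,
        "thresholds": {
            "outlier_quantile": config.outlier_quantile, "rda_z": config.rda_z,
            "de_fdr": config.de_fdr, "eqtl_fdr": config.eqtl_fdr,
            "eqtl_window": config.eqtl_window,
            "module": [config.module_min_size, config.module_cut_height,
                       config.module_merge_dist],
        },
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
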
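"""Expression normalisation, differential expression, co-expression
modules and cis-eQTL mapping.

Counts are normalised by median-of-ratios size factors (each library's
median ratio to the per-gene geometric mean, rescaled to geometric mean
one) and log2 transformed, ``log2(count / sf + 1)``.

Differential expression between sympatric ecotypes is a per-gene Welch
t-test on the normalised values within each lake, Benjamini–Hochberg
corrected per lake (DEG set at FDR < 0.05).

Co-expression modules come from average-linkage hierarchical clustering
of the correlation-based dissimilarity ``1 - |r|^soft_power`` with a
static cut (cut height 0.992, minimum module size 25) and eigengene
merging (correlation distance < 0.25).  Module eigengenes (first
principal component of member expression, sign-oriented to a positive
mean loading) are correlated with ecotype and lake.

cis-eQTL: for every gene-SNP pair within 1 Mb, least-squares fit of
normalised expression on additive dosage with lake and lineage dummies;
BH-FDR across all tested pairs (significant sets at 0.1 and 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    counts: pd.DataFrame            # genes x individuals, raw
    size_factors: pd.Series         # per individual, geometric mean 1
    log2: pd.DataFrame              # normalised log2 values
    genes: pd.DataFrame | None = None   # chrom, pos per gene


@dataclass
class DeResult:
    table: pd.DataFrame             # gene, lake, log2fc, t, p, fdr
    fdr_threshold: float = 0.05

    def degs(self, lake: str | None = None) -> set:
        t = self.table
        if lake is not None:
            t = t[t["lake"] == lake]
        return set(t.loc[t["fdr"] < self.fdr_threshold, "gene"])


@dataclass
class ModuleSet:
    assignment: pd.Series           # gene -> module label ("M1", ...) or "unassigned"
    eigengenes: pd.DataFrame        # individuals x modules, unit-norm columns
    module_sizes: pd.Series

    def members(self, module: str) -> list:
        return list(self.assignment.index[self.assignment == module])


@dataclass
class EqtlResult:
    table: pd.DataFrame             # gene, snp, distance, beta, t, p, fdr

    def significant(self, fdr: float = 0.1) -> pd.DataFrame:
        return self.table[self.table["fdr"] < fdr]


# ---------------------------------------------------------------------------


def normalize(counts: pd.DataFrame, genes: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Median-of-ratios size factors and log2 normalisation.

    Size factors are the per-library median of count ratios to the
    per-gene geometric mean (genes with any zero count excluded from the
    reference), rescaled so their geometric mean is one.
    """
    X = counts.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    zero_lib = X.sum(axis=0) == 0
    if zero_lib.any():
        bad = list(counts.columns[zero_lib])
        raise ValueError(f"samples with all-zero counts: {bad}")
    positive = (X > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with all-positive counts for the reference")
    ref = np.exp(np.log(X[positive]).mean(axis=1))
    ratios = X[positive] / ref[:, None]
    sf = np.median(ratios, axis=0)
    sf = sf / np.exp(np.log(sf).mean())   # geometric mean 1
    log2 = np.log2(X / sf[None, :] + 1.0)
    return ExpressionMatrix(
        counts=counts,
        size_factors=pd.Series(sf, index=counts.columns, name="size_factor"),
        log2=pd.DataFrame(log2, index=counts.index, columns=counts.columns),
        genes=genes,
    )


def filter_genes(counts: pd.DataFrame, lakes: pd.Series,
                 min_per_lake: int = 20) -> pd.DataFrame:
    """Keep genes with at least ``min_per_lake`` total counts in every lake."""
    lakes = pd.Series(np.asarray(lakes, dtype=object), index=counts.columns)
    keep = np.ones(len(counts), dtype=bool)
    for lake in pd.unique(lakes):
        cols = counts.columns[lakes == lake]
        keep &= counts[cols].sum(axis=1).to_numpy() >= min_per_lake
    out = counts.loc[keep]
    if out.empty:
        logger.warning("no genes survive the per-lake count filter")
    return out


def differential_expression(expr: ExpressionMatrix, samples: pd.DataFrame,
                            lake: str, eco_a: str, eco_b: str) -> DeResult:
    """Welch t-test per gene between two sympatric ecotypes of one lake.

    log2 fold change is oriented derived-minus-reference (B - A).  Genes
    with zero variance in both groups are reported with p = 1.  BH
    correction is applied within the lake.
    """
    sub = samples[samples["lake"] == lake]
    ids_a = sub.loc[sub["ecotype"] == eco_a, "id"]
    ids_b = sub.loc[sub["ecotype"] == eco_b, "id"]
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError(f"lake {lake} lacks one of the requested ecotypes")
    if min(len(ids_a), len(ids_b)) < 3:
        logger.warning("fewer than 3 individuals per ecotype in %s", lake)
    A = expr.log2[list(ids_a)].to_numpy()
    B = expr.log2[list(ids_b)].to_numpy()
    lfc = B.mean(axis=1) - A.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(B, A, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, 1.0, p)
    t = np.where(np.isfinite(t), t, 0.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({
        "gene": expr.log2.index, "lake": lake, "log2fc": lfc,
        "t": t, "p": p, "fdr": fdr,
    })
    return DeResult(table=table)


def deg_sharing(de_a: DeResult, de_b: DeResult, universe,
                seed: int | None = None, n_resample: int = 10000):
    """Sharing of DEG sets between two comparisons (resampling test)."""
    from .popgen import sharing_test
    return sharing_test(de_a.degs(), de_b.degs(), universe,
                        n_resample=n_resample, level="gene", seed=seed)


def ecotype_variance_filter(expr: ExpressionMatrix, samples: pd.DataFrame,
                            threshold: float = 0.10) -> list:
    """Genes whose ecotype term explains > ``threshold`` of total variance.

    Per gene, a fixed-effects two-way ANOVA ``log2 ~ ecotype + lake``
    (sequential with ecotype fitted after lake, so the ecotype share is
    net of lake differences); the retained fraction is SS_eco / SS_total.
    """
    sample_ids = list(expr.log2.columns)
    meta = samples.set_index("id").loc[sample_ids]
    if meta["ecotype"].nunique() < 2 or meta["lake"].nunique() < 2:
        raise ValueError("need >= 2 ecotypes and >= 2 lakes")
    lake_d = pd.get_dummies(meta["lake"], drop_first=False).to_numpy(dtype=float)
    eco_d = pd.get_dummies(meta["ecotype"], drop_first=True).to_numpy(dtype=float)
    Y = expr.log2.to_numpy().T               # samples x genes
    ss_total = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    beta_l, *_ = np.linalg.lstsq(lake_d, Y, rcond=None)
    resid_lake = Y - lake_d @ beta_l
    X_full = np.hstack([lake_d, eco_d])
    beta_f, *_ = np.linalg.lstsq(X_full, Y, rcond=None)
    resid_full = Y - X_full @ beta_f
    ss_eco = (resid_lake ** 2).sum(axis=0) - (resid_full ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(ss_total > 0, ss_eco / ss_total, 0.0)
    return list(expr.log2.index[frac > threshold])


def _eigengene(block: np.ndarray) -> np.ndarray:
    """First PC of a genes x samples block, unit norm, positive mean loading."""
    centered = block - block.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eg = vt[0]
    if u[:, 0].mean() < 0:
        eg = -eg
    return eg


def coexpression_modules(expr: ExpressionMatrix, gene_subset=None,
                         soft_power: float = 6.0, cut_height: float = 0.992,
                         min_size: int = 25, merge_dist: float = 0.25) -> ModuleSet:
    """Static-cut co-expression modules on correlation dissimilarity.

    Adjacency ``|r|^soft_power`` between gene expression profiles;
    dissimilarity ``1 - adjacency``; average-linkage hierarchical
    clustering cut at ``cut_height``; clusters below ``min_size`` go to
    "unassigned"; modules whose eigengenes have correlation distance
    ``1 - r`` below ``merge_dist`` are merged.  Labels ("M1", "M2", ...)
    are ordered by decreasing size, deterministically.
    """
    log2 = expr.log2 if gene_subset is None else expr.log2.loc[list(gene_subset)]
    X = log2.to_numpy()
    variable = X.std(axis=1) > 0
    if variable.sum() < 2:
        raise ValueError("need >= 2 genes with expression variance")
    if (~variable).any():
        logger.warning("excluding %d zero-variance genes", int((~variable).sum()))
    genes = log2.index[variable]
    X = X[variable]
    if len(genes) < min_size:
        assignment = pd.Series("unassigned", index=log2.index)
        return ModuleSet(assignment=assignment,
                         eigengenes=pd.DataFrame(index=log2.columns),
                         module_sizes=pd.Series(dtype=int))
    r = np.corrcoef(X)
    dissim = 1.0 - np.abs(r) ** soft_power
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0
    linkage = hierarchy.average(squareform(dissim, checks=False))
    labels = hierarchy.fcluster(linkage, t=cut_height, criterion="distance")

    clusters = {}
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        if len(members) >= min_size:
            clusters[lab] = members

    # merge modules with similar eigengenes until stable
    merged = {i: list(m) for i, m in enumerate(clusters.values())}
    changed = True
    while changed and len(merged) > 1:
        changed = False
        keys = sorted(merged)
        egs = {k: _eigengene(X[merged[k]]) for k in keys}
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                d = 1.0 - np.corrcoef(egs[keys[ai]], egs[keys[bi]])[0, 1]
                if d < merge_dist and (best is None or d < best[0]):
                    best = (d, keys[ai], keys[bi])
        if best is not None:
            _, ka, kb = best
            merged[ka] = merged[ka] + merged.pop(kb)
            changed = True

    modules = sorted(merged.values(), key=lambda m: (-len(m), min(m)))
    assignment = pd.Series("unassigned", index=log2.index, dtype=object)
    eg_cols = {}
    sizes = {}
    for k, members in enumerate(modules, start=1):
        label = f"M{k}"
        assignment.loc[genes[members]] = label
        eg_cols[label] = _eigengene(X[members])
        sizes[label] = len(members)
    eigengenes = pd.DataFrame(eg_cols, index=log2.columns)
    return ModuleSet(assignment=assignment, eigengenes=eigengenes,
                     module_sizes=pd.Series(sizes, dtype=int))


def module_trait_correlation(modules: ModuleSet, samples: pd.DataFrame,
                             ecotype_reference: str | None = None) -> pd.DataFrame:
    """Pearson correlation of module eigengenes with ecotype and lake.

    Ecotype is coded 0 for the reference (planktivorous by convention)
    and 1 otherwise; for lake (a multi-level factor) the maximum |r| over
    per-lake dummies is reported with its p-value.  BH correction across
    the whole table; significant at FDR < 0.05.
    """
    ids = list(modules.eigengenes.index)
    meta = samples.set_index("id").loc[ids]
    if ecotype_reference is None:
        ecotype_reference = "planktivorous" if "planktivorous" in set(meta["ecotype"]) \
            else sorted(meta["ecotype"].unique())[0]
    eco_code = (meta["ecotype"] != ecotype_reference).to_numpy(dtype=float)
    lake_dummies = pd.get_dummies(meta["lake"]).to_numpy(dtype=float)
    rows = []
    for module in modules.eigengenes.columns:
        eg = modules.eigengenes[module].to_numpy()
        r, p = stats.pearsonr(eg, eco_code)
        rows.append({"module": module, "variable": "ecotype", "r": r, "p": p})
        best = None
        for j in range(lake_dummies.shape[1]):
            rj, pj = stats.pearsonr(eg, lake_dummies[:, j])
            if best is None or abs(rj) > abs(best[0]):
                best = (rj, pj)
        rows.append({"module": module, "variable": "lake", "r": best[0], "p": best[1]})
    table = pd.DataFrame(rows)
    if not table.empty:
        table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["fdr"] < 0.05
    return table


def cis_eqtl(expr: ExpressionMatrix, genotypes, loci: pd.DataFrame,
             samples: pd.DataFrame, genes: pd.DataFrame | None = None,
             window: int = 1_000_000, fdr: float = 0.1) -> EqtlResult:
    """Additive-dosage cis-eQTL scan with lake and lineage covariates.

    For every (gene, SNP) pair on the same chromosome within ``window``
    bp, fits ``log2 expression ~ dosage + lake + lineage`` by OLS and
    t-tests the dosage coefficient.  Monomorphic SNPs are skipped.  BH
    correction spans all tested pairs.
    """
    genes = genes if genes is not None else expr.genes
    if genes is None:
        raise ValueError("gene positions required")
    from .popgen import GenotypeDataset
    if isinstance(genotypes, GenotypeDataset):
        dos_all = genotypes.dosages
        sample_ids = genotypes.sample_ids
    else:
        dos_all = np.asarray(genotypes, dtype=float)
        sample_ids = list(samples["id"])
    ids = [s for s in expr.log2.columns if s in set(sample_ids)]
    if np.isnan(dos_all).any():
        raise ValueError("genotypes must be imputed before eQTL mapping")
    row_of = {s: i for i, s in enumerate(sample_ids)}
    rows = [row_of[s] for s in ids]
    dos = dos_all[rows]
    meta = samples.set_index("id").loc[ids]
    covs = [np.ones((len(ids), 1))]
    for col in ("lake", "lineage"):
        if meta[col].nunique() > 1:
            covs.append(pd.get_dummies(meta[col], drop_first=True).to_numpy(dtype=float))
    C = np.hstack(covs)
    gene_pos = genes.set_index("gene") if "gene" in genes.columns else genes
    snp_chrom = loci["chrom"].to_numpy()
    snp_pos = loci["pos"].to_numpy()

    records = []
    expr_mat = expr.log2[ids]
    for gene in expr_mat.index:
        if gene not in gene_pos.index:
            continue
        gchrom = gene_pos.loc[gene, "chrom"]
        gpos = int(gene_pos.loc[gene, "pos"])
        near = np.where((snp_chrom == gchrom) & (np.abs(snp_pos - gpos) <= window))[0]
        if near.size == 0:
            continue
        y = expr_mat.loc[gene].to_numpy()
        for si in near:
            g = dos[:, si]
            if g.std() == 0:
                continue
            X = np.hstack([g[:, None], C])
            beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            df = len(y) - rank
            if df <= 0:
                continue
            sigma2 = float(resid @ resid) / df
            xtx_inv = np.linalg.pinv(X.T @ X)
            se = float(np.sqrt(max(sigma2 * xtx_inv[0, 0], 0.0)))
            if se == 0:
                continue
            tstat = beta[0] / se
            p = 2 * stats.t.sf(abs(tstat), df)
            records.append({"gene": gene, "snp": int(si),
                            "distance": int(abs(snp_pos[si] - gpos)),
                            "beta": float(beta[0]), "t": float(tstat), "p": float(p)})
    table = pd.DataFrame(records, columns=["gene", "snp", "distance", "beta", "t", "p"])
    if not table.empty:
        table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["fdr"] = pd.Series(dtype=float)
    return EqtlResult(table=table)
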
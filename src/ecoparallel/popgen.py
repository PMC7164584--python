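"""Genotype QC, Weir–Cockerham Fst scans, diversity, outliers, sharing,
LD decay and introgression statistics.

Per-locus differentiation uses the Weir & Cockerham (1984) theta-hat
estimator from the three variance components a (between populations),
b (between individuals within populations) and c (within individuals),
computed from genotype counts with the sample-size corrections and the
observed heterozygote frequencies.  The genome-wide estimate is the
ratio of sums, sum(a) / sum(a + b + c).

Outlier loci are flagged two ways: empirically (per-locus Fst strictly
above the 95th percentile of the scan) and against a permuted panmixia
null built by re-assigning ecotype labels to individuals within lakes
and pooling the per-locus Fst values over all permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GenotypeDataset:
    """Dosage matrix (individuals x loci, values 0/1/2/NaN) plus locus table."""

    dosages: np.ndarray
    loci: pd.DataFrame              # chrom, pos, contig (and any flags)
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError("dosage matrix shape does not match samples x loci")

    def subset_loci(self, keep: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(self.dosages[:, keep],
                               self.loci.iloc[np.asarray(keep)].reset_index(drop=True),
                               self.sample_ids)

    def row_indices(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in ids], dtype=int)


@dataclass
class FstScan:
    per_locus: np.ndarray            # WC theta-hat, NaN where undefined
    zfst: np.ndarray
    genome_wide: float               # ratio of sums
    components: tuple[np.ndarray, np.ndarray, np.ndarray]  # a, b, c
    empirical_outliers: np.ndarray | None = None    # bool
    permuted_outliers: np.ndarray | None = None
    permuted_q95: float | None = None
    zfst_significant: np.ndarray | None = None      # ZFst > 4
    zfst_reported: np.ndarray | None = None         # ZFst > 3

    def neutral_mask(self) -> np.ndarray:
        if self.empirical_outliers is None:
            raise ValueError("run outliers_empirical first")
        return ~self.empirical_outliers & np.isfinite(self.per_locus)


@dataclass
class DiversityResult:
    pi: dict                         # population label -> mean per-site pi
    per_site: dict                   # population label -> per-locus pi (NaN = skipped)

    def delta_pi(self, eco1: str, eco2: str) -> np.ndarray:
        """Per-locus pi_ecotype2 - pi_ecotype1 (derived minus reference)."""
        return self.per_site[eco2] - self.per_site[eco1]


@dataclass
class SharingResult:
    observed: int
    expected: float
    resample_sd: float
    p_value: float
    level: str
    n_resample: int
    universe_size: int
    chi2_p: float | None = None


@dataclass
class IntrogressionStats:
    statistic: str                   # "D" or "f3"
    value: float
    z: float
    n_blocks: int
    block_size: int


@dataclass
class LdResult:
    bins: pd.DataFrame               # bin_left, bin_right, mean_r2, median_r2, n_pairs
    focal: bool


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def _allele_freq(dosages: np.ndarray) -> np.ndarray:
    """Alternate-allele frequency per locus over non-missing genotypes."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(dosages, axis=0) / 2.0


def genotype_qc(dataset: GenotypeDataset, populations: pd.Series,
                per_pop_presence: float = 0.66, pop_fraction: float = 2 / 3,
                maf: float = 0.05, max_het: float = 0.5,
                hwe_alpha: float = 0.05, one_snp_per_locus: bool = True,
                ) -> tuple[GenotypeDataset, dict[str, int]]:
    """Apply the standard RAD-locus SNP filters, in order.

    1. presence: genotyped in >= ``per_pop_presence`` of individuals in at
       least ``pop_fraction`` of populations;
    2. global MAF >= ``maf``;
    3. observed heterozygosity <= ``max_het``;
    4. Hardy–Weinberg equilibrium (chi-square, P > ``hwe_alpha``) in at
       least ``pop_fraction`` of populations;
    5. one SNP per contig (the first by position).

    Returns the filtered dataset and the number of loci removed by each
    filter (applied sequentially).
    """
    X = dataset.dosages
    pops = pd.Series(np.asarray(populations, dtype=object))
    pop_groups = [np.where(pops.to_numpy() == p)[0] for p in pops.unique()]
    n_loci = X.shape[1]
    keep = np.ones(n_loci, dtype=bool)
    removed: dict[str, int] = {}

    present_ok = np.zeros(n_loci)
    for rows in pop_groups:
        frac = np.mean(~np.isnan(X[rows]), axis=0)
        present_ok += (frac >= per_pop_presence)
    step = present_ok >= pop_fraction * len(pop_groups)
    removed["presence"] = int((keep & ~step).sum())
    keep &= step

    p = _allele_freq(X)
    with np.errstate(invalid="ignore"):
        step = np.minimum(p, 1 - p) >= maf
    step &= np.isfinite(p)
    removed["maf"] = int((keep & ~step).sum())
    keep &= step

    with np.errstate(invalid="ignore"):
        het = np.nanmean(X == 1, axis=0)
    step = het <= max_het
    removed["heterozygosity"] = int((keep & ~step).sum())
    keep &= step

    hwe_ok = np.zeros(n_loci)
    for rows in pop_groups:
        sub = X[rows]
        n = np.sum(~np.isnan(sub), axis=0).astype(float)
        n_aa = np.nansum(sub == 0, axis=0)
        n_ab = np.nansum(sub == 1, axis=0)
        n_bb = np.nansum(sub == 2, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            q = (n_ab + 2 * n_bb) / (2 * n)
            exp_aa = n * (1 - q) ** 2
            exp_ab = n * 2 * q * (1 - q)
            exp_bb = n * q ** 2
            chi2 = np.zeros(n_loci)
            for obs, exp in ((n_aa, exp_aa), (n_ab, exp_ab), (n_bb, exp_bb)):
                valid = exp > 0
                chi2 = chi2 + np.where(valid, (obs - exp) ** 2 / np.where(valid, exp, 1.0), 0.0)
        pval = stats.chi2.sf(chi2, df=1)
        # monomorphic within the population: trivially in HWE
        mono = (q == 0) | (q == 1) | ~np.isfinite(q)
        hwe_ok += np.where(mono, True, pval > hwe_alpha)
    step = hwe_ok >= pop_fraction * len(pop_groups)
    removed["hwe"] = int((keep & ~step).sum())
    keep &= step

    if one_snp_per_locus and "contig" in dataset.loci.columns:
        first = ~dataset.loci["contig"].duplicated().to_numpy()
        removed["one_snp_per_locus"] = int((keep & ~first).sum())
        keep &= first
    else:
        removed["one_snp_per_locus"] = 0

    if not keep.any():
        exhausted = next((k for k, v in removed.items() if v > 0), "presence")
        raise ValueError(f"no loci survive QC (first exhausting filter: {exhausted})")
    return dataset.subset_loci(np.where(keep)[0]), removed


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst
# ---------------------------------------------------------------------------

def _wc_components(dosA: np.ndarray, dosB: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus WC (1984) variance components for two populations.

    Vectorised over loci; loci with < 2 genotyped individuals in either
    group yield NaN components.
    """
    comps = []
    ns, ps, hs = [], [], []
    for dos in (dosA, dosB):
        n = np.sum(~np.isnan(dos), axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(dos, axis=0) / (2 * n)
            h = np.nansum(dos == 1, axis=0) / n
        ns.append(n)
        ps.append(p)
        hs.append(h)
    n1, n2 = ns
    p1, p2 = ps
    h1, h2 = hs
    r = 2.0
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (1.0 / (nbar - 1)) *
                           (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                                   - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c = hbar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def wc_fst(dataset: GenotypeDataset, group_a, group_b) -> FstScan:
    """Per-locus and genome-wide Weir–Cockerham Fst between two groups.

    ``group_a`` / ``group_b`` are disjoint lists of sample ids.  Loci
    monomorphic across both groups get theta = NaN (no allelic variance);
    negative estimates at nearly-monomorphic loci are retained.
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValueError("groups overlap")
    rows_a = dataset.row_indices(group_a)
    rows_b = dataset.row_indices(group_b)
    a, b, c = _wc_components(dataset.dosages[rows_a], dataset.dosages[rows_b])
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)
    ok = np.isfinite(theta)
    gw = float(np.nansum(np.where(ok, a, 0.0)) / np.nansum(np.where(ok, denom, 0.0)))
    mu = np.nanmean(theta) if ok.any() else np.nan
    sd = np.nanstd(theta, ddof=1) if ok.sum() > 1 else np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (theta - mu) / sd if np.isfinite(sd) and sd > 0 else np.full_like(theta, np.nan)
    return FstScan(per_locus=theta, zfst=z, genome_wide=gw, components=(a, b, c))


def outliers_empirical(scan: FstScan, quantile: float = 0.95,
                       z_significant: float = 4.0, z_reported: float = 3.0) -> FstScan:
    """Flag loci strictly above the scan's 95th Fst percentile, plus ZFst tiers."""
    theta = scan.per_locus
    ok = np.isfinite(theta)
    if ok.sum() < 20:
        raise ValueError("need >= 20 informative loci for the empirical quantile")
    q = np.quantile(theta[ok], quantile)
    scan.empirical_outliers = ok & (theta > q)
    scan.zfst_significant = np.isfinite(scan.zfst) & (scan.zfst > z_significant)
    scan.zfst_reported = np.isfinite(scan.zfst) & (scan.zfst > z_reported)
    return scan


def outliers_permuted(dataset: GenotypeDataset, samples: pd.DataFrame,
                      lake: str, eco_a: str, eco_b: str,
                      n_perm: int = 1000, seed: int | None = None,
                      quantile: float = 0.95, pooled: bool = True,
                      scan: FstScan | None = None) -> FstScan:
    """Outliers against a permuted panmixia null for one sympatric pair.

    Ecotype labels are re-assigned at random among the individuals of the
    two ecotypes within the lake (sample sizes preserved); per-locus Fst
    from every permutation is pooled into one null distribution whose
    95th percentile is the outlier threshold.  ``pooled=False`` instead
    uses a per-locus null quantile.
    """
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    ids_a = samples.loc[(samples["lake"] == lake) & (samples["ecotype"] == eco_a), "id"]
    ids_b = samples.loc[(samples["lake"] == lake) & (samples["ecotype"] == eco_b), "id"]
    if scan is None:
        scan = wc_fst(dataset, list(ids_a), list(ids_b))
    rows = dataset.row_indices(list(ids_a) + list(ids_b))
    n_a = len(ids_a)
    X = dataset.dosages[rows]
    null = np.empty((n_perm, X.shape[1]))
    for k in range(n_perm):
        perm = rng.permutation(len(rows))
        a, b, c = _wc_components(X[perm[:n_a]], X[perm[n_a:]])
        with np.errstate(invalid="ignore", divide="ignore"):
            null[k] = np.where((a + b + c) != 0, a / (a + b + c), np.nan)
    theta = scan.per_locus
    if pooled:
        flat = null[np.isfinite(null)]
        q95 = float(np.quantile(flat, quantile))
        scan.permuted_outliers = np.isfinite(theta) & (theta > q95)
        scan.permuted_q95 = q95
    else:
        with np.errstate(invalid="ignore"):
            q_loc = np.nanquantile(null, quantile, axis=0)
        scan.permuted_outliers = np.isfinite(theta) & (theta > q_loc)
        scan.permuted_q95 = float(np.nanmean(q_loc))
    return scan


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def nucleotide_diversity(dataset: GenotypeDataset,
                         populations: dict[str, list]) -> DiversityResult:
    """Per-site nucleotide diversity pi = k(n-k)/C(n,2) over variant sites.

    ``n`` is the non-missing allele count and ``k`` the alternate allele
    count in the population; the population value is the mean over sites
    with n >= 2 (others skipped).
    """
    pi_mean: dict = {}
    per_site: dict = {}
    for label, ids in populations.items():
        rows = dataset.row_indices(ids)
        if len(rows) < 2:
            raise ValueError(f"population {label} needs >= 2 individuals")
        sub = dataset.dosages[rows]
        n = 2.0 * np.sum(~np.isnan(sub), axis=0)
        k = np.nansum(sub, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = np.where(n >= 2, k * (n - k) / (n * (n - 1) / 2.0), np.nan)
        per_site[label] = pi
        pi_mean[label] = float(np.nanmean(pi))
    return DiversityResult(pi=pi_mean, per_site=per_site)


# ---------------------------------------------------------------------------
# sharing
# ---------------------------------------------------------------------------

def sharing_test(set_a, set_b, universe, n_resample: int = 10000,
                 level: str = "SNP", seed: int | None = None) -> SharingResult:
    """Is the overlap of two feature sets larger than expected by chance?

    Expected sharing is estimated by drawing |A| and |B| features with
    replacement from the universe 10,000 times and intersecting the
    de-duplicated draws.  The p-value is a two-sample proportion test of
    observed vs expected shared counts against the universe size (as R's
    ``prop.test``, chi-square with continuity correction).
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty universe")
    if seed is None:
        raise ValueError("a seed is required")
    set_a, set_b = set(set_a), set(set_b)
    uni = set(universe)
    if not set_a <= uni or not set_b <= uni:
        raise ValueError("candidate sets must be subsets of the universe")
    observed = len(set_a & set_b)
    rng = np.random.default_rng(seed)
    u = len(universe)
    arr = np.asarray(universe, dtype=object)
    overlaps = np.empty(n_resample)
    for k in range(n_resample):
        ra = set(arr[rng.integers(0, u, size=len(set_a))]) if set_a else set()
        rb = set(arr[rng.integers(0, u, size=len(set_b))]) if set_b else set()
        overlaps[k] = len(ra & rb)
    expected = float(overlaps.mean())
    sd = float(overlaps.std(ddof=1)) if n_resample > 1 else 0.0
    p = _prop_test(observed, expected, u)
    return SharingResult(observed=observed, expected=expected, resample_sd=sd,
                         p_value=p, level=level, n_resample=n_resample,
                         universe_size=u)


def _prop_test(count_a: float, count_b: float, n: int) -> float:
    """Two-sample proportion chi-square test with Yates continuity correction.

    Mirrors R's prop.test(c(a, b), c(n, n)); a fractional expected count
    is accepted.  Returns 1.0 for two empty counts.
    """
    if count_a == 0 and count_b == 0:
        return 1.0
    p_pool = (count_a + count_b) / (2.0 * n)
    if p_pool in (0.0, 1.0):
        return 1.0
    diff = abs(count_a / n - count_b / n)
    correction = min(diff, 1.0 / n)  # Yates, capped so it cannot flip the sign
    se2 = p_pool * (1 - p_pool) * (2.0 / n)
    chi2 = (diff - correction) ** 2 / se2
    return float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def ld_decay(dataset: GenotypeDataset, max_dist: int = 1_000_000,
             n_bins: int = 20, focal: np.ndarray | None = None) -> LdResult:
    """Mean/median dosage r-squared binned by physical distance.

    Pairs are restricted to the same chromosome and separation
    <= ``max_dist``.  ``focal`` (a boolean locus mask) restricts pairs to
    (focal locus, any locus), giving LD decay around e.g. Fst outliers.
    Monomorphic or < 2 complete observations pairs are skipped.
    """
    X = dataset.dosages
    chrom = dataset.loci["chrom"].to_numpy()
    pos = dataset.loci["pos"].to_numpy()
    dists, r2s = [], []
    n_loci = X.shape[1]
    for i in range(n_loci):
        if focal is not None and not focal[i]:
            continue
        js = np.where((chrom == chrom[i]) & (np.abs(pos - pos[i]) <= max_dist)
                      & (np.arange(n_loci) > i if focal is None else np.arange(n_loci) != i))[0]
        for j in js:
            both = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
            if both.sum() < 3:
                continue
            xi, xj = X[both, i], X[both, j]
            if xi.std() == 0 or xj.std() == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            dists.append(abs(pos[j] - pos[i]))
            r2s.append(r * r)
    dists = np.asarray(dists, dtype=float)
    r2s = np.asarray(r2s)
    edges = np.linspace(0, max_dist, n_bins + 1)
    rows = []
    for k in range(n_bins):
        m = (dists >= edges[k]) & (dists < edges[k + 1] if k < n_bins - 1 else dists <= edges[k + 1])
        rows.append({"bin_left": edges[k], "bin_right": edges[k + 1],
                     "mean_r2": float(r2s[m].mean()) if m.any() else np.nan,
                     "median_r2": float(np.median(r2s[m])) if m.any() else np.nan,
                     "n_pairs": int(m.sum())})
    return LdResult(bins=pd.DataFrame(rows), focal=focal is not None)


# ---------------------------------------------------------------------------
# introgression
# ---------------------------------------------------------------------------

def _block_jackknife(num: np.ndarray, den: np.ndarray, block_size: int
                     ) -> tuple[float, float, int]:
    """Ratio-of-sums estimate with leave-one-block-out jackknife Z."""
    total = float(num.sum() / den.sum())
    n_loci = len(num)
    n_blocks = int(np.ceil(n_loci / block_size))
    if n_blocks < 5:
        logger.warning("only %d jackknife blocks (< 5); Z not estimated", n_blocks)
        return total, float("nan"), n_blocks
    est = np.empty(n_blocks)
    for b in range(n_blocks):
        sl = slice(b * block_size, min((b + 1) * block_size, n_loci))
        est[b] = (num.sum() - num[sl].sum()) / (den.sum() - den[sl].sum())
    var = (n_blocks - 1) / n_blocks * np.sum((est - est.mean()) ** 2)
    se = float(np.sqrt(var))
    z = total / se if se > 0 else np.inf * np.sign(total)
    return total, float(z), n_blocks


def patterson_d(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray,
                block_size: int = 200) -> IntrogressionStats:
    """ABBA–BABA D statistic from per-locus allele frequencies.

    D = sum(ABBA - BABA) / sum(ABBA + BABA) with
    ABBA = (1-p1) p2 p3 (1-p4), BABA = p1 (1-p2) p3 (1-p4); the Z score
    comes from a leave-one-block-out jackknife over contiguous blocks.
    """
    p1, p2, p3, p4 = (np.asarray(x, dtype=float) for x in (p1, p2, p3, p4))
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    num = abba - baba
    den = abba + baba
    if den.sum() == 0:
        raise ValueError("D undefined: no ABBA/BABA information")
    d, z, n_blocks = _block_jackknife(num, den, block_size)
    return IntrogressionStats(statistic="D", value=d, z=z,
                              n_blocks=n_blocks, block_size=block_size)


def f3_stat(a: np.ndarray, b: np.ndarray, c: np.ndarray, n_c: np.ndarray | int,
            block_size: int = 200, het_correction: bool = True) -> IntrogressionStats:
    """Three-population f3(C; A, B) with the within-C sampling-bias correction.

    f3 = mean over loci of (c-a)(c-b) - h_c / (2 n_c), where h_c is the
    unbiased heterozygosity estimate of the target C and n_c its diploid
    sample size.  A significantly negative value (Z <= -3) indicates that
    C is admixed between sources related to A and B.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    n_c = np.broadcast_to(np.asarray(n_c, dtype=float), c.shape)
    if het_correction and (n_c < 2).any():
        raise ValueError("need n_c >= 2 for the heterozygosity correction")
    num = (c - a) * (c - b)
    if het_correction:
        n_hap = 2.0 * n_c
        h_c = n_hap / (n_hap - 1.0) * 2.0 * c * (1.0 - c)
        num = num - h_c / n_hap
    den = np.ones_like(num)
    f3, z, n_blocks = _block_jackknife(num, den, block_size)
    return IntrogressionStats(statistic="f3", value=f3, z=z,
                              n_blocks=n_blocks, block_size=block_size)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_missing(dataset: GenotypeDataset, populations: pd.Series
                   ) -> tuple[GenotypeDataset, float]:
    """Replace missing dosages with the per-population mean dosage.

    Loci fully missing within a population fall back to the global mean
    (warning logged).  Returns the completed dataset and the Pearson
    correlation between per-population allele frequencies before and
    after imputation (1.0 when nothing was missing).
    """
    X = dataset.dosages.copy()
    pops = np.asarray(populations, dtype=object)
    pre_freqs, post_freqs = [], []
    fallback = 0
    global_mean = np.nanmean(X, axis=0)
    global_mean = np.where(np.isfinite(global_mean), global_mean, 1.0)
    for p in pd.unique(pops):
        rows = np.where(pops == p)[0]
        sub = X[rows]
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(sub, axis=0)
        missing_all = ~np.isfinite(mean)
        fallback += int(missing_all.sum())
        mean = np.where(missing_all, global_mean, mean)
        miss = np.isnan(sub)
        sub[miss] = np.broadcast_to(mean, sub.shape)[miss]
        X[rows] = sub
        pre = np.nanmean(dataset.dosages[rows], axis=0) / 2.0
        post = mean / 2.0
        ok = np.isfinite(pre)
        pre_freqs.append(pre[ok])
        post_freqs.append(post[ok])
    if fallback:
        logger.warning("%d locus/population cells fully missing; global mean used", fallback)
    pre = np.concatenate(pre_freqs)
    post = np.concatenate(post_freqs)
    if np.array_equal(dataset.dosages, X, equal_nan=True) or pre.std() == 0:
        corr = 1.0
    else:
        corr = float(np.corrcoef(pre, post)[0, 1])
    out = GenotypeDataset(X, dataset.loci, dataset.sample_ids)
    return out, corr
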
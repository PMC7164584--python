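"""Synthetic multi-lake, multi-lineage ecotype studies with planted ground truth.

The generator emulates the structure of a replicated lake-ecotype study:
two (or more) evolutionary lineages, several lakes per lineage, and two or
three sympatric trophic ecotypes per lake.  Every downstream analysis —
size correction, trajectory analysis, Fst scans, RDA, differential
expression, eQTL mapping, ecosystem-size integration — can therefore be
scored against known planted signals.

Model sketch
------------
* Genotypes: ancestral allele frequencies ~ Uniform(0.05, 0.95); each lake
  drifts from the ancestor under a Balding–Nichols model with parameter
  ``drift_F``; sympatric ecotypes share the lake frequency except at
  planted ecotype-associated SNPs, which are shifted by ``±assoc_delta/2``.
* Traits: allometric growth around the lineage mean fork length with a
  lineage-shared ecotype effect vector on the log10 scale, lake-specific
  rotation/length deviations scaled by ``lake_noise_scale``, and Gaussian
  residual noise.
* Expression: negative-binomial counts with ecotype log2 fold changes
  shared across lakes, plus an additive genotype term for planted eQTL.
* Ecosystem size: per-lake depth/area; when ``ecosystem_coupling`` > 0 the
  lake-specific rotation angle of the true ecotype effect vector tracks
  the lake's ecosystem-size PC1 score, planting a direction-of-divergence
  vs ecosystem-distance correlation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ECOTYPE_NAMES = ("planktivorous", "benthivorous", "piscivorous")
TRAIT_NAMES = ("HDE", "HDO", "HL", "PFL", "ED", "ML", "LJL")
#: baseline trait size as a fraction of fork length (head depths, head
#: length, pectoral fin, eye, maxilla, lower jaw — roughly salmonid-shaped)
_TRAIT_BASE_FRACTION = (0.14, 0.16, 0.24, 0.17, 0.05, 0.09, 0.10)


class ConfigError(ValueError):
    """Raised when a SynthConfig violates its invariants."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic study.

    Scales are on the log10 trait scale; ``assoc_delta`` is an allele
    frequency difference; ``de_log2fc`` a log2 expression fold change.
    """

    n_lineages: int = 2
    lakes_per_lineage: int = 3
    ecotypes_per_lake: int = 2
    n_per_group: int = 20
    n_traits: int = 7
    n_snps: int = 2000
    n_genes: int = 3000
    shared_effect_scale: float = 0.04
    lake_noise_scale: float = 0.3
    trait_noise_sd: float = 0.03
    allometry_slopes: tuple[float, ...] | None = None
    drift_F: float = 0.1
    n_assoc_snps: int = 20
    assoc_delta: float = 0.3
    n_de_genes: int = 100
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    n_eqtl: int = 10
    eqtl_beta: float = 1.0
    ecosystem_coupling: float = 0.5
    missing_rate: float = 0.05
    n_chromosomes: int = 10
    chrom_length: int = 25_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ecotypes_per_lake not in (2, 3):
            raise ConfigError("ecotypes_per_lake must be 2 or 3")
        for name in ("n_lineages", "lakes_per_lineage", "n_per_group",
                     "n_traits", "n_snps", "n_genes"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("shared_effect_scale", "lake_noise_scale",
                     "trait_noise_sd", "assoc_delta", "de_log2fc",
                     "nb_dispersion", "eqtl_beta"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 < self.drift_F < 1.0:
            raise ConfigError("drift_F must be in (0, 1)")
        if not 0.0 <= self.ecosystem_coupling <= 1.0:
            raise ConfigError("ecosystem_coupling must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.allometry_slopes is not None and len(self.allometry_slopes) != self.n_traits:
            raise ConfigError("allometry_slopes must have n_traits entries")

    def slopes(self) -> np.ndarray:
        if self.allometry_slopes is not None:
            return np.asarray(self.allometry_slopes, dtype=float)
        # mild allometry around isometry, deterministic per trait index
        return 1.0 + 0.1 * np.cos(np.arange(self.n_traits, dtype=float))


@dataclass
class StudyBundle:
    """The five linked tables of one study plus the planted truth record.

    Attributes
    ----------
    samples : DataFrame with id, lake, lineage, ecotype, fork_length (mm).
    traits : DataFrame (individuals x traits, mm), index = sample id.
    genotypes : float array (individuals x SNPs) with values {0,1,2, NaN}.
    loci : DataFrame (chrom, pos, contig, assoc flag), one row per SNP.
    counts : DataFrame (genes x individuals), non-negative integers.
    genes : DataFrame (chrom, pos, de flag, eqtl_snp_index or -1).
    environment : DataFrame (lake, max_depth_m, surface_area_km2).
    truth : dict of planted signals (effect vectors, flags, couplings).
    """

    samples: pd.DataFrame
    traits: pd.DataFrame
    genotypes: np.ndarray
    loci: pd.DataFrame
    counts: pd.DataFrame
    genes: pd.DataFrame
    environment: pd.DataFrame
    truth: dict
    config: SynthConfig

    @property
    def lakes(self) -> list[str]:
        return list(self.environment["lake"])


def _ecosystem_tables(rng: np.random.Generator, lakes: list[str]) -> tuple[pd.DataFrame, np.ndarray]:
    """Lake depth/area plus the standardized ecosystem-size PC1 scores."""
    n = len(lakes)
    latent = rng.normal(size=n)  # shared "lake size" factor
    log_depth = np.log10(30.0) + 0.45 * latent + 0.15 * rng.normal(size=n)
    log_area = np.log10(5.0) + 0.55 * latent + 0.15 * rng.normal(size=n)
    env = pd.DataFrame({
        "lake": lakes,
        "max_depth_m": np.round(10.0 ** log_depth, 2),
        "surface_area_km2": np.round(10.0 ** log_area, 3),
    })
    # internal PC1 of the standardized log variables, oriented larger = higher
    if n < 2:
        return env, np.zeros(n)
    x = np.column_stack([log_depth, log_area])
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    pc1 = x @ vt[0]
    if np.corrcoef(pc1, log_depth + log_area)[0, 1] < 0:
        pc1 = -pc1
    pc1 = (pc1 - pc1.mean()) / (pc1.std(ddof=1) if n > 1 else 1.0)
    return env, pc1


def _rotate_in_plane(v: np.ndarray, q: np.ndarray, angle: float) -> np.ndarray:
    """Rotate v by `angle` (radians) in the plane spanned by unit vectors v̂, q."""
    norm = np.linalg.norm(v)
    u = v / norm
    return norm * (np.cos(angle) * u + np.sin(angle) * q)


def simulate_study(config: SynthConfig) -> StudyBundle:
    """Generate one complete synthetic study.

    Deterministic: the same config (including seed) yields byte-identical
    tables.
    """
    rng = np.random.default_rng(config.seed)
    c = config

    lineages = [chr(ord("A") + i) for i in range(c.n_lineages)]
    lakes = [f"{lin}_lake{j + 1}" for lin in lineages for j in range(c.lakes_per_lineage)]
    lake_lineage = {lake: lake.split("_")[0] for lake in lakes}
    ecotypes = list(ECOTYPE_NAMES[: c.ecotypes_per_lake])

    env, eco_pc1 = _ecosystem_tables(rng, lakes)
    pc1_by_lake = dict(zip(lakes, eco_pc1))

    # ---- samples -------------------------------------------------------
    rows = []
    for lake in lakes:
        for eco in ecotypes:
            for k in range(c.n_per_group):
                rows.append({
                    "id": f"{lake}_{eco[:4]}_{k + 1:02d}",
                    "lake": lake,
                    "lineage": lake_lineage[lake],
                    "ecotype": eco,
                })
        # guard against duplicated ids (distinct eco prefixes by design)
    samples = pd.DataFrame(rows)
    n_ind = len(samples)

    # fork length: lineage-specific mean, lognormal individual variation
    lin_mean_fl = {lin: 180.0 + 15.0 * i for i, lin in enumerate(lineages)}
    log_fl = np.array([np.log10(lin_mean_fl[lin]) for lin in samples["lineage"]])
    log_fl = log_fl + rng.normal(0.0, 0.06, size=n_ind)
    samples["fork_length"] = 10.0 ** log_fl

    # ---- true ecotype effect vectors on log10 traits -------------------
    t = c.n_traits
    trait_names = list(TRAIT_NAMES[:t]) if t <= len(TRAIT_NAMES) else [
        f"T{i + 1}" for i in range(t)]
    shared_dirs: dict[str, np.ndarray] = {}
    ortho_dirs: dict[str, np.ndarray] = {}
    for eco in ecotypes[1:]:  # effects are relative to planktivorous
        u = rng.normal(size=t)
        u /= np.linalg.norm(u)
        q = rng.normal(size=t)
        q -= (q @ u) * u
        q /= np.linalg.norm(q)
        shared_dirs[eco] = u
        ortho_dirs[eco] = q

    w = c.ecosystem_coupling
    lake_angles = {}
    effect_vectors: dict[tuple[str, str], np.ndarray] = {}
    for lake in lakes:
        noise = rng.normal()
        angle = c.lake_noise_scale * (w * pc1_by_lake[lake] + np.sqrt(max(0.0, 1 - w ** 2)) * noise)
        lake_angles[lake] = angle
        for eco in ecotypes[1:]:
            v = c.shared_effect_scale * shared_dirs[eco]
            if c.shared_effect_scale > 0 and c.lake_noise_scale > 0:
                v = _rotate_in_plane(v, ortho_dirs[eco], angle)
                v = v * float(np.exp(c.lake_noise_scale * 0.5 * rng.normal()))
            effect_vectors[(lake, eco)] = v

    # ---- traits --------------------------------------------------------
    b = c.slopes()
    base = np.array(_TRAIT_BASE_FRACTION[:t]) if t <= 7 else np.full(t, 0.1)
    log_y_true = np.zeros((n_ind, t))
    for i, row in enumerate(samples.itertuples()):
        lm = lin_mean_fl[row.lineage]
        vec = np.zeros(t)
        if row.ecotype != ecotypes[0] and c.shared_effect_scale > 0:
            vec = effect_vectors[(row.lake, row.ecotype)]
        log_y_true[i] = np.log10(base * lm) + vec
    noise = rng.normal(0.0, c.trait_noise_sd, size=(n_ind, t))
    log_y = log_y_true + noise
    # invert the size correction: measured M grows allometrically with L
    log_lm = np.array([np.log10(lin_mean_fl[lin]) for lin in samples["lineage"]])
    log_m = log_y - b[None, :] * (log_lm[:, None] - log_fl[:, None])
    traits = pd.DataFrame(10.0 ** log_m, columns=trait_names, index=samples["id"].values)

    # ---- genotypes -----------------------------------------------------
    p_anc = rng.uniform(0.05, 0.95, size=c.n_snps)
    F = c.drift_F
    shape_a = p_anc * (1 - F) / F
    shape_b = (1 - p_anc) * (1 - F) / F
    lake_freq = {lake: rng.beta(shape_a, shape_b) for lake in lakes}

    n_assoc = min(c.n_assoc_snps, c.n_snps)
    assoc_idx = rng.choice(c.n_snps, size=n_assoc, replace=False) if n_assoc else np.array([], dtype=int)
    assoc_idx.sort()
    assoc_sign = rng.choice([-1.0, 1.0], size=n_assoc)
    # lake-specific shift pattern: the vector of per-SNP shifts rotates in
    # SNP space by the same lake angle that tilts the trait effect vector,
    # so the direction of adaptive allele-frequency divergence tracks
    # ecosystem size exactly as the phenotypic direction does
    lake_shift: dict[str, np.ndarray] = {}
    if n_assoc:
        u_g = assoc_sign / np.sqrt(n_assoc)
        q_raw = rng.normal(size=n_assoc)
        q_raw -= (q_raw @ u_g) * u_g
        q_g = q_raw / np.linalg.norm(q_raw) if n_assoc > 1 else u_g
        for lake in lakes:
            ang = lake_angles[lake]
            direction = np.cos(ang) * u_g + np.sin(ang) * q_g
            lake_shift[lake] = (c.assoc_delta / 2.0) * np.sqrt(n_assoc) * direction

    genotypes = np.empty((n_ind, c.n_snps))
    group_of = samples.groupby(["lake", "ecotype"]).indices
    for (lake, eco), idx in group_of.items():
        freq = lake_freq[lake].copy()
        if n_assoc:
            shift = lake_shift[lake]
            if eco == ecotypes[0]:
                freq[assoc_idx] = np.clip(freq[assoc_idx] - shift, 0.01, 0.99)
            else:
                freq[assoc_idx] = np.clip(freq[assoc_idx] + shift, 0.01, 0.99)
        genotypes[idx] = rng.binomial(2, freq[None, :], size=(len(idx), c.n_snps)).astype(float)
    complete_genotypes = genotypes.copy()
    if c.missing_rate > 0:
        mask = rng.random(genotypes.shape) < c.missing_rate
        genotypes[mask] = np.nan

    # loci: positions sorted within chromosomes; nearby SNPs share a contig
    chrom = rng.integers(1, c.n_chromosomes + 1, size=c.n_snps)
    pos = rng.integers(1, c.chrom_length + 1, size=c.n_snps)
    order = np.lexsort((pos, chrom))
    chrom, pos = chrom[order], pos[order]
    # deduplicate positions within chromosome
    for i in range(1, c.n_snps):
        if chrom[i] == chrom[i - 1] and pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    inv = np.empty(c.n_snps, dtype=int)
    inv[order] = np.arange(c.n_snps)  # loci row j corresponds to old column order[j]
    genotypes = genotypes[:, order]
    complete_genotypes = complete_genotypes[:, order]
    assoc_flag = np.zeros(c.n_snps, dtype=bool)
    assoc_flag[inv[assoc_idx]] = True
    loci = pd.DataFrame({
        "chrom": [f"chr{k}" for k in chrom],
        "pos": pos,
        "contig": [f"ctg{k}_{p // 5000}" for k, p in zip(chrom, pos)],
        "assoc": assoc_flag,
    })

    # ---- expression counts --------------------------------------------
    g = c.n_genes
    base_mean = 10.0 ** rng.normal(1.8, 0.7, size=g)  # per-gene baseline
    lib_factor = 10.0 ** rng.normal(0.0, 0.08, size=n_ind)

    n_de = min(c.n_de_genes, g)
    de_idx = rng.choice(g, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    de_idx.sort()
    de_sign = rng.choice([-1.0, 1.0], size=n_de)
    remaining = np.setdiff1d(np.arange(g), de_idx)
    n_eqtl = min(c.n_eqtl, len(remaining))
    eqtl_gene_idx = rng.choice(remaining, size=n_eqtl, replace=False) if n_eqtl else np.array([], dtype=int)
    eqtl_gene_idx.sort()
    eqtl_snp_idx = rng.choice(c.n_snps, size=n_eqtl, replace=False) if n_eqtl else np.array([], dtype=int)

    eco_is_derived = (samples["ecotype"] != ecotypes[0]).to_numpy(dtype=float)
    log2_mu = np.log2(base_mean)[:, None] + np.log2(lib_factor)[None, :]
    if n_de:
        log2_mu[de_idx] += (de_sign[:, None] * c.de_log2fc) * eco_is_derived[None, :]
    if n_eqtl:
        dos = complete_genotypes[:, eqtl_snp_idx].T  # n_eqtl x n_ind
        log2_mu[eqtl_gene_idx] += c.eqtl_beta * dos
    mu = 2.0 ** log2_mu
    if c.nb_dispersion > 0:
        lam = rng.gamma(1.0 / c.nb_dispersion, mu * c.nb_dispersion)
    else:
        lam = mu
    counts_arr = rng.poisson(lam)
    gene_ids = [f"gene{i + 1}" for i in range(g)]
    counts = pd.DataFrame(counts_arr, index=gene_ids, columns=samples["id"].values)

    gene_chrom = rng.integers(1, c.n_chromosomes + 1, size=g)
    gene_pos = rng.integers(1, c.chrom_length + 1, size=g)
    # plant eQTL genes within the cis window of their SNP
    for gi, si in zip(eqtl_gene_idx, eqtl_snp_idx):
        gene_chrom[gi] = int(loci["chrom"].iloc[si].removeprefix("chr"))
        offset = int(rng.integers(-500_000, 500_001))
        gene_pos[gi] = int(np.clip(loci["pos"].iloc[si] + offset, 1, c.chrom_length))
    de_flag = np.zeros(g, dtype=bool)
    de_flag[de_idx] = True
    eqtl_col = np.full(g, -1, dtype=int)
    eqtl_col[eqtl_gene_idx] = eqtl_snp_idx
    genes = pd.DataFrame({
        "gene": gene_ids,
        "chrom": [f"chr{k}" for k in gene_chrom],
        "pos": gene_pos,
        "de": de_flag,
        "eqtl_snp_index": eqtl_col,
    })

    truth = {
        "effect_vectors": {f"{lake}|{eco}": v.tolist() for (lake, eco), v in effect_vectors.items()},
        "shared_directions": {eco: u.tolist() for eco, u in shared_dirs.items()},
        "lake_rotation_angles": lake_angles,
        "ecosystem_pc1": {lake: float(s) for lake, s in pc1_by_lake.items()},
        "assoc_snp_indices": inv[assoc_idx].tolist(),
        "de_gene_indices": de_idx.tolist(),
        "de_gene_ids": [gene_ids[i] for i in de_idx],
        "eqtl_pairs": [(gene_ids[gi], int(si)) for gi, si in zip(eqtl_gene_idx, eqtl_snp_idx)],
        "allometry_slopes": b.tolist(),
        "lineage_mean_fork_length": lin_mean_fl,
    }
    return StudyBundle(samples=samples, traits=traits, genotypes=genotypes,
                       loci=loci, counts=counts, genes=genes,
                       environment=env, truth=truth, config=c)


def truth_report(bundle: StudyBundle) -> pd.DataFrame:
    """Flat table of all planted signals, for recall/precision scoring.

    One row per planted feature: assoc SNPs (by locus row index), DE genes
    and eQTL gene–SNP pairs.
    """
    rows = []
    for i in bundle.truth["assoc_snp_indices"]:
        rows.append({"signal": "assoc_snp", "feature": int(i), "partner": ""})
    for gid in bundle.truth["de_gene_ids"]:
        rows.append({"signal": "de_gene", "feature": gid, "partner": ""})
    for gid, si in bundle.truth["eqtl_pairs"]:
        rows.append({"signal": "eqtl", "feature": gid, "partner": int(si)})
    return pd.DataFrame(rows, columns=["signal", "feature", "partner"])


def sympatric_pairs(bundle: StudyBundle) -> list[tuple[str, str, str]]:
    """All (lake, planktivorous, derived-ecotype) pairs present in the study.

    The orientation convention is planktivorous -> derived ecotype so that
    divergence vectors are comparable across lakes.
    """
    pairs = []
    for lake, sub in bundle.samples.groupby("lake", sort=False):
        ecos = [e for e in ECOTYPE_NAMES if e in set(sub["ecotype"])]
        ref = ecos[0]
        for other in ecos[1:]:
            pairs.append((lake, ref, other))
    return pairs
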
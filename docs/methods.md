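# Methods

This note documents the statistical machinery implemented in
`ecoparallel`, the assumptions behind the synthetic-study generator, and
the numerical and design choices made where the method description left
room for interpretation.

## Study design and orientation conventions

The unit of replication is the *sympatric ecotype pair*: two (or three)
trophic ecotypes coexisting in one lake, replicated over lakes and over
evolutionary lineages. All divergence vectors are oriented from the
planktivorous ecotype to the derived (benthivorous or piscivorous)
ecotype, so angles and signed quantities (Δπ, log2 fold changes,
module–trait correlations) are comparable across pairs. Comparisons
between two pairs of the *same* ecotype contrast (e.g.
benthivorous–planktivorous in two lakes) are "replicated"; contrasts of
different types are "non-replicated".

## Trait size correction

Linear traits scale allometrically with body size, so raw values are
standardised to the lineage mean fork length `Lm`:

    log10 Y_i = log10 M_i + b * (log10 Lm − log10 L_i)

`b` is estimated per trait, per lineage, by OLS of `log10 M` on
`log10 L` with population (lake) and ecotype as additive categorical
covariates — a common-slope ANCOVA. The method text can also be read as
fitting `b` separately within each lake-and-ecotype group; the covariate
reading was adopted because it is the stated estimation procedure and is
far more stable in small groups. The correction is exactly invertible:
on noise-free synthetic data with additive effects the generating slope
is recovered to machine precision and re-correcting corrected traits
yields `b ≈ 0` (tested).

Non-positive measurements are rejected (set missing) with a logged
warning; groups with fewer than three individuals are refused.

## Variance partitioning (partial η²)

Each trait or PC score is fit by OLS to
`ecotype + lake + lineage + ecotype:lake + ecotype:lineage` and each
term's partial effect size is `η² = SS_term / (SS_term + SS_residual)`
with Type-II sums of squares (robust to the unbalanced lake sizes that
are the norm in such designs). A response is "parallel-dominant" when
the ecotype η² exceeds both interaction η². Lakes are nested in
lineages, so single-level factors are dropped with a note and the
rank-deficient lineage contrast is absorbed by the lake dummies. Sums
of squares below 1e-12 of the total are floored to zero so that exact
fits do not produce spurious effect-size ratios from numerical dust.

## Trajectory analysis

Trajectories are two-point (all comparisons here are two-ecotype
pairs), so direction reduces to the centroid-difference vector `v` in
the retained score space (the smallest number of leading PCs whose
cumulative explained variance exceeds one half, `k50`; or all columns
of a raw matrix). θ is reported in degrees in [0, 180]; pairs with
identical centroids have undefined direction and are recorded as
missing, never as zero.

**Significance.** For each pair-of-pairs comparison, ecotype labels are
permuted independently within each of the two lakes (sample sizes
preserved) and (θ, ΔL) recomputed; `p = (1 + #{perm ≥ obs}) / (n_perm + 1)`.
This label scheme was chosen over residual randomisation under the
reduced (common-trajectory) model after the latter proved structurally
miscalibrated for a two-pair comparison: the reduced-model constraint
makes the two observed deviation-from-common-trajectory vectors exactly
anticorrelated while permuted ones are independent, so null p-values
for θ are far from uniform. Within-lake label permutation is exactly
valid under the no-ecotype-effect null (the same exchangeability
argument as the panmixia Fst null) and passes a KS uniformity check
across 200 simulated null studies. Its trade-off is conservatism when a
strong shared ecotype effect exists but directions differ only
moderately — permuted vectors then concentrate along the shared axis —
which errs toward calling such pairs "parallel". The minimum attainable
p, `1/(n_perm+1)`, is reached by the ΔL statistic on extreme planted
length contrasts; for θ the permutation geometry keeps a ~2% floor on
antiparallel signals regardless of noise level.

## Weir–Cockerham Fst and outlier scans

Per-locus differentiation is the Weir & Cockerham (1984) θ̂ from
variance components a/b/c computed from genotype counts with observed
heterozygote frequencies and sample-size corrections; the genome-wide
value is Σa / Σ(a+b+c). Negative per-locus estimates are retained —
clipping would bias the scan mean, the 95th percentile and ZFst.

Outliers are flagged two ways: (i) empirically, per-locus Fst strictly
above the scan's 95th percentile (the complement is the "neutral" locus
mask used for neutral trajectories and neutral Fst); ZFst > 4 is
additionally flagged "significant" and ZFst > 3 "reported"; and (ii)
against a permuted panmixia null: ecotype labels reassigned among the
individuals of the pair within the lake, per-locus Fst pooled over all
permutations into a single null distribution whose 95th percentile is
the threshold (a per-locus null is available behind a flag). On null
data the permuted rule flags ~5% of loci; when modest true
differentiation inflates the empirical quantile, the permuted rule
flags at least as many loci as the empirical rule (tested).

Nucleotide diversity is per-site `π = k(n−k)/C(n,2)` over non-missing
allele counts, averaged over sites; D and f3 use ratio-of-sums /
mean-with-bias-correction estimates with leave-one-block-out jackknife
Z scores (default block 200 loci; with fewer than five blocks the point
estimate is returned with Z = NaN).

The sharing test draws |A| and |B| features with replacement from the
universe, de-duplicates, intersects (10,000 resamples), and compares
observed to expected shared counts with a two-sample proportion
chi-square test with continuity correction (as R's `prop.test`); the
2×2 candidate/non-candidate chi-square accompanies the cross-lineage
comparison and is the decisive test when expected overlaps are
fractional.

## Partial RDA

Response and the numeric ecotype predictor are residualised on the
condition dummies (lake, plus lineage for expression); the residual
response is regressed on the residual predictor; constrained axes are
the principal axes of the fitted values; feature loadings are
z-standardised per axis and |z| > 2 defines candidates. Significance is
a permutation pseudo-F with rows of the residualised predictor
permuted. Two ecotypes are coded 0/1 (one constrained axis). Three
ecotypes use two indicator contrasts (benthivorous-vs-rest,
piscivorous-vs-rest): a single ordinal 0/1/2 predictor can yield only
one constrained axis, while the two-contrast coding reproduces the
RDA1 + RDA2 geometry in which RDA1 separates benthivorous from
planktivorous and RDA2 isolates the piscivorous ecotype. Genotypes are
mean-imputed per population before RDA (a deliberately simple,
documented replacement for LD-informed imputation) and centred but not
variance-standardised (dosages share a scale).

## Expression

Counts are filtered (≥ 20 reads per lake in every lake), normalised by
median-of-ratios size factors (rescaled to geometric mean one) and
log2(x+1)-transformed. This transform, and the per-gene Welch t-test
with per-lake BH correction used for differential expression, are
deliberately simple, self-contained stand-ins for heavier count-model
machinery; their calibration (null FDR) and power (≥ 70% recall at
log2FC = 2 with 4 + 4 samples) are verified by simulation rather than
assumed. The ecotype variance filter fits `expression ~ lake + ecotype`
per gene and keeps genes whose ecotype term (fitted after lake) exceeds
10% of total variance.

Co-expression modules: adjacency `|r|^6` between gene profiles,
dissimilarity `1 − adjacency`, average-linkage clustering with a static
cut at 0.992, minimum module size 25, and iterative merging of modules
whose eigengenes (first PC of member expression, sign-oriented to a
positive mean loading) are closer than 0.25 in correlation distance.
The printed numeric parameters are kept even though the topology
measure (plain correlation adjacency, static cut) is simpler than a
TOM + dynamic-cut pipeline; unsigned networks and soft power 6 are
assumed. Labels are ordered by module size, making the partition
deterministic and input-order invariant.

cis-eQTL: every (gene, SNP) pair within 1 Mb (gene anchored at its
annotated start) is fit by OLS of normalised expression on additive
dosage with lake and lineage dummies; the dosage coefficient is
t-tested, BH-corrected across all tested pairs, with significant sets
at FDR 0.1 (primary) and 0.05.

## Integration layer

Ecosystem size is PC1 of log10 lake depth and log10 surface area
(z-standardised; both span orders of magnitude), oriented so larger
lakes score higher; pairwise ecosystem distance is |PC1_i − PC1_j|,
lifted to ecotype pairs via their lakes. Mantel tests use Pearson r
over lower-triangle entries with object-label permutation and a
one-sided (positive association) p by default, 999 permutations
(two-sided available). The report assembles twelve pre-registered rows
— four Mantel tests among divergence matrices, three regressions
(neutral Fst ~ trajectory length; π and mean within-lake trait variance
~ ecosystem PC1) and five Mantel tests against ecosystem distance —
reporting "not computed" (never silently dropping) when an input is
missing or degenerate. "Mean trait variance" is the mean over traits of
the within-lake variance of size-corrected values.

## Synthetic-study generator

The generator emulates the *structure* of a two-lineage, multi-lake,
replicated-ecotype study; its defaults are the package's study
conditions.

- **Genotypes.** Ancestral frequencies ~ Uniform(0.05, 0.95); each lake
  drifts under a Balding–Nichols model (Beta with parameter `drift_F`,
  default 0.1); sympatric ecotypes share the lake frequency except at
  `n_assoc_snps` planted SNPs shifted ±`assoc_delta`/2 (clipped to
  [0.01, 0.99]); genotypes are binomial draws; 5% missingness
  completely at random.
- **Traits.** Seven linear traits as fractions of fork length on the
  log10 scale, mild allometry (`b` ≈ 0.9–1.1 per trait), a
  lineage-shared ecotype effect vector (norm 0.04 log10 units), a
  lake-specific rotation of that vector plus lognormal length jitter
  scaled by `lake_noise_scale` (0.3; zero means perfect parallelism),
  and Gaussian residual noise (sd 0.03 log10 units — chosen so the
  trait PCA has a realistically diffuse spectrum needing ~3 PCs for
  50%, rather than a single dominant axis). The Gaussian residual model
  is an assumption of the generator, not a claim about real trait noise.
- **Ecosystem coupling.** Lake depth/area are lognormal around a shared
  latent size factor; the lake-specific rotation angle is
  `lake_noise_scale · (w·PC1 + sqrt(1−w²)·ε)` with `w =
  ecosystem_coupling` (default 0.5), and the *same* angle rotates the
  vector of per-SNP association shifts in SNP space — so both the
  phenotypic and the adaptive-genetic divergence directions track
  ecosystem size, which is the planted analogue of the observed
  direction-vs-ecosystem correlations.
- **Expression.** Negative-binomial counts (gamma–Poisson, dispersion
  α = 0.05 so var ≈ μ + αμ²), lognormal gene base means and library
  size factors, `n_de_genes` with ecotype log2 fold change ±2 shared
  across lakes, and `n_eqtl` genes (disjoint from DE genes) with an
  additive `eqtl_beta` log2 effect of a genotype placed within 500 kb.

What the generator does *not* emulate: linkage between SNPs (loci are
independent given lake frequencies), sequence-level artefacts (no
reads, coverage or genotyping error beyond MCAR missingness), selection
acting on standing haplotypes, trans-eQTL, and correlated residual
structure among traits. Passing recovery tests therefore demonstrates
that the estimators are correct and calibrated under the stated
generative model — not that real charr data would yield the same power.

## Problem sizes and determinism

The demo study used throughout (and by `scripts/acceptance.py`) is
2 lineages × 3 lakes × 2 ecotypes × 20 fish, 2,000 SNPs and 3,000
genes, with 199–999 permutations per test and 1,000 permutations for
the panmixia null — sizes chosen to exercise every stage at interactive
runtimes on a single CPU. Every stochastic stage draws its seed
deterministically from the global seed and the stage name
(`seed·1000003 + crc32(stage) mod 2³¹`), and a rerun with the same
configuration is byte-identical (verified via SHA-256 manifest hashes).

## Known limitations

- The trajectory permutation test is conservative for moderate
  direction differences in the presence of a strong shared effect (see
  above).
- The HWE filter uses a 1-df chi-square rather than an exact test;
  behaviour at the stated α differs only for rare alleles.
- With strongly parallel planted signals, PCA-based score spaces can
  retain a single component (`k50 = 1`), making angles degenerate
  (0°/180°); downstream Mantel rows then report "not computed" rather
  than a sham correlation.
- D and f3 use allele frequencies, not genotype likelihoods; no
  correction for unequal sample sizes across loci beyond the f3 target
  bias term.
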
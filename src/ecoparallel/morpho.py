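"""Allometric size correction, PCA and variance partitioning of linear traits.

Linear morphological traits scale with body size, so between-ecotype
comparisons require standardisation to a common fork length.  The
correction is the classic allometric rescaling

    log10 Y_i = log10 M_i + b * (log10 Lm - log10 L_i)

where ``M_i`` is the measured trait, ``L_i`` the individual's fork length,
``Lm`` the lineage mean fork length and ``b`` the common allometric slope
estimated by ANCOVA of log10 M on log10 L with population (lake) and
ecotype as additive covariates, fitted within each lineage.

Variance partitioning fits, per trait or PC score,

    response ~ ecotype + lake + lineage + ecotype:lake + ecotype:lineage

and reports the partial eta-squared of each term (Type-II sums of
squares), separating parallel (ecotype) from non-parallel (interaction)
divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

logger = logging.getLogger(__name__)

ETA2_TERMS = ("ecotype", "lake", "lineage", "ecotype:lake", "ecotype:lineage")


@dataclass
class CorrectedTraits:
    """Size-adjusted trait values with the regression machinery that made them."""

    Y: pd.DataFrame            # corrected values, mm, same shape as M
    b: pd.DataFrame            # per (lineage, trait) allometric slope
    Lm: dict                   # lineage -> mean fork length (mm)
    M: pd.DataFrame            # raw measured values, mm
    L: pd.Series               # fork length per individual, mm


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame     # variables x components
    explained_fraction: np.ndarray
    k50: int
    mean: np.ndarray
    scale: np.ndarray | None = None

    def retained_scores(self) -> pd.DataFrame:
        """Scores on the first k50 components (cumulative variance > 50%)."""
        return self.scores.iloc[:, : self.k50]


@dataclass
class TraitModelResult:
    response: str
    eta2: dict[str, float]
    pvalues: dict[str, float]
    label: str                 # "parallel-dominant" or "non-parallel"
    dropped_terms: list[str]


def size_correct_traits(traits: pd.DataFrame, fork_length: pd.Series,
                        population: pd.Series, ecotype: pd.Series,
                        lineage: pd.Series,
                        min_group_size: int = 3) -> CorrectedTraits:
    """Allometrically standardise traits to the lineage mean fork length.

    Parameters
    ----------
    traits : raw measurements (mm), individuals x traits.
    fork_length : fork length per individual (mm), same index.
    population, ecotype : lake and ecotype label per individual; both
        enter the slope ANCOVA as additive covariates (common slope).
    lineage : lineage label; ``b`` is fitted and ``Lm`` computed per
        lineage.

    Non-positive measurements are rejected (set missing) with a logged
    warning; a (population, ecotype) group smaller than
    ``min_group_size`` raises.
    """
    traits = traits.astype(float).copy()
    fl = pd.Series(np.asarray(fork_length, dtype=float), index=traits.index)
    if (fl <= 0).any():
        raise ValueError("fork lengths must be positive")
    bad = traits <= 0
    if bad.to_numpy().any():
        logger.warning("rejecting %d non-positive trait measurements",
                       int(bad.to_numpy().sum()))
        traits = traits.mask(bad)
    pop = pd.Series(np.asarray(population, dtype=object), index=traits.index)
    eco = pd.Series(np.asarray(ecotype, dtype=object), index=traits.index)
    lin = pd.Series(np.asarray(lineage, dtype=object), index=traits.index)
    sizes = traits.groupby([pop, eco]).size()
    if (sizes < min_group_size).any():
        small = list(sizes[sizes < min_group_size].index)
        raise ValueError(f"groups with < {min_group_size} individuals: {small}")

    log_l = np.log10(fl)
    corrected = pd.DataFrame(index=traits.index, columns=traits.columns, dtype=float)
    slope_rows = []
    lm_by_lineage: dict = {}
    for lineage_name in pd.unique(lin):
        sel = lin == lineage_name
        lm = float(fl[sel].mean())
        lm_by_lineage[lineage_name] = lm
        for trait in traits.columns:
            sub = pd.DataFrame({
                "logM": np.log10(traits.loc[sel, trait]),
                "logL": log_l[sel],
                "pop": pop[sel],
                "eco": eco[sel],
            }).dropna()
            terms = ["logL"]
            if sub["pop"].nunique() > 1:
                terms.append("C(pop)")
            if sub["eco"].nunique() > 1:
                terms.append("C(eco)")
            fit = smf.ols(f"logM ~ {' + '.join(terms)}", data=sub).fit()
            b = float(fit.params["logL"])
            slope_rows.append({"lineage": lineage_name, "trait": trait, "b": b})
            log_y = np.log10(traits.loc[sel, trait]) + b * (np.log10(lm) - log_l[sel])
            corrected.loc[sel, trait] = 10.0 ** log_y
    slopes = pd.DataFrame(slope_rows)
    return CorrectedTraits(Y=corrected, b=slopes, Lm=lm_by_lineage, M=traits, L=fl)


def pca(matrix: pd.DataFrame, center: bool = True, scale: bool = False,
        impute_missing: bool = False) -> PcaResult:
    """Principal component analysis via SVD with a fixed sign convention.

    The sign of each component is chosen so its largest-magnitude loading
    is positive, making results deterministic.  ``k50`` is the smallest
    number of leading components whose cumulative explained variance
    exceeds one half.

    Missing values are column-mean imputed when ``impute_missing`` is
    set (count logged); otherwise they raise.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    if np.isnan(X).any():
        if not impute_missing:
            raise ValueError("missing values present; set impute_missing=True")
        n_miss = int(np.isnan(X).sum())
        logger.info("mean-imputing %d missing values before PCA", n_miss)
        col_mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = col_mean[idx[1]]
    mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mean
    sd = None
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        zero = np.where(sd == 0)[0]
        if zero.size:
            names = [str(matrix.columns[i]) for i in zero] if hasattr(matrix, "columns") else list(zero)
            raise ValueError(f"constant columns cannot be scaled: {names}")
        Xc = Xc / sd
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| positive per component
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    var = s ** 2
    explained = var / var.sum() if var.sum() > 0 else var
    k50 = int(np.searchsorted(np.cumsum(explained), 0.5, side="right") + 1)
    k50 = min(k50, len(explained))
    comp_names = [f"PC{j + 1}" for j in range(len(s))]
    index = matrix.index if hasattr(matrix, "index") else pd.RangeIndex(X.shape[0])
    columns = matrix.columns if hasattr(matrix, "columns") else pd.RangeIndex(X.shape[1])
    scores = pd.DataFrame(u * s, index=index, columns=comp_names)
    loadings = pd.DataFrame(vt.T, index=columns, columns=comp_names)
    return PcaResult(scores=scores, loadings=loadings, explained_fraction=explained,
                     k50=k50, mean=mean, scale=sd)


def _buildable_terms(samples: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Model terms that are estimable in this design, and those dropped.

    A lake is always nested in exactly one lineage here, so with >1
    lineage the lake dummies span the lineage contrast; statsmodels
    handles the resulting rank deficiency, but a single-level factor is
    genuinely aliased and is dropped with a note.
    """
    kept, dropped = [], []
    n_eco = samples["ecotype"].nunique()
    n_lake = samples["lake"].nunique()
    n_lin = samples["lineage"].nunique()
    if n_eco > 1:
        kept.append("ecotype")
    else:
        dropped.append("ecotype")
    if n_lake > 1:
        kept.append("lake")
    else:
        dropped.append("lake")
    if n_lin > 1:
        kept.append("lineage")
    else:
        dropped.append("lineage")
    if n_eco > 1 and n_lake > 1:
        kept.append("ecotype:lake")
    else:
        dropped.append("ecotype:lake")
    if n_eco > 1 and n_lin > 1:
        kept.append("ecotype:lineage")
    else:
        dropped.append("ecotype:lineage")
    return kept, dropped


def trait_anova_eta2(response: pd.Series, samples: pd.DataFrame,
                     name: str | None = None) -> TraitModelResult:
    """Partition one response into parallel and non-parallel components.

    Fits ``response ~ ecotype + lake + lineage + ecotype:lake +
    ecotype:lineage`` by OLS and reports partial eta-squared
    ``SS_term / (SS_term + SS_residual)`` with Type-II sums of squares.

    The response is labelled "parallel-dominant" when the ecotype effect
    size exceeds both interaction effect sizes.
    """
    name = name or (response.name if response.name is not None else "response")
    kept, dropped = _buildable_terms(samples)
    if "ecotype" not in kept:
        raise ValueError("need >= 2 ecotypes")
    if "lake" not in kept:
        raise ValueError("need >= 2 lakes")
    if dropped:
        logger.info("dropping aliased/degenerate terms: %s", dropped)
    df = samples[["ecotype", "lake", "lineage"]].copy()
    df["y"] = np.asarray(response, dtype=float)
    formula_terms = {
        "ecotype": "C(ecotype)",
        "lake": "C(lake)",
        "lineage": "C(lineage)",
        "ecotype:lake": "C(ecotype):C(lake)",
        "ecotype:lineage": "C(ecotype):C(lineage)",
    }
    formula = "y ~ " + " + ".join(formula_terms[t] for t in kept)
    fit = smf.ols(formula, data=df).fit()
    table = anova_lm(fit, typ=2)
    # floor numerically-zero sums of squares (exact fits leave ~1e-29 dust)
    ss_floor = 1e-12 * float(np.var(df["y"]) * len(df)) if np.var(df["y"]) > 0 else 0.0
    ss_res = float(table.loc["Residual", "sum_sq"])
    if ss_res < ss_floor:
        ss_res = 0.0
    eta2: dict[str, float] = {}
    pvalues: dict[str, float] = {}
    for term in kept:
        row = formula_terms[term]
        if row not in table.index:
            dropped.append(term)
            continue
        ss = float(table.loc[row, "sum_sq"])
        if not np.isfinite(ss) or ss < ss_floor:
            ss = 0.0
        eta2[term] = ss / (ss + ss_res) if (ss + ss_res) > 0 else 0.0
        pvalues[term] = float(table.loc[row, "PR(>F)"])
    e = eta2.get("ecotype", 0.0)
    label = "parallel-dominant" if (e > eta2.get("ecotype:lake", 0.0)
                                    and e > eta2.get("ecotype:lineage", 0.0)) else "non-parallel"
    return TraitModelResult(response=str(name), eta2=eta2, pvalues=pvalues,
                            label=label, dropped_terms=dropped)


def eta2_table(responses: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """trait_anova_eta2 over every column; tidy long-format table."""
    rows = []
    for col in responses.columns:
        res = trait_anova_eta2(responses[col], samples, name=col)
        for term, value in res.eta2.items():
            rows.append({"response": col, "term": term, "eta2": value,
                         "p": res.pvalues[term], "label": res.label})
    return pd.DataFrame(rows)
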
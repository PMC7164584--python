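"""Partial redundancy analysis (RDA) for ecotype-association scans.

Associates a multivariate response (SNP dosages or normalised
expression) with ecotype while conditioning on lake (and lineage):

1. response and ecotype predictor are residualised on the condition
   dummies;
2. the residual response is regressed on the residual predictor by least
   squares;
3. the constrained axes are the principal axes of the fitted values;
   feature loadings on those axes are z-standardised per axis and
   features with |z| > 2 are candidates;
4. significance comes from a permutation pseudo-F test (rows of the
   residualised predictor permuted).

Two-ecotype designs use the numeric 0/1 coding (one constrained axis);
three-ecotype designs use two indicator contrasts (benthivorous-vs-rest,
piscivorous-vs-rest) giving the RDA1 + RDA2 geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import SharingResult, sharing_test

logger = logging.getLogger(__name__)


@dataclass
class RdaResult:
    loadings: pd.DataFrame          # features x constrained axes
    z: pd.DataFrame                 # z-standardised loadings
    candidates: list                # feature ids with |z| > 2 on any axis
    explained_fraction: float       # constrained / total (after conditioning)
    pseudo_f: float
    p_value: float
    n_perm: int
    seed: int | None
    axis_explained: np.ndarray | None = None
    dropped_features: list | None = None


def _condition_dummies(condition: pd.DataFrame) -> np.ndarray:
    """Full-rank dummy matrix (with intercept) for the condition factors."""
    mats = [np.ones((len(condition), 1))]
    for col in condition.columns:
        d = pd.get_dummies(condition[col], drop_first=True).to_numpy(dtype=float)
        mats.append(d)
    return np.hstack(mats)


def _residualize(Y: np.ndarray, C: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(C, Y, rcond=None)
    return Y - C @ beta


def partial_rda(response: pd.DataFrame, ecotype: pd.Series,
                condition: pd.DataFrame, n_perm: int = 999,
                seed: int | None = None, z_threshold: float = 2.0) -> RdaResult:
    """Constrained ordination of ``response`` on ecotype given conditions.

    Parameters
    ----------
    response : samples x features matrix (dosages or normalised
        expression); centred internally.  Constant features are dropped
        with a warning.
    ecotype : ecotype label or numeric code per sample.  Two levels are
        coded 0/1; three levels become two indicator contrasts.
    condition : DataFrame of categorical condition factors (lake, and
        optionally lineage) to be partialled out.
    """
    if seed is None:
        raise ValueError("a seed is required")
    Y = np.asarray(response, dtype=float)
    n, m = Y.shape
    feat_ids = list(response.columns)
    keep = Y.std(axis=0) > 0
    dropped = [f for f, k in zip(feat_ids, keep) if not k]
    if dropped:
        logger.warning("dropping %d constant features", len(dropped))
        Y = Y[:, keep]
        feat_ids = [f for f, k in zip(feat_ids, keep) if k]
    Y = Y - Y.mean(axis=0)

    eco = pd.Series(np.asarray(ecotype), index=response.index)
    levels = pd.unique(eco)
    if len(levels) == 2:
        codes = np.asarray(eco == levels[1], dtype=float)[:, None]
        axis_names = ["RDA1"]
    elif len(levels) == 3:
        codes = np.column_stack([
            np.asarray(eco == levels[1], dtype=float),
            np.asarray(eco == levels[2], dtype=float),
        ])
        axis_names = ["RDA1", "RDA2"]
    else:
        raise ValueError("ecotype must have 2 or 3 levels")

    C = _condition_dummies(condition)
    if n < C.shape[1] + codes.shape[1] + 2:
        raise ValueError("too few samples for the conditioned model")
    Yr = _residualize(Y, C)
    Xr = _residualize(codes, C)
    if np.allclose(Xr.std(axis=0), 0):
        raise ValueError("ecotype is constant within condition strata")

    def constrained(Yr, Xr):
        beta, *_ = np.linalg.lstsq(Xr, Yr, rcond=None)
        fitted = Xr @ beta
        return fitted

    fitted = constrained(Yr, Xr)
    ss_total = float((Yr ** 2).sum())
    ss_fit = float((fitted ** 2).sum())
    ss_res = ss_total - ss_fit
    df1 = Xr.shape[1]
    df2 = n - C.shape[1] - df1
    f_obs = (ss_fit / df1) / (ss_res / df2)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        fp = constrained(Yr, Xr[perm])
        ssf = float((fp ** 2).sum())
        fperm = (ssf / df1) / ((ss_total - ssf) / df2)
        if fperm >= f_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)

    # constrained axes: SVD of fitted values; loadings = feature scores
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    k = len(axis_names)
    load = vt[:k].T * s[:k]
    site_scores = u[:, :k]
    # orientation: positive correlation with the (first) ecotype contrast
    for j in range(k):
        ref = codes[:, min(j, codes.shape[1] - 1)]
        r = np.corrcoef(site_scores[:, j], ref)[0, 1] if site_scores[:, j].std() > 0 else 0.0
        if r < 0:
            load[:, j] = -load[:, j]
            site_scores[:, j] = -site_scores[:, j]
    loadings = pd.DataFrame(load, index=feat_ids, columns=axis_names)
    z = (loadings - loadings.mean()) / loadings.std(ddof=0)
    cand_mask = (z.abs() > z_threshold).any(axis=1)
    candidates = list(z.index[cand_mask])
    axis_explained = (s[:k] ** 2) / ss_total if ss_total > 0 else np.zeros(k)
    return RdaResult(loadings=loadings, z=z, candidates=candidates,
                     explained_fraction=ss_fit / ss_total if ss_total else 0.0,
                     pseudo_f=float(f_obs), p_value=float(p), n_perm=n_perm,
                     seed=seed, axis_explained=axis_explained,
                     dropped_features=dropped)


def cross_lineage_candidates(rda_a: RdaResult, rda_b: RdaResult, universe,
                             seed: int | None = None,
                             n_resample: int = 10000) -> SharingResult:
    """Sharing of RDA candidates across lineages, by resampling + chi-square.

    Delegates the resampling machinery to ``popgen.sharing_test`` and
    additionally reports a chi-square test of the 2x2
    candidate/non-candidate cross-classification.
    """
    uni = set(universe)
    set_a, set_b = set(rda_a.candidates), set(rda_b.candidates)
    if not set_a <= uni or not set_b <= uni:
        raise ValueError("candidate sets are not drawn from the given universe")
    res = sharing_test(set_a, set_b, universe, n_resample=n_resample,
                       level="SNP", seed=seed)
    both = len(set_a & set_b)
    only_a = len(set_a - set_b)
    only_b = len(set_b - set_a)
    neither = len(uni) - both - only_a - only_b
    table = np.array([[both, only_a], [only_b, neither]])
    if both == 0 and (only_a == 0 or only_b == 0):
        res.chi2_p = 1.0
    else:
        res.chi2_p = float(stats.chi2_contingency(table, correction=True).pvalue)
    return res
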
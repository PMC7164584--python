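"""Ecosystem-size axis, Mantel tests and the cross-level correlation battery.

Ecosystem size is summarised as the first principal component of each
lake's (standardised, log-scaled) maximum depth and surface area; the
pairwise Euclidean distance of PC1 scores is the environmental-distance
matrix.  Mantel tests (Pearson correlation of lower-triangle entries,
object-label permutation, one-sided by default) relate the pairwise
divergence-angle and length-difference matrices from the trajectory
analyses to each other and to ecosystem distance; ordinary least-squares
regressions relate scalar quantities (trajectory length, neutral Fst,
nucleotide diversity, trait variance, ecosystem PC1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EcosystemPC:
    table: pd.DataFrame             # lake, max_depth_m, surface_area_km2, pc1
    explained: float                # fraction explained by PC1
    distance: pd.DataFrame          # lakes x lakes |pc1_i - pc1_j|

    def score(self, lake: str) -> float:
        return float(self.table.set_index("lake").loc[lake, "pc1"])


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    n_objects: int
    seed: int | None
    two_sided: bool = False


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def ecosystem_pc(environment: pd.DataFrame, log_transform: bool = True) -> EcosystemPC:
    """Ecosystem-size PC1 per lake and its pairwise Euclidean distances.

    Depth and area are log10 transformed (both span orders of magnitude),
    z-standardised and PCA'd; PC1 is oriented so larger lakes score
    higher.
    """
    env = environment.copy()
    for col in ("max_depth_m", "surface_area_km2"):
        if col not in env.columns or env[col].isna().any():
            raise ValueError(f"environment table needs complete column {col}")
        if (env[col] <= 0).any():
            raise ValueError(f"{col} must be positive")
    if len(env) < 3:
        raise ValueError("need >= 3 lakes")
    X = env[["max_depth_m", "surface_area_km2"]].to_numpy(dtype=float)
    if log_transform:
        X = np.log10(X)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    pc1 = X @ vt[0]
    if np.corrcoef(pc1, X.sum(axis=1))[0, 1] < 0:
        pc1 = -pc1
    explained = float(s[0] ** 2 / (s ** 2).sum())
    env["pc1"] = pc1
    lakes = list(env["lake"])
    dist = np.abs(pc1[:, None] - pc1[None, :])
    distance = pd.DataFrame(dist, index=lakes, columns=lakes)
    return EcosystemPC(table=env, explained=explained, distance=distance)


def mantel(mat_a: pd.DataFrame, mat_b: pd.DataFrame, n_perm: int = 999,
           seed: int | None = None, two_sided: bool = False) -> MantelResult:
    """Mantel test between two labelled symmetric distance/similarity matrices.

    Pearson r over the lower-triangle entries; the null distribution
    permutes the object labels of the second matrix.  One-sided p
    (positive association) by default:
    ``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)``.
    """
    if seed is None:
        raise ValueError("a seed is required")
    if list(mat_a.index) != list(mat_a.columns) or list(mat_b.index) != list(mat_b.columns):
        raise ValueError("matrices must have matching row/column labels")
    if list(mat_a.index) != list(mat_b.index):
        if set(mat_a.index) != set(mat_b.index):
            raise ValueError("matrices are not over the same objects")
        mat_b = mat_b.loc[mat_a.index, mat_a.index]
    A = np.asarray(mat_a, dtype=float)
    B = np.asarray(mat_b, dtype=float)
    n = A.shape[0]
    if n < 4:
        raise ValueError("need >= 4 objects")
    il = np.tril_indices(n, k=-1)
    ok = np.isfinite(A[il]) & np.isfinite(B[il])
    a, b = A[il][ok], B[il][ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate (constant) distance matrix")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Bp = B[np.ix_(perm, perm)]
        bp = Bp[il][ok]
        if bp.std() == 0:
            continue
        r_perm = float(np.corrcoef(a, bp)[0, 1])
        if two_sided:
            if abs(r_perm) >= abs(r_obs):
                count += 1
        elif r_perm >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, n_objects=n,
                        seed=seed, two_sided=two_sided)


def regression(x, y) -> RegressionResult:
    """Ordinary least-squares simple linear regression with two-sided slope p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0:
        raise ValueError("predictor has zero variance")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r2=float(res.rvalue ** 2), p=float(res.pvalue), n=len(x))


# ---------------------------------------------------------------------------
# the pre-registered correlation battery
# ---------------------------------------------------------------------------

def _pair_matrix(trajset, stat: str) -> pd.DataFrame:
    mat = trajset.theta if stat == "theta" else trajset.delta_l
    return pd.DataFrame(mat, index=trajset.pair_labels, columns=trajset.pair_labels)


def ecosystem_pair_distance(eco: EcosystemPC, trajset) -> pd.DataFrame:
    """Ecosystem-distance matrix between ecotype pairs (via their lakes)."""
    lakes = trajset.lakes
    vals = np.array([[abs(eco.score(li) - eco.score(lj)) for lj in lakes] for li in lakes])
    return pd.DataFrame(vals, index=trajset.pair_labels, columns=trajset.pair_labels)


def predictability_report(traj_pheno=None, traj_neutral=None, traj_assoc=None,
                          traj_expr=None, traj_assoc_expr=None,
                          fst_neutral_by_pair: dict | None = None,
                          pi_by_lake: dict | None = None,
                          trait_variance_by_lake: dict | None = None,
                          ecosystem: EcosystemPC | None = None,
                          n_perm: int = 999, seed: int | None = None) -> pd.DataFrame:
    """Assemble the cross-level correlation battery as one tidy table.

    Twelve pre-registered rows: four Mantel tests among divergence-angle
    and length matrices (phenotype vs neutral SNPs, ecotype-associated
    SNPs, ecotype-associated expression; length differences vs overall
    expression), three regressions (trajectory length vs neutral Fst;
    nucleotide diversity and mean trait variance vs ecosystem PC1), and
    five Mantel tests against ecosystem distance.  Rows whose inputs are
    missing are reported as "not computed" rather than dropped.
    """
    if seed is None:
        raise ValueError("a seed is required")
    rows = []

    def add_mantel(name, ta, sa, tb, sb, seed_offset):
        if ta is None or tb is None:
            rows.append({"analysis": name, "kind": "mantel", "statistic": np.nan,
                         "p": np.nan, "n": 0, "status": "not computed"})
            return
        A = _pair_matrix(ta, sa)
        common = [l for l in A.index if l in set(_pair_matrix(tb, sb).index)]
        try:
            res = mantel(A.loc[common, common],
                         _pair_matrix(tb, sb).loc[common, common],
                         n_perm=n_perm, seed=seed + seed_offset)
            rows.append({"analysis": name, "kind": "mantel", "statistic": res.r,
                         "p": res.p, "n": res.n_objects, "status": "ok"})
        except ValueError as e:
            rows.append({"analysis": name, "kind": "mantel", "statistic": np.nan,
                         "p": np.nan, "n": 0, "status": f"not computed ({e})"})

    def add_mantel_eco(name, ta, sa, seed_offset):
        if ta is None or ecosystem is None:
            rows.append({"analysis": name, "kind": "mantel", "statistic": np.nan,
                         "p": np.nan, "n": 0, "status": "not computed"})
            return
        A = _pair_matrix(ta, sa)
        E = ecosystem_pair_distance(ecosystem, ta)
        try:
            res = mantel(A, E, n_perm=n_perm, seed=seed + seed_offset)
            rows.append({"analysis": name, "kind": "mantel", "statistic": res.r,
                         "p": res.p, "n": res.n_objects, "status": "ok"})
        except ValueError as e:
            rows.append({"analysis": name, "kind": "mantel", "statistic": np.nan,
                         "p": np.nan, "n": 0, "status": f"not computed ({e})"})

    def add_regression(name, x, y):
        if x is None or y is None:
            rows.append({"analysis": name, "kind": "regression", "statistic": np.nan,
                         "p": np.nan, "n": 0, "status": "not computed"})
            return
        try:
            res = regression(x, y)
            rows.append({"analysis": name, "kind": "regression", "statistic": res.r2,
                         "p": res.p, "n": res.n, "status": "ok"})
        except ValueError as e:
            rows.append({"analysis": name, "kind": "regression", "statistic": np.nan,
                         "p": np.nan, "n": 0, "status": f"not computed ({e})"})

    add_mantel("theta_P ~ theta_Gn", traj_pheno, "theta", traj_neutral, "theta", 1)
    add_mantel("theta_P ~ theta_RDA", traj_pheno, "theta", traj_assoc, "theta", 2)
    add_mantel("theta_P ~ theta_canGEx", traj_pheno, "theta", traj_assoc_expr, "theta", 3)
    add_mantel("deltaL_P ~ deltaL_GEx", traj_pheno, "delta_l", traj_expr, "delta_l", 4)

    if traj_pheno is not None and fst_neutral_by_pair:
        labels = [l for l in traj_pheno.pair_labels if l in fst_neutral_by_pair]
        lp = [traj_pheno.lengths[traj_pheno.pair_labels.index(l)] for l in labels]
        fst = [fst_neutral_by_pair[l] for l in labels]
        add_regression("Fst_neut ~ L_P", lp, fst)
    else:
        add_regression("Fst_neut ~ L_P", None, None)
    if ecosystem is not None and pi_by_lake:
        lakes = [l for l in ecosystem.table["lake"] if l in pi_by_lake]
        add_regression("pi ~ ecosystem_PC1",
                       [ecosystem.score(l) for l in lakes],
                       [pi_by_lake[l] for l in lakes])
    else:
        add_regression("pi ~ ecosystem_PC1", None, None)
    if ecosystem is not None and trait_variance_by_lake:
        lakes = [l for l in ecosystem.table["lake"] if l in trait_variance_by_lake]
        add_regression("trait_variance ~ ecosystem_PC1",
                       [ecosystem.score(l) for l in lakes],
                       [trait_variance_by_lake[l] for l in lakes])
    else:
        add_regression("trait_variance ~ ecosystem_PC1", None, None)

    add_mantel_eco("theta_P ~ ecosystem_distance", traj_pheno, "theta", 5)
    add_mantel_eco("theta_Gn ~ ecosystem_distance", traj_neutral, "theta", 6)
    add_mantel_eco("theta_RDA ~ ecosystem_distance", traj_assoc, "theta", 7)
    add_mantel_eco("deltaL_GEx ~ ecosystem_distance", traj_expr, "delta_l", 8)
    add_mantel_eco("theta_GEx ~ ecosystem_distance", traj_expr, "theta", 9)
    out = pd.DataFrame(rows)
    out["seed"] = seed
    return out


def mean_trait_variance_by_lake(corrected_traits: pd.DataFrame,
                                lakes: pd.Series) -> dict:
    """Mean over traits of the within-lake variance of size-corrected values."""
    lakes = pd.Series(np.asarray(lakes, dtype=object), index=corrected_traits.index)
    out = {}
    for lake in pd.unique(lakes):
        sub = corrected_traits[lakes == lake]
        out[lake] = float(sub.var(ddof=1).mean())
    return out
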
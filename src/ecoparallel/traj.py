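"""Trajectory analysis of divergence between sympatric ecotype pairs.

Each ecotype pair defines a divergence vector ``v`` — the difference of
the two ecotype centroids in a multivariate score space (size-corrected
traits, PC scores of allele frequencies or expression, ...).  Its norm
``L`` is the magnitude of divergence; for two pairs the angle

    theta(i, j) = arccos( v_i . v_j / (||v_i|| ||v_j||) )   [degrees]

measures how parallel their directions of divergence are (0 deg = fully
parallel, 180 deg = antiparallel), and ``dL = |L_i - L_j|`` the
difference in magnitude.  Significance of theta and dL is assessed by
residual randomisation under the reduced (common-trajectory) model; a
pair-of-pairs is called parallel when neither statistic differs
significantly from zero.

Vectors are oriented planktivorous -> derived ecotype so angles are
comparable across lakes and lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TrajectorySet:
    """Per-pair divergence vectors and all pairwise comparison statistics."""

    pair_labels: list[str]             # e.g. "A_lake1:planktivorous>benthivorous"
    lakes: list[str]
    lineages: list[str]
    vectors: np.ndarray                # n_pairs x k
    lengths: np.ndarray                # n_pairs
    theta: np.ndarray                  # n_pairs x n_pairs, degrees, NaN diag-safe
    delta_l: np.ndarray                # n_pairs x n_pairs
    replicated: np.ndarray             # bool matrix: same ecotype contrast?
    p_theta: np.ndarray | None = None
    p_delta_l: np.ndarray | None = None
    n_perm: int | None = None
    seed: int | None = None

    def comparisons(self) -> pd.DataFrame:
        """Long-format table of all pair-of-pairs comparisons."""
        rows = []
        n = len(self.pair_labels)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({
                    "pair_i": self.pair_labels[i],
                    "pair_j": self.pair_labels[j],
                    "theta": self.theta[i, j],
                    "delta_L": self.delta_l[i, j],
                    "replicated": bool(self.replicated[i, j]),
                    "p_theta": self.p_theta[i, j] if self.p_theta is not None else np.nan,
                    "p_delta_L": self.p_delta_l[i, j] if self.p_delta_l is not None else np.nan,
                })
        df = pd.DataFrame(rows)
        if self.p_theta is not None and not df.empty:
            df["parallel"] = (df["p_theta"] > 0.05) & (df["p_delta_L"] > 0.05)
        return df


def _angles_and_lengths(vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lengths = np.linalg.norm(vectors, axis=1)
    n = len(vectors)
    theta = np.full((n, n), np.nan)
    dl = np.abs(lengths[:, None] - lengths[None, :])
    for i in range(n):
        for j in range(n):
            if i == j:
                theta[i, j] = 0.0
                continue
            if lengths[i] == 0 or lengths[j] == 0:
                continue  # undefined direction, stays NaN
            cosang = np.clip(vectors[i] @ vectors[j] / (lengths[i] * lengths[j]), -1.0, 1.0)
            theta[i, j] = np.degrees(np.arccos(cosang))
    return theta, dl, lengths


def compute_trajectories(scores, samples: pd.DataFrame,
                         pair_spec: list[tuple[str, str, str]]) -> TrajectorySet:
    """Centroid-difference vectors and pairwise (theta, dL) for ecotype pairs.

    Parameters
    ----------
    scores : a ``morpho.PcaResult`` (its first k50 components are used) or
        a plain matrix/DataFrame indexed like ``samples`` (all columns used).
    samples : table with id, lake, lineage, ecotype.
    pair_spec : list of (lake, ecotypeA, ecotypeB); the vector points
        A -> B (convention: A = planktivorous).

    Pairs with identical centroids get a zero-length vector; their angles
    are recorded as missing (NaN), not zero.
    """
    from .morpho import PcaResult
    if isinstance(scores, PcaResult):
        X = scores.retained_scores().to_numpy()
    else:
        X = np.asarray(scores, dtype=float)
    if X.shape[0] != len(samples):
        raise ValueError("scores and samples disagree on the number of individuals")
    lake_arr = samples["lake"].to_numpy()
    eco_arr = samples["ecotype"].to_numpy()
    vectors, labels, lakes, lineages, contrasts = [], [], [], [], []
    for lake, eco_a, eco_b in pair_spec:
        sel_a = (lake_arr == lake) & (eco_arr == eco_a)
        sel_b = (lake_arr == lake) & (eco_arr == eco_b)
        if sel_a.sum() < 2 or sel_b.sum() < 2:
            raise ValueError(f"pair ({lake}, {eco_a}, {eco_b}) needs >= 2 individuals per ecotype")
        v = X[sel_b].mean(axis=0) - X[sel_a].mean(axis=0)
        vectors.append(v)
        labels.append(f"{lake}:{eco_a}>{eco_b}")
        lakes.append(lake)
        lineages.append(str(samples.loc[samples["lake"] == lake, "lineage"].iloc[0]))
        contrasts.append((eco_a, eco_b))
    vectors = np.asarray(vectors)
    theta, dl, lengths = _angles_and_lengths(vectors)
    n = len(labels)
    replicated = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            replicated[i, j] = contrasts[i] == contrasts[j]
    return TrajectorySet(pair_labels=labels, lakes=lakes, lineages=lineages,
                         vectors=vectors, lengths=lengths, theta=theta,
                         delta_l=dl, replicated=replicated)


def permutation_test(trajset: TrajectorySet, scores, samples: pd.DataFrame,
                     pair_spec: list[tuple[str, str, str]],
                     n_perm: int = 1000, seed: int | None = None) -> TrajectorySet:
    """Permutation p-values for every pairwise (theta, dL) comparison.

    For each pair-of-pairs, ecotype labels are shuffled independently
    within each of the two lakes (sample sizes preserved — the same
    exchangeability argument as the panmixia Fst null), the two
    divergence vectors recomputed, and the permuted (theta, dL) compared
    to the observed values: ``p = (1 + #{perm >= obs}) / (n_perm + 1)``.
    Under the no-ecotype-effect null this label scheme is exactly valid,
    which residual randomisation under the common-trajectory model is
    not for a two-pair comparison (its two observed deviation vectors
    are perfectly anticorrelated by construction).
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible permutation tests")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    from .morpho import PcaResult
    if isinstance(scores, PcaResult):
        X = scores.retained_scores().to_numpy()
    else:
        X = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    lake_arr = samples["lake"].to_numpy()
    eco_arr = samples["ecotype"].to_numpy()
    n_pairs = len(pair_spec)
    p_theta = np.full((n_pairs, n_pairs), np.nan)
    p_dl = np.full((n_pairs, n_pairs), np.nan)

    groups = []  # per pair: (rows_a, rows_b)
    for lake, eco_a, eco_b in pair_spec:
        rows_a = np.where((lake_arr == lake) & (eco_arr == eco_a))[0]
        rows_b = np.where((lake_arr == lake) & (eco_arr == eco_b))[0]
        groups.append((rows_a, rows_b))

    def perm_vector(rows_a, rows_b):
        pool = np.concatenate([rows_a, rows_b])
        perm = rng.permutation(len(pool))
        new_a = pool[perm[: len(rows_a)]]
        new_b = pool[perm[len(rows_a):]]
        return X[new_b].mean(axis=0) - X[new_a].mean(axis=0)

    for i in range(n_pairs):
        for j in range(i + 1, n_pairs):
            obs_t = trajset.theta[i, j]
            obs_d = trajset.delta_l[i, j]
            count_t = 0
            count_d = 0
            n_valid_t = 0
            for _ in range(n_perm):
                vi = perm_vector(*groups[i])
                vj = perm_vector(*groups[j])
                li, lj = np.linalg.norm(vi), np.linalg.norm(vj)
                if li > 0 and lj > 0 and np.isfinite(obs_t):
                    t = np.degrees(np.arccos(np.clip(vi @ vj / (li * lj), -1, 1)))
                    n_valid_t += 1
                    if t >= obs_t:
                        count_t += 1
                if abs(li - lj) >= obs_d:
                    count_d += 1
            if np.isfinite(obs_t) and n_valid_t > 0:
                p_theta[i, j] = p_theta[j, i] = (1 + count_t) / (n_valid_t + 1)
            p_dl[i, j] = p_dl[j, i] = (1 + count_d) / (n_perm + 1)
    np.fill_diagonal(p_theta, 1.0)
    np.fill_diagonal(p_dl, 1.0)
    trajset.p_theta = p_theta
    trajset.p_delta_l = p_dl
    trajset.n_perm = n_perm
    trajset.seed = seed
    return trajset


def group_contrast(trajset: TrajectorySet) -> dict:
    """Are replicated ecotype contrasts more parallel than non-replicated ones?

    Compares the off-diagonal angles (and dL) between replicated
    comparisons (same ecotype contrast in two lakes) and non-replicated
    ones with a two-sided Wilcoxon rank-sum test.
    """
    n = len(trajset.pair_labels)
    iu = np.triu_indices(n, k=1)
    rep = trajset.replicated[iu]
    out = {}
    for stat_name, mat in (("theta", trajset.theta), ("delta_L", trajset.delta_l)):
        vals = mat[iu]
        ok = np.isfinite(vals)
        a = vals[ok & rep]
        b = vals[ok & ~rep]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >= 2 comparisons per group")
        if np.all(a[:, None] == b[None, :]) and len(set(a)) == 1 and len(set(b)) == 1:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        out[stat_name] = {
            "replicated_mean": float(a.mean()), "replicated_sd": float(a.std(ddof=1)),
            "nonreplicated_mean": float(b.mean()), "nonreplicated_sd": float(b.std(ddof=1)),
            "difference": float(a.mean() - b.mean()),
            "wilcoxon_p": p,
            "n_replicated": int(len(a)), "n_nonreplicated": int(len(b)),
        }
    return out
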
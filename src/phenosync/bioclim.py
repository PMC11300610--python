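"""Climate-based site classification.

Sites are described by a table of bioclimatic covariates (temperature and
precipitation summaries in mixed units).  The workflow mirrors common
practice for climate ordination: drop collinear variables (|Pearson r|
above a threshold), cluster sites with Partitioning Around Medoids (PAM,
BUILD + SWAP) on Euclidean distances between standardized variables,
choose the cluster count by the within-sum-of-squares elbow, and ordinate
with PCA on standardized variables.

PAM is implemented here directly (no established Python implementation of
BUILD + SWAP k-medoids is available in this stack); it is validated
against exhaustive medoid search on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "BioclimTable",
    "filter_collinear",
    "pam_cluster",
    "choose_k_wss",
    "pca_ordination",
]


@dataclass
class BioclimTable:
    """Site-by-variable table of bioclimatic covariates."""

    data: pd.DataFrame  # index: site_id; columns: variable names

    def __post_init__(self):
        if self.data.isna().any().any():
            raise ValueError("bioclimatic table contains missing values")
        if self.data.shape[1] < 1:
            raise ValueError("need >= 1 bioclimatic variable")

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)


def filter_collinear(table: BioclimTable, threshold: float = 0.7) -> BioclimTable:
    """Greedily drop variables until all pairwise |Pearson r| <= threshold.

    At each step the currently most-correlated pair is examined and the
    member with the larger mean absolute correlation to all other retained
    variables is dropped; ties are broken by dropping the later variable
    in name order.
    """
    df = table.data.copy()
    if df.shape[1] < 2:
        raise ValueError("collinearity filtering needs >= 2 variables")
    if (df.std(ddof=0) == 0).any():
        bad = list(df.columns[df.std(ddof=0) == 0])
        raise ValueError(f"constant bioclimatic variable(s): {bad}")
    while df.shape[1] >= 2:
        corr = df.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        if corr.values.max() <= threshold:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.columns[i], corr.columns[j]
        # mean |r| to all other retained variables, the offender itself included
        mean_a = corr[a].drop(a).mean()
        mean_b = corr[b].drop(b).mean()
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)
        df = df.drop(columns=[drop])
    return BioclimTable(df)


def _validate_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if np.any(D < 0) or not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("dissimilarity must be non-negative with zero diagonal")
    return D


def _pam_cost(D: np.ndarray, medoids: np.ndarray) -> tuple[float, np.ndarray]:
    sub = D[:, medoids]
    assign = np.argmin(sub, axis=1)
    return float(sub[np.arange(len(D)), assign].sum()), medoids[assign]


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = len(D)
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dist_to_med = D[:, medoids].min(axis=1)
        best_gain, best_cand = -np.inf, None
        for cand in range(n):
            if cand in medoids:
                continue
            gain = np.maximum(dist_to_med - D[:, cand], 0.0).sum()
            if gain > best_gain or (gain == best_gain and cand < (best_cand or n)):
                best_gain, best_cand = gain, cand
        medoids.append(int(best_cand))
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int]) -> list[int]:
    n = len(D)
    medoids = list(medoids)
    cost, _ = _pam_cost(D, np.array(medoids))
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                new_cost, _ = _pam_cost(D, np.array(trial))
                delta = new_cost - cost
                if delta < best[0] - 1e-12:
                    best = (delta, mi, h)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            cost += best[0]
            assert best[0] < 0  # SWAP must strictly decrease the cost
            improved = True
    return medoids


def _farthest_first(D: np.ndarray, k: int) -> list[int]:
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        dmin[medoids] = -1.0
        medoids.append(int(np.argmax(dmin)))
    return medoids


def pam_cluster(
    dissimilarity: np.ndarray, k: int, init_medoids: list[int] | None = None,
    n_restarts: int = 6,
) -> tuple[np.ndarray, np.ndarray, float]:
    """PAM k-medoids clustering (BUILD + SWAP, deterministic multi-start).

    The SWAP phase is steepest-descent and can stall in a local optimum,
    so the search is repeated from the BUILD solution, a farthest-first
    seeding and ``n_restarts`` reproducible random seedings, keeping the
    lowest-cost result.  Returns ``(medoids, labels, total_cost)`` where
    ``labels[i]`` indexes ``medoids`` and ``total_cost`` is the sum of
    dissimilarities of points to their assigned medoid.
    """
    D = _validate_dissimilarity(dissimilarity)
    n = len(D)
    if not (1 <= k < n) and k != n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    if k == n:
        medoids = np.arange(n)
        return medoids, np.arange(n), 0.0
    if init_medoids is not None:
        inits = [list(init_medoids)]
    else:
        inits = [_pam_build(D, k), _farthest_first(D, k)]
        for s in range(n_restarts):
            rng = np.random.default_rng(1000 + s)
            inits.append(list(rng.choice(n, k, replace=False)))
    best_cost, best_medoids = np.inf, None
    for init in inits:
        med = _pam_swap(D, list(init))
        cost, _ = _pam_cost(D, np.array(med))
        if cost < best_cost:
            best_cost, best_medoids = cost, med
    medoids = np.array(sorted(best_medoids))
    cost, assigned = _pam_cost(D, medoids)
    labels = np.searchsorted(medoids, assigned)
    return medoids, labels, cost


def choose_k_wss(
    table: BioclimTable, k_range: range | list[int] | None = None,
    elbow_drop: float = 0.10,
) -> tuple[int, dict[int, float]]:
    """Select the cluster count by the within-sum-of-squares elbow.

    PAM is run on squared Euclidean distances between standardized
    variables, so its cost is the WSS about the medoids.  For each k the
    better of a fresh BUILD + SWAP solution and a warm start extending the
    previous k's medoids is kept, which makes the WSS curve non-increasing
    in k.  The selected k is the smallest whose relative WSS drop to k+1
    falls below ``elbow_drop``.
    """
    X = standardize(table.data).values
    n = len(X)
    if k_range is None:
        k_range = range(1, min(n, 9))
    ks = sorted(k_range)
    if ks[0] < 1 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie in [1, {n - 1}]")
    diff = X[:, None, :] - X[None, :, :]
    D2 = np.einsum("ijk,ijk->ij", diff, diff)
    wss: dict[int, float] = {}
    prev_medoids: np.ndarray | None = None
    for k in ks:
        med, _, cost = pam_cluster(D2, k)
        if prev_medoids is not None and len(prev_medoids) == k - 1:
            # warm start: previous medoids plus the best additional one
            dist_to_med = D2[:, prev_medoids].min(axis=1)
            gains = np.maximum(dist_to_med[:, None] - D2, 0.0).sum(axis=0)
            gains[prev_medoids] = -np.inf
            extra = int(np.argmax(gains))
            warm = _pam_swap(D2, list(prev_medoids) + [extra])
            warm = np.array(sorted(warm))
            warm_cost, _ = _pam_cost(D2, warm)
            if warm_cost < cost:
                med, cost = warm, warm_cost
        wss[k] = cost
        prev_medoids = med
    k_selected = ks[-1]
    for k, k_next in zip(ks, ks[1:]):
        if wss[k] <= 0:
            k_selected = k
            break
        drop = (wss[k] - wss[k_next]) / wss[k]
        if drop < elbow_drop:
            k_selected = k
            break
    return k_selected, wss


def standardize(df: pd.DataFrame) -> pd.DataFrame:
    """Zero-mean, unit-variance columns (population sd)."""
    sd = df.std(ddof=0)
    if (sd == 0).any():
        raise ValueError("cannot standardize constant variable(s)")
    return (df - df.mean()) / sd


def pca_ordination(
    table: BioclimTable,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA on standardized variables.

    Returns (scores, loadings, variance_explained); loadings rows are the
    orthonormal principal axes and variance_explained sums to 1 over all
    components (zero-variance components reported as zeros).
    """
    if table.data.shape[0] < 3:
        raise ValueError("need >= 3 sites for ordination")
    Z = standardize(table.data)
    n_comp = min(Z.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(Z.values)
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    scores_df = pd.DataFrame(scores, index=Z.index, columns=comp_names)
    loadings_df = pd.DataFrame(pca.components_, index=comp_names, columns=Z.columns)
    var_exp = pca.explained_variance_ratio_
    return scores_df, loadings_df, var_exp
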
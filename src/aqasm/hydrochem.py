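"""Correlate taxa with hydrochemical parameters and summarize the profiles.

Spearman rank correlations (two-sided) relate the relative abundance of
each taxon or OTU to each measured parameter across wells and sampling
dates. Correlation profiles are then clustered (UPGMA on Euclidean
distances between rows of r_s values) to find taxa with similar
hydrochemical preferences, or ordinated by PCA of the significant
coefficients to relate co-occurrence clusters to their environmental
signatures.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

logger = logging.getLogger(__name__)


def _exact_spearman_p(x_ranks: np.ndarray, y_ranks: np.ndarray,
                      rho_obs: float) -> float:
    """Two-sided exact p by full enumeration of the n! rank permutations.

    Midranks are enumerated as a multiset via permutations of positions,
    which weighs tied arrangements correctly.
    """
    n = len(x_ranks)
    perms = np.array(list(itertools.permutations(range(n))))
    xs = x_ranks[perms]                       # (n!, n)
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = y_ranks - y_ranks.mean()
    denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(invalid="ignore"):
        rhos = (xc @ yc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_with_p(x: np.ndarray, y: np.ndarray,
                    exact_max_n: int = 9) -> tuple[float, float, int]:
    """Spearman r_s with a two-sided p-value.

    Ties are midranked. For n <= ``exact_max_n`` the p-value is exact
    (full permutation enumeration); otherwise the t-approximation of
    ``scipy.stats.spearmanr`` is used. Returns (r_s, p, n); r_s is NaN
    for constant inputs.
    """
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3 or len(set(x)) == 1 or len(set(y)) == 1:
        return float("nan"), float("nan"), n
    rho, p = stats.spearmanr(x, y)
    if n <= exact_max_n:
        p = _exact_spearman_p(stats.rankdata(x), stats.rankdata(y), rho)
    return float(rho), float(p), n


@dataclass
class CorrelationResults:
    """Entity x parameter Spearman profiles with p-values and flags."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        return (self.p < self.alpha) & self.r.notna()

    def significant_r(self) -> pd.DataFrame:
        """r_s with nonsignificant (or undefined) cells zero-filled."""
        return self.r.where(self.significant, 0.0).fillna(0.0)

    def summary(self) -> str:
        sig = self.significant
        lines = [
            "Spearman correlation profiles",
            f"  entities: {self.r.shape[0]}   parameters: {self.r.shape[1]}"
            f"   alpha: {self.alpha}",
            f"  significant cells: {int(sig.to_numpy().sum())}"
            f" / {sig.size}",
            "",
            self.r.round(3).to_string(),
        ]
        return "\n".join(lines)

    # ---- downstream analyses ------------------------------------------
    def cluster(self, n_clusters: int | None = None):
        return cluster_correlation_profiles(self.significant_r(),
                                            n_clusters=n_clusters)

    def pca(self):
        return pca_of_significant_correlations(self)


class HydrochemCorrelation:
    """Model relating abundance profiles to hydrochemical parameters.

    ``abundances``: samples x entities relative abundances, indexed like
    ``hydrochem`` (same sample keys). Missing hydrochemistry values are
    pairwise-deleted.
    """

    def __init__(self, abundances: pd.DataFrame, hydrochem: pd.DataFrame):
        common = abundances.index.intersection(hydrochem.index)
        if len(common) == 0:
            raise ValueError("no samples shared between tables")
        self.abundances = abundances.loc[common]
        self.hydrochem = hydrochem.loc[common]

    def fit(self, alpha: float = 0.05, min_pairs: int = 5,
            fdr: bool = False) -> CorrelationResults:
        ents = self.abundances.columns
        params = self.hydrochem.columns
        r = pd.DataFrame(index=ents, columns=params, dtype=float)
        p = pd.DataFrame(index=ents, columns=params, dtype=float)
        n = pd.DataFrame(index=ents, columns=params, dtype=float)
        for e in ents:
            xe = self.abundances[e].to_numpy(dtype=float)
            for q in params:
                yq = self.hydrochem[q].to_numpy(dtype=float)
                mask = ~(np.isnan(xe) | np.isnan(yq))
                if mask.sum() < min_pairs:
                    r.loc[e, q], p.loc[e, q], n.loc[e, q] = (np.nan, np.nan,
                                                             mask.sum())
                    continue
                r.loc[e, q], p.loc[e, q], n.loc[e, q] = spearman_with_p(
                    xe, yq)
        if fdr:
            flat = p.to_numpy().ravel()
            ok = ~np.isnan(flat)
            adj = flat.copy()
            adj[ok] = stats.false_discovery_control(flat[ok])
            p = pd.DataFrame(adj.reshape(p.shape), index=p.index,
                             columns=p.columns)
        return CorrelationResults(r, p, n.astype(int), alpha)


def cluster_correlation_profiles(profile: pd.DataFrame,
                                 n_clusters: int | None = None):
    """UPGMA (average linkage, Euclidean) on rows of correlation profiles.

    Undefined cells are zero-imputed (logged). Returns (linkage matrix,
    flat cluster labels as a Series); with ``n_clusters`` None, flat
    clusters are cut at half the maximum merge height.
    """
    X = profile.to_numpy(dtype=float)
    if np.isnan(X).any():
        logger.info("cluster_correlation_profiles: zero-imputing NaN cells")
        X = np.nan_to_num(X)
    if X.shape[0] == 1:
        return np.empty((0, 4)), pd.Series([1], index=profile.index)
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    if n_clusters is None:
        labels = hierarchy.fcluster(Z, t=0.5 * Z[-1, 2],
                                    criterion="distance")
    else:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, pd.Series(labels, index=profile.index, name="cluster")


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca_of_significant_correlations(results_or_matrix,
                                    alpha: float = 0.05) -> PCAResult:
    """PCA (via SVD) of the zero-filled significant correlation matrix.

    Nonsignificant coefficients are set to 0 ("no detected association"),
    columns are mean-centered, and components are limited to the matrix
    rank. Explained-variance fractions sum to 1 over the retained
    components (all zero for an all-zero matrix, with a warning).
    """
    if isinstance(results_or_matrix, CorrelationResults):
        M = results_or_matrix.significant_r()
    else:
        M = results_or_matrix.fillna(0.0)
    X = M.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        logger.warning("PCA input is all zero after filtering")
        k = min(X.shape)
        return PCAResult(
            pd.DataFrame(np.zeros((X.shape[0], k)), index=M.index,
                         columns=[f"PC{i+1}" for i in range(k)]),
            pd.DataFrame(np.zeros((k, X.shape[1])), columns=M.columns,
                         index=[f"PC{i+1}" for i in range(k)]),
            np.zeros(k))
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12))
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]
    var = s ** 2
    names = [f"PC{i+1}" for i in range(rank)]
    return PCAResult(
        scores=pd.DataFrame(U * s, index=M.index, columns=names),
        loadings=pd.DataFrame(Vt, index=names, columns=M.columns),
        explained_variance_ratio=var / var.sum())
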
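"""Clustering of regional differential-complexity curves.

Each region contributes one curve (case mean minus control mean across age
windows). Regions with similar developmental deviation patterns are grouped
by agglomerative clustering with Euclidean distance and complete linkage;
the cluster count is chosen by scanning the Calinski-Harabasz (CH) index
over a small range of k. Deterministic dendrogram leaf order provides the
display permutation for heatmaps, and a window-by-window Pearson
correlation matrix of mean entropy profiles summarizes how similar the
regional pattern is across ages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from sklearn.metrics import calinski_harabasz_score

from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    """Distance matrix, linkage tree, chosen labels, CH scan, and leaf order."""

    row_ids: list                     # region ids in matrix order (rows actually clustered)
    distance_matrix: np.ndarray       # condensed -> square, symmetric, zero diagonal
    linkage: np.ndarray               # scipy linkage matrix (complete)
    labels: dict                      # region id -> cluster id (1-based) for chosen k
    k: int
    ch_scores: dict[int, float]
    leaf_order: list                  # region ids in dendrogram left-to-right order
    excluded_rows: list = field(default_factory=list)


def curve_distances(curves: pd.DataFrame) -> tuple[np.ndarray, list, list]:
    """Pairwise Euclidean distances between curve rows.

    Rows containing any missing value are excluded (with a logged list)
    rather than imputed. Returns (square distance matrix, kept row ids,
    excluded row ids).
    """
    keep = curves.dropna(axis=0, how="any")
    excluded = [i for i in curves.index if i not in keep.index]
    if excluded:
        logger.warning("curve_distances: excluding rows with missing values: %s", excluded)
    if keep.shape[0] < 2:
        raise ParameterError("need at least 2 complete curves to compute distances")
    dist = squareform(pdist(keep.to_numpy(dtype=float), metric="euclidean"))
    return dist, list(keep.index), excluded


def complete_linkage(dist: np.ndarray) -> np.ndarray:
    """Complete-linkage merge tree from a square distance matrix."""
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ParameterError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ParameterError("distance matrix must be symmetric")
    if d.shape[0] < 2:
        raise ParameterError("need at least 2 items")
    return hierarchy.linkage(squareform(d, checks=False), method="complete")


def cut_tree_labels(linkage: np.ndarray, k: int) -> np.ndarray:
    """Partition into k clusters by undoing the last k-1 merges (labels 1..k)."""
    n = linkage.shape[0] + 1
    if not (isinstance(k, (int, np.integer)) and 1 <= k <= n):
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    return hierarchy.cut_tree(linkage, n_clusters=k).ravel() + 1


def calinski_harabasz(curves: np.ndarray, labels) -> float:
    """CH index: between-cluster over within-cluster dispersion, df-normalized.

    A clustering with zero within-cluster dispersion (e.g. all singletons or
    exactly coincident members) is reported as infinite.
    """
    X = np.asarray(curves, dtype=float)
    lab = np.asarray(labels)
    uniq = np.unique(lab)
    if uniq.size < 2:
        raise ParameterError("CH needs at least 2 clusters")
    if uniq.size >= X.shape[0]:
        logger.warning("CH: singleton-only clustering, zero within dispersion -> inf")
        return float("inf")
    within = 0.0
    for u in uniq:
        sub = X[lab == u]
        within += float(((sub - sub.mean(axis=0)) ** 2).sum())
    if within == 0.0:
        logger.warning("CH: zero within-cluster dispersion -> inf")
        return float("inf")
    return float(calinski_harabasz_score(X, lab))


def leaf_ordering(linkage: np.ndarray) -> np.ndarray:
    """Deterministic left-to-right dendrogram leaf order (display permutation)."""
    return hierarchy.leaves_list(linkage)


def choose_k_by_ch(curves: np.ndarray, linkage: np.ndarray,
                   k_range: tuple[int, int] = (2, 6)) -> tuple[int, dict[int, float]]:
    """Scan k over [k_lo, k_hi], pick the CH maximum (smallest k on ties)."""
    lo, hi = k_range
    n = np.asarray(curves).shape[0]
    scores: dict[int, float] = {}
    for k in range(lo, min(hi, n - 1) + 1):
        scores[k] = calinski_harabasz(curves, cut_tree_labels(linkage, k))
    best = max(sorted(scores), key=lambda k: (scores[k], -k))
    return best, scores


def cluster_curves(curves: pd.DataFrame, k: int | None = None,
                   k_range: tuple[int, int] = (2, 6)) -> ClusterResult:
    """Full clustering of a differential-curve matrix (rows = regions)."""
    dist, kept, excluded = curve_distances(curves)
    Z = complete_linkage(dist)
    X = curves.loc[kept].to_numpy(dtype=float)
    if k is None:
        k, ch_scores = choose_k_by_ch(X, Z, k_range)
    else:
        _, ch_scores = choose_k_by_ch(X, Z, k_range)
    lab = cut_tree_labels(Z, k)
    order = leaf_ordering(Z)
    return ClusterResult(row_ids=kept, distance_matrix=dist, linkage=Z,
                         labels={rid: int(c) for rid, c in zip(kept, lab)}, k=int(k),
                         ch_scores=ch_scores, leaf_order=[kept[i] for i in order],
                         excluded_rows=excluded)


def age_group_correlations(mean_entropy_by_window: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between every pair of window rows of a window x region matrix.

    Zero-variance rows produce missing entries (flagged), diagonal is 1.
    """
    M = mean_entropy_by_window
    if M.shape[1] < 3:
        raise ParameterError("need at least 3 regions for between-window correlations")
    X = M.to_numpy(dtype=float)
    sd = X.std(axis=1)
    out = np.full((X.shape[0], X.shape[0]), np.nan)
    for i in range(X.shape[0]):
        for j in range(i, X.shape[0]):
            if i == j:
                out[i, j] = 1.0
            elif sd[i] > 0 and sd[j] > 0:
                out[i, j] = out[j, i] = float(np.corrcoef(X[i], X[j])[0, 1])
    if np.any(sd == 0):
        logger.warning("age_group_correlations: zero-variance windows %s",
                       list(np.asarray(M.index)[sd == 0]))
    return pd.DataFrame(out, index=M.index, columns=M.index)


def cluster_mean_curves(curves: pd.DataFrame, labels: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Column-wise mean curve per cluster plus each curve's extreme values.

    Returns (mean_curves: cluster x window, extremes: per cluster peak/trough
    value and window). All-zero curves report no extremes.
    """
    lab = pd.Series(labels)
    if lab.empty:
        raise ParameterError("labels must be nonempty")
    rows = []
    means = {}
    for c in sorted(lab.unique()):
        members = lab.index[lab == c]
        if len(members) == 0:
            raise ParameterError(f"cluster {c} is empty")
        mc = curves.loc[members].mean(axis=0)
        means[c] = mc
        if np.allclose(mc.to_numpy(dtype=float), 0.0):
            rows.append(dict(cluster=c, n_regions=len(members), peak_value=np.nan,
                             peak_window=pd.NA, trough_value=np.nan, trough_window=pd.NA))
        else:
            rows.append(dict(cluster=c, n_regions=len(members),
                             peak_value=float(mc.max()), peak_window=mc.idxmax(),
                             trough_value=float(mc.min()), trough_window=mc.idxmin()))
    mean_df = pd.DataFrame(means).T
    mean_df.index.name = "cluster"
    return mean_df, pd.DataFrame(rows).set_index("cluster")


def export_heatmap(curves: pd.DataFrame, result: ClusterResult, path) -> None:
    """Static heatmap of the differential curves in dendrogram leaf order."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = curves.loc[result.leaf_order]
    vmax = float(np.nanmax(np.abs(ordered.to_numpy(dtype=float)))) or 1.0
    fig, ax = plt.subplots(figsize=(8, 10))
    im = ax.imshow(ordered.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax)
    ax.set_xlabel("age window")
    ax.set_ylabel("region (leaf order)")
    ax.set_yticks(range(len(ordered.index)))
    ax.set_yticklabels([str(r) for r in ordered.index], fontsize=4)
    fig.colorbar(im, ax=ax, label="case - control mean SampEn (nats)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def cluster_trendline_ttest(mean_curves: pd.DataFrame, paired: bool = True
                            ) -> tuple[float, float]:
    """t-test between two clusters' mean trendlines across windows.

    ``paired=True`` pairs by window (the windows are shared between the two
    curves); the unpaired variant treats the window values as independent
    samples. Both are reported by the pipeline, with the paired one primary.
    """
    if mean_curves.shape[0] != 2:
        raise ParameterError("trendline t-test needs exactly 2 clusters")
    a, b = (mean_curves.iloc[i].to_numpy(dtype=float) for i in range(2))
    if paired:
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b)
    return float(t), float(p)
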
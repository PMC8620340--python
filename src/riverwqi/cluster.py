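"""Agglomerative clustering of entities by their (scaled) WQI triplets.

Stations (or years) are described by their three index values (CCME, BC,
weighted), standardized column-wise, and grouped by agglomerative
hierarchical clustering on Euclidean distances.  The strength of the
clustering structure is summarised by the agglomerative coefficient: the mean
over entities of 1 - (height of the entity's first merge / final merge
height), close to 1 when tight groups merge early and join late.

The number of clusters is chosen by majority vote over a panel of internal
validity indices (silhouette, Calinski-Harabasz, Davies-Bouldin, gap
statistic, Dunn), mirroring the majority-vote selection practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn import metrics


class ClusterError(ValueError):
    pass


@dataclass
class ClusterResult:
    entities: list[str]
    features: np.ndarray
    linkage_matrix: np.ndarray
    k: int
    labels: dict[str, int]
    agglomerative_coefficient: float
    votes: dict[int, int] = field(default_factory=dict)


def standardize_features(matrix) -> np.ndarray:
    """Center each column to mean 0 and scale to unit sample sd (ddof=1).

    A zero-variance column is centered only, with a warning.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ClusterError("need a 2-D matrix with at least 2 rows")
    if np.isnan(x).any():
        raise ClusterError("missing cells not allowed in the feature matrix")
    centered = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"zero-variance column(s) {np.flatnonzero(zero).tolist()}: "
            "centered only", stacklevel=2,
        )
    sd = np.where(zero, 1.0, sd)
    return centered / sd


def agglomerative_coefficient(link: np.ndarray) -> float:
    """Mean over entities of 1 - h_first / h_final from a linkage matrix."""
    n = link.shape[0] + 1
    h_final = link[-1, 2]
    if h_final == 0:
        return 0.0
    first = np.full(n, np.nan)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step, (a, b, h, _) in enumerate(link):
        a, b = int(a), int(b)
        for node in (a, b):
            for leaf in members[node]:
                if np.isnan(first[leaf]):
                    first[leaf] = h
        members[n + step] = members[a] + members[b]
    return float(np.mean(1.0 - first / h_final))


def hierarchical_cluster(
    features,
    k: int,
    entities: list[str] | None = None,
    linkage_method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering (Euclidean) cut at k clusters."""
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ClusterError(f"k={k} outside [1, {n}]")
    if linkage_method not in {"average", "ward", "complete", "single"}:
        raise ClusterError(f"unsupported linkage {linkage_method!r}")
    entities = entities or [f"E{i + 1}" for i in range(n)]
    link = linkage(x, method=linkage_method, metric="euclidean")
    raw = cut_tree(link, n_clusters=k).ravel()
    labels = {e: int(c) for e, c in zip(entities, raw)}
    return ClusterResult(
        entities=list(entities),
        features=x,
        linkage_matrix=link,
        k=k,
        labels=labels,
        agglomerative_coefficient=agglomerative_coefficient(link),
    )


# -- validity indices for the k vote ----------------------------------------


def _dunn(x: np.ndarray, labels: np.ndarray) -> float:
    d = squareform(pdist(x))
    ks = np.unique(labels)
    min_between = np.inf
    max_within = 0.0
    for a in ks:
        ia = labels == a
        within = d[np.ix_(ia, ia)]
        if within.size > 1:
            max_within = max(max_within, within.max())
        for b in ks:
            if b <= a:
                continue
            min_between = min(min_between, d[np.ix_(ia, labels == b)].min())
    if max_within == 0:
        return np.inf
    return min_between / max_within


def _gap_statistic(
    x: np.ndarray, k: int, linkage_method: str, rng: np.random.Generator,
    n_ref: int = 20,
) -> float:
    def log_wk(data: np.ndarray, lab: np.ndarray) -> float:
        wk = 0.0
        for c in np.unique(lab):
            pts = data[lab == c]
            if len(pts) > 1:
                wk += pdist(pts).sum() / (2 * len(pts)) * 2  # sum d / (2 n_r)
        return np.log(wk) if wk > 0 else -np.inf

    def cluster_labels(data: np.ndarray) -> np.ndarray:
        return cut_tree(
            linkage(data, method=linkage_method), n_clusters=k
        ).ravel()

    obs = log_wk(x, cluster_labels(x))
    lo, hi = x.min(axis=0), x.max(axis=0)
    refs = []
    for _ in range(n_ref):
        ref = rng.uniform(lo, hi, size=x.shape)
        refs.append(log_wk(ref, cluster_labels(ref)))
    return float(np.mean(refs) - obs)


def select_k(
    features,
    k_range=range(2, 6),
    linkage_method: str = "average",
    index_panel: tuple[str, ...] = (
        "silhouette", "calinski_harabasz", "davies_bouldin", "gap", "dunn",
    ),
    seed: int = 0,
) -> tuple[int, dict[int, int]]:
    """Choose the cluster count by majority vote of validity indices.

    Each index scores every k in ``k_range`` on the hierarchical labels and
    votes for its best k; ties in the vote go to the smaller k.
    """
    if not index_panel:
        raise ClusterError("empty validity-index panel")
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    ks = [k for k in k_range]
    if not ks or min(ks) < 2 or max(ks) > n - 1:
        raise ClusterError(f"k_range must lie within [2, {n - 1}]")
    link = linkage(x, method=linkage_method, metric="euclidean")
    labels_by_k = {k: cut_tree(link, n_clusters=k).ravel() for k in ks}
    rng = np.random.default_rng(seed)
    scores: dict[str, dict[int, float]] = {name: {} for name in index_panel}
    for k in ks:
        lab = labels_by_k[k]
        if len(np.unique(lab)) < 2:
            continue
        for name in index_panel:
            if name == "silhouette":
                scores[name][k] = metrics.silhouette_score(x, lab)
            elif name == "calinski_harabasz":
                scores[name][k] = metrics.calinski_harabasz_score(x, lab)
            elif name == "davies_bouldin":
                scores[name][k] = -metrics.davies_bouldin_score(x, lab)
            elif name == "gap":
                scores[name][k] = _gap_statistic(x, k, linkage_method, rng)
            elif name == "dunn":
                scores[name][k] = _dunn(x, lab)
            else:
                raise ClusterError(f"unknown validity index {name!r}")
    votes: dict[int, int] = {k: 0 for k in ks}
    for name, by_k in scores.items():
        if not by_k:
            continue
        best = max(sorted(by_k), key=lambda k: (by_k[k], -k))
        votes[best] += 1
    winner = max(sorted(votes), key=lambda k: (votes[k], -k))
    return winner, votes
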
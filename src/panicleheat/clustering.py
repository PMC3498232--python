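"""Co-expression clustering of heat-responsive genes and per-cluster
category over-representation.

k-means (with several seeded restarts) partitions temporal profiles into k
clusters, defaulting to k = 12 — the granularity at which the panicle heat
time course resolves into early/late/continuous up- and down-regulated
patterns.  A rule-based labeller names each centroid's pattern from its
log2 fold-change trajectory, and a hypergeometric test scores annotation
categories over-represented within each cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .datatypes import TREATMENT_TIME_POINTS
from .stats import benjamini_hochberg, hypergeom_upper_tail

__all__ = [
    "ClusterAssignment",
    "kmeans_cluster",
    "hierarchical_cluster",
    "label_cluster_pattern",
    "category_enrichment",
    "PATTERN_LABELS",
]

#: Recognized temporal pattern labels.  The early window covers 20 min-2 h,
#: the late window 4 h-8 h.
PATTERN_LABELS = (
    "early-up",
    "late-up",
    "continuous-up",
    "early-down",
    "late-down",
    "continuous-down",
    "early-down-late-up",
    "mixed",
)

_EARLY = slice(0, 3)  # 20min, 60min, 2h
_LATE = slice(3, 5)  # 4h, 8h


@dataclass
class ClusterAssignment:
    """k-means result: 1-based cluster memberships, centroids, objective."""

    members: pd.Series  # item -> cluster index in 1..k
    centroids: pd.DataFrame  # k rows (index 1..k) x input columns
    k: int
    seed: int
    inertia: float
    pattern_labels: dict[int, str] | None = None

    def cluster_items(self, cluster: int) -> list:
        return list(self.members.index[self.members == cluster])


def kmeans_cluster(
    profiles: pd.DataFrame, k: int = 12, seed: int = 0, n_init: int = 10
) -> ClusterAssignment:
    """Partition profile rows into ``k`` clusters by Euclidean k-means.

    Uses k-means++ initialization with ``n_init`` seeded restarts, keeping
    the lowest within-cluster sum of squares; deterministic given ``seed``.
    Rows may be the 12 normalized sample columns or the 5-point log2
    fold-change trajectories — both are meaningful profile spaces.
    """
    n = profiles.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows ({n})")
    if k > 1 and np.allclose(profiles.to_numpy(), profiles.to_numpy()[0]):
        warnings.warn("all profiles identical; clustering is degenerate")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(profiles.to_numpy(dtype=float))
    members = pd.Series(labels + 1, index=profiles.index, name="cluster")
    centroids = pd.DataFrame(
        km.cluster_centers_, index=range(1, k + 1), columns=profiles.columns
    )
    return ClusterAssignment(
        members=members,
        centroids=centroids,
        k=k,
        seed=seed,
        inertia=float(km.inertia_),
    )


def hierarchical_cluster(
    profiles: pd.DataFrame, metric: str = "euclidean", method: str = "complete"
) -> tuple[np.ndarray, list]:
    """Agglomerative clustering of profile rows; returns the linkage matrix
    and the leaf order for heatmap rendering.

    ``metric`` may be any scipy pdist metric; ``"correlation"`` gives the
    1 - Pearson distance used for sample trees.
    """
    if profiles.shape[0] < 2:
        raise ValueError("hierarchical clustering needs >= 2 rows")
    z = linkage(pdist(profiles.to_numpy(dtype=float), metric=metric), method=method)
    order = [profiles.index[i] for i in leaves_list(z)]
    return z, order


def label_cluster_pattern(centroid_log2fc, up_thresh: float = 1.0) -> str:
    """Name the temporal pattern of a 5-point log2FC centroid.

    Windows: early = (20 min, 60 min, 2 h), late = (4 h, 8 h).  Rules, in
    precedence order with threshold T = ``up_thresh`` (log2 units):

    - continuous-up: all five points >= T
    - continuous-down: all five points <= -T
    - early-down-late-up: early mean <= -T and late mean >= T
    - early-up / late-up: one window mean >= T, the other < T
    - early-down / late-down: one window mean <= -T, the other > -T
    - otherwise: mixed
    """
    v = np.asarray(centroid_log2fc, dtype=float)
    if v.shape != (len(TREATMENT_TIME_POINTS),):
        raise ValueError(f"centroid must have {len(TREATMENT_TIME_POINTS)} entries")
    t = up_thresh
    early = v[_EARLY].mean()
    late = v[_LATE].mean()
    if np.all(v >= t):
        return "continuous-up"
    if np.all(v <= -t):
        return "continuous-down"
    if early <= -t and late >= t:
        return "early-down-late-up"
    if early >= t and late < t:
        return "early-up"
    if late >= t and early < t:
        return "late-up"
    if early <= -t and late > -t:
        return "early-down"
    if late <= -t and early > -t:
        return "late-down"
    return "mixed"


def label_assignment_patterns(
    assignment: ClusterAssignment, centroid_log2fc: pd.DataFrame | None = None,
    up_thresh: float = 1.0,
) -> dict[int, str]:
    """Label every cluster of an assignment; uses ``assignment.centroids``
    when they already live in log2FC space, else the supplied frame."""
    cents = centroid_log2fc if centroid_log2fc is not None else assignment.centroids
    labels = {
        c: label_cluster_pattern(cents.loc[c].to_numpy(), up_thresh=up_thresh)
        for c in cents.index
    }
    assignment.pattern_labels = labels
    return labels


def category_enrichment(
    cluster_members: dict[int, set],
    annotation: dict | pd.Series,
    universe: set,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation categories per cluster.

    ``annotation`` maps gene -> iterable of category names.  For each
    (cluster, category): t members annotated, T cluster size, k annotated in
    the universe, K universe size, upper-tail p.  Raw p-values are compared
    with ``alpha``; Benjamini–Hochberg adjustment is optional and off by
    default (the analysis tradition here reports raw p).
    """
    universe = set(universe)
    gene_cats = {
        g: set(cats) for g, cats in dict(annotation).items() if g in universe
    }
    cat_genes: dict[str, set] = {}
    for g, cats in gene_cats.items():
        for c in cats:
            cat_genes.setdefault(c, set()).add(g)

    K = len(universe)
    rows = []
    for cluster, members in cluster_members.items():
        members = set(members)
        if not members <= universe:
            raise ValueError(f"cluster {cluster} has genes outside the universe")
        T = len(members)
        for cat, carriers in sorted(cat_genes.items()):
            k = len(carriers)
            t = len(members & carriers)
            p = hypergeom_upper_tail(t, K, k, T)
            rows.append((cluster, cat, t, T, k, K, p))
    df = pd.DataFrame(
        rows, columns=["cluster", "category", "t", "T", "k", "K", "p"]
    )
    if bh_correct and len(df):
        df["p_adj"] = benjamini_hochberg(df["p"].to_numpy())
        df["significant"] = df["p_adj"] < alpha
    else:
        df["significant"] = df["p"] < alpha
    return df
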
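"""Single-cell phenotype clustering: log features → KNN graph → Louvain.

Cells are balanced across groups by random subsampling, features
(morphology + mean marker intensities) are natural-log transformed with a
pseudocount of 1 for equal weighting, an unweighted union-symmetrized
k-nearest-neighbour graph is built with k = floor(sqrt(N)), and Louvain
modularity optimisation at resolution 1.0 assigns every cell to a
cluster. Clusters are renumbered by decreasing size (1 = largest) and
summarised by per-cluster phenotype means and per-case abundance.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_FEATURES = (
    "cell_body_area",
    "process_number",
    "total_outgrowth",
    "branch_number",
    "iba1",
    "cd68",
)

DEFAULT_SEED = 20250221
PER_GROUP_N = 7340


@dataclass
class FeatureMatrix:
    """Cells x features with case/group labels and a transform flag."""

    values: pd.DataFrame           # numeric feature columns only
    cells: pd.DataFrame            # cell_id / case_id / group metadata
    transformed: bool = False

    def __post_init__(self) -> None:
        if len(self.values) != len(self.cells):
            raise ValueError("values and cell metadata disagree in length")
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_cells(self) -> int:
        return len(self.values)


@dataclass
class NeighborGraph:
    edges: np.ndarray              # (m, 2) int array, i < j, unique
    n_nodes: int
    k: int


@dataclass
class ClusterResult:
    labels: np.ndarray             # per-cell cluster id, 1..C by size
    k: int
    resolution: float
    seed: int
    modularity: float
    cells: pd.DataFrame
    feature_means: pd.DataFrame = field(default=None)
    abundance: pd.DataFrame = field(default=None)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


def balanced_subsample(
    cells: pd.DataFrame, per_group_n: int, seed: int, group_col: str = "group"
) -> pd.DataFrame:
    """Exactly ``per_group_n`` cells per group, uniformly without
    replacement; deterministic under ``seed``. Raises naming the first
    deficient group."""
    rng = np.random.default_rng(seed)
    parts = []
    for group, sub in cells.groupby(group_col, sort=True):
        if len(sub) < per_group_n:
            raise ValueError(
                f"group {group!r} has only {len(sub)} cells, "
                f"need {per_group_n}")
        take = rng.choice(len(sub), size=per_group_n, replace=False)
        parts.append(sub.iloc[np.sort(take)])
    return pd.concat(parts, ignore_index=True)


def log_transform(fm: FeatureMatrix, pseudocount: float = 1.0) -> FeatureMatrix:
    """Elementwise x -> ln(x + pseudocount); refuses to run twice."""
    if fm.transformed:
        raise ValueError("feature matrix is already log-transformed")
    if (fm.values < 0).any().any():
        raise ValueError("features must be non-negative before log transform")
    return FeatureMatrix(
        values=np.log(fm.values + pseudocount),
        cells=fm.cells,
        transformed=True,
    )


def knn_k(n_cells: int) -> int:
    """The default neighbourhood size: floor(sqrt(N))."""
    return int(np.floor(np.sqrt(n_cells)))


def build_knn_graph(
    fm: FeatureMatrix, k: int | None = None, mutual: bool = False
) -> NeighborGraph:
    """Euclidean KNN graph, symmetrized by union (or intersection when
    ``mutual``), unweighted, no self-loops.

    Distance ties are broken by cell index for the exact (brute-force)
    search used at small N; the tree-based search used at scale resolves
    ties arbitrarily, which only matters for exactly duplicated points.
    """
    if not fm.transformed:
        raise ValueError("build the graph on log-transformed features")
    X = fm.values.to_numpy(dtype=np.float64)
    n = len(X)
    if k is None:
        k = knn_k(n)
    if n < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} cells, have {n}")

    if n <= 2000:
        d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        # lexicographic (distance, index) sort makes ties deterministic
        nbrs = np.argsort(d2, axis=1, kind="stable")[:, :k]
    else:
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        _, idx = nn.kneighbors(X)
        nbrs = np.empty((n, k), dtype=np.int64)
        for i in range(n):
            row = idx[i][idx[i] != i][:k]
            if len(row) < k:  # self not returned (duplicate points)
                row = idx[i][:k]
            nbrs[i] = row

    src = np.repeat(np.arange(n), k)
    dst = nbrs.ravel()
    lo = np.minimum(src, dst)
    hi = np.maximum(src, dst)
    directed = set(zip(lo.tolist(), hi.tolist()))
    if mutual:
        pair_count: dict[tuple[int, int], int] = {}
        for a, b in zip(lo.tolist(), hi.tolist()):
            pair_count[(a, b)] = pair_count.get((a, b), 0) + 1
        edges = np.array([e for e, c in pair_count.items() if c == 2],
                         dtype=np.int64)
    else:
        edges = np.array(sorted(directed), dtype=np.int64)
    return NeighborGraph(edges=edges, n_nodes=n, k=k)


def louvain_cluster(
    g: NeighborGraph,
    cells: pd.DataFrame,
    resolution: float = 1.0,
    seed: int = DEFAULT_SEED,
) -> ClusterResult:
    """Louvain community detection on the KNN graph.

    Modularity is optimised at the given resolution; the partition is
    deterministic under ``seed``. Cluster ids are renumbered by
    decreasing size starting at 1. Disconnected components are handled
    independently by the algorithm.
    """
    import igraph

    if g.n_nodes == 0:
        raise ValueError("empty graph")
    graph = igraph.Graph(n=g.n_nodes, edges=[tuple(e) for e in g.edges])
    state = _random.getstate()
    try:
        _random.seed(seed)
        part = graph.community_multilevel(resolution=resolution)
    finally:
        _random.setstate(state)
    raw = np.asarray(part.membership)
    modularity = float(graph.modularity(raw.tolist(), resolution=resolution))

    # renumber by decreasing size; ties by original id for determinism
    ids, counts = np.unique(raw, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    remap = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = np.array([remap[int(v)] for v in raw], dtype=np.int64)
    return ClusterResult(labels=labels, k=g.k, resolution=resolution,
                         seed=seed, modularity=modularity,
                         cells=cells.reset_index(drop=True))


def summarize_clusters(
    cr: ClusterResult, features: pd.DataFrame
) -> ClusterResult:
    """Attach per-cluster phenotype means and per-case abundance.

    ``features`` are the untransformed per-cell features aligned with the
    clustered cells. Abundance is the percentage of each case's cells in
    each cluster (rows sum to 100)."""
    if len(features) != len(cr.labels):
        raise ValueError("features misaligned with cluster labels")
    feats = features.reset_index(drop=True).copy()
    feats["cluster"] = cr.labels
    cr.feature_means = feats.groupby("cluster").mean(numeric_only=True)

    tab = pd.crosstab(cr.cells["case_id"], cr.labels)
    cr.abundance = tab.div(tab.sum(axis=1), axis=0) * 100.0
    cr.abundance.columns.name = "cluster"
    return cr


def abundance_by_group(cr: ClusterResult) -> pd.DataFrame:
    """Mean per-case cluster abundance (%) within each group.

    Rows = groups, columns = clusters; the differential-abundance view
    used to call clusters enriched or depleted in a disease group."""
    if cr.abundance is None:
        raise ValueError("run summarize_clusters first")
    case_group = cr.cells.drop_duplicates("case_id").set_index("case_id")["group"]
    ab = cr.abundance.copy()
    ab["group"] = case_group.reindex(ab.index)
    return ab.groupby("group").mean()
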
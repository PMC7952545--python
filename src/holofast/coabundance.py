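"""Signed weighted co-abundance clustering of omics feature matrices.

The clustering pipeline is the weighted correlation network analysis
family: a robust biweight midcorrelation between features, a signed soft
threshold ``a_ij = ((1 + cor_ij)/2)**beta``, a topological-overlap
dissimilarity, average-linkage hierarchical clustering, a dynamic hybrid
tree cut (sensitivity set by ``deep_split`` in 0-4), and cluster eigengenes
(first principal component of the standardized member profiles).

Per-dataset defaults used by the orchestration layer: soft threshold beta
8 for metabolites, 6 for lipids, 14/7/9 for ileal/cecal/colonic OTUs;
minimum cluster size 5 (3 for lipids); deep split 2 for OTUs and 4 for
metabolites and lipids. Metabolite and lipid tables are log-transformed
before correlation (pseudocount of half the smallest nonzero value); OTU
relative abundances enter untransformed.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import linregress
from sklearn.base import BaseEstimator, ClusterMixin

logger = logging.getLogger(__name__)

__all__ = [
    "bicor_matrix",
    "signed_adjacency",
    "scale_free_fit",
    "tom_dissimilarity",
    "cut_dynamic_hybrid",
    "compute_eigengenes",
    "log_transform",
    "linkage_to_newick",
    "CoabundanceClusterer",
]

# deep-split sensitivity scale of the hybrid cut: maximum relative core
# scatter at deep_split = 0..4 (minimum gap is 3/4 of the complement)
_CORE_SCATTER_GRID = (0.64, 0.73, 0.82, 0.91, 0.95)


# ------------------------------------------------------------------- bicor


def _biweight_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median-centered, biweight-scaled unit columns.

    Weights are ``w = (1 - u^2)^2`` for ``|u| < 1`` with
    ``u = (x - median) / (9 * MAD)``. Columns with MAD = 0 fall back to
    Pearson standardization (mean-centering, uniform weights).
    Returns the normalized columns and the fallback mask.
    """
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    fallback = mad == 0
    u = np.zeros_like(X)
    ok = ~fallback
    u[:, ok] = (X[:, ok] - med[ok]) / (9.0 * mad[ok])
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    xt = (X - med) * w
    if fallback.any():
        xt[:, fallback] = X[:, fallback] - X[:, fallback].mean(axis=0)
    norm = np.sqrt((xt**2).sum(axis=0))
    zero = norm == 0
    norm[zero] = 1.0
    xt = xt / norm
    xt[:, zero] = 0.0
    return xt, fallback


def bicor_matrix(data: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Biweight midcorrelation between all feature pairs.

    ``data`` is samples x features with at least 4 samples. Symmetric,
    unit diagonal, entries clipped to [-1, 1].
    """
    df = pd.DataFrame(data).astype(float)
    if df.shape[0] < 4:
        raise ValueError("biweight midcorrelation requires at least 4 samples")
    xt, fallback = _biweight_columns(df.to_numpy())
    if fallback.any():
        logger.warning(
            "MAD = 0 for %d feature(s); Pearson fallback used: %s",
            int(fallback.sum()),
            list(df.columns[fallback]),
        )
    cor = np.clip(xt.T @ xt, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=df.columns, columns=df.columns)


# ------------------------------------------------------- adjacency and TOM


def signed_adjacency(cor: pd.DataFrame | np.ndarray, beta: int) -> pd.DataFrame:
    """Signed soft-threshold adjacency ``((1 + cor)/2)**beta`` with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be a positive integer")
    cor = pd.DataFrame(cor).astype(float)
    adj = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(adj.to_numpy(), 1.0)
    return adj


def scale_free_fit(adjacency: pd.DataFrame | np.ndarray, n_bins: int = 10) -> float:
    """Signed R-squared of the log-log degree-distribution fit.

    Connectivity ``k_i = sum_{j != i} a_ij`` is discretized into ``n_bins``
    equal-width bins; ``log10 p(k)`` is regressed on ``log10 mean(k)`` per
    occupied bin. The R-squared is negated when the slope is positive
    (a scale-free topology has a decreasing degree distribution). Returns
    NaN when the degree distribution is degenerate.
    """
    A = np.asarray(pd.DataFrame(adjacency), dtype=float)
    if A.shape[0] < 10:
        raise ValueError("scale-free fit requires at least 10 features")
    k = A.sum(axis=0) - np.diag(A)
    if np.ptp(k) == 0:
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        p = mask.mean()
        if mean_k > 0 and p > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(p))
    if len(xs) < 3 or np.ptp(xs) == 0:
        return float("nan")
    fit = linregress(xs, ys)
    r2 = fit.rvalue**2
    return float(-r2 if fit.slope > 0 else r2)


def tom_dissimilarity(
    adjacency: pd.DataFrame | np.ndarray, mode: str = "tom"
) -> pd.DataFrame:
    """Topological-overlap dissimilarity ``1 - TOM`` (or ``1 - adjacency``).

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    the sum over shared neighbors ``u != i, j`` and ``k`` the connectivity
    excluding the diagonal.
    """
    adj = pd.DataFrame(adjacency).astype(float)
    A = adj.to_numpy()
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if A.min() < 0 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if mode == "adjacency":
        D = 1.0 - A
        np.fill_diagonal(D, 0.0)
        return pd.DataFrame(D, index=adj.index, columns=adj.columns)
    if mode != "tom":
        raise ValueError(f"unknown dissimilarity mode {mode!r}")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=0)
    shared = A0 @ A0
    denom = np.minimum.outer(k, k) + 1.0 - A0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + A0) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    D = np.clip(1.0 - tom, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=adj.index, columns=adj.columns)


# -------------------------------------------------- dynamic hybrid tree cut


class _Tree:
    """Per-node bookkeeping over a scipy linkage matrix."""

    def __init__(self, Z: np.ndarray, n_leaves: int):
        self.Z = Z
        self.n = n_leaves
        self.height = Z[:, 2]
        self.leaves: list[list[int]] = [[i] for i in range(n_leaves)]
        self.merges: list[list[float]] = [[] for _ in range(n_leaves)]
        for i in range(Z.shape[0]):
            l, r = int(Z[i, 0]), int(Z[i, 1])
            self.leaves.append(self.leaves[l] + self.leaves[r])
            self.merges.append(sorted(self.merges[l] + self.merges[r] + [Z[i, 2]]))
        self.parent = np.full(n_leaves + Z.shape[0], -1, dtype=int)
        for i in range(Z.shape[0]):
            self.parent[int(Z[i, 0])] = n_leaves + i
            self.parent[int(Z[i, 1])] = n_leaves + i

    def is_leaf(self, node: int) -> bool:
        return node < self.n

    def children(self, node: int) -> tuple[int, int]:
        row = self.Z[node - self.n]
        return int(row[0]), int(row[1])

    def node_height(self, node: int) -> float:
        return 0.0 if self.is_leaf(node) else float(self.Z[node - self.n, 2])

    def size(self, node: int) -> int:
        return len(self.leaves[node])

    def core_scatter(self, node: int, min_cluster_size: int) -> float:
        """Mean height of the lowest merges forming the branch core."""
        if self.is_leaf(node):
            return 0.0
        size = self.size(node)
        core = int(min_cluster_size / 2 + 1)
        if core < size:
            core = int(core + np.sqrt(size - core))
        core = min(core, size)
        k = max(core - 1, 1)
        return float(np.mean(self.merges[node][:k]))


def cut_dynamic_hybrid(
    dissimilarity: pd.DataFrame | np.ndarray,
    min_cluster_size: int = 5,
    deep_split: int = 2,
    cut_height: float | None = None,
    pam_stage: bool = True,
    pam_max_dissimilarity: float | None = None,
) -> np.ndarray:
    """Dynamic hybrid cut of an average-linkage tree built from ``dissimilarity``.

    Adaptive branch identification: descending from each subtree below
    ``cut_height`` (default 99% of the tallest merge), a branch qualifies as
    a distinct cluster when it has at least ``min_cluster_size`` members,
    its core scatter (mean height of the lowest core merges) stays below a
    deep-split-dependent ceiling, and it is separated from its attachment
    point by a minimum gap. ``deep_split`` in 0-4 raises the scatter ceiling
    and shrinks the gap, splitting more aggressively. Unassigned elements
    (label 0) are then attached to the nearest eligible cluster by mean
    dissimilarity (PAM-like stage), provided that distance does not exceed
    ``pam_max_dissimilarity`` (default ``cut_height``). Labels are renumbered
    by decreasing cluster size.
    """
    D = np.asarray(pd.DataFrame(dissimilarity), dtype=float)
    n = D.shape[0]
    if not (0 <= deep_split <= 4):
        raise ValueError("deep_split must lie in [0, 4]")
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be at least 2")
    if n < min_cluster_size:
        return np.zeros(n, dtype=int)

    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    tree = _Tree(Z, n)
    heights = Z[:, 2]
    hmax = float(heights.max())
    if hmax == 0.0:
        return np.zeros(n, dtype=int)
    if cut_height is None:
        cut_height = 0.99 * hmax
    ref = float(np.quantile(heights, 0.05))
    max_core_scatter = float(np.interp(deep_split, range(5), _CORE_SCATTER_GRID))
    min_gap = (1.0 - max_core_scatter) * 0.75
    max_abs_scatter = ref + max_core_scatter * (cut_height - ref)
    min_abs_gap = min_gap * (cut_height - ref)

    def qualifies(node: int, attach_height: float) -> bool:
        if tree.size(node) < min_cluster_size:
            return False
        scatter = tree.core_scatter(node, min_cluster_size)
        return scatter <= max_abs_scatter and (attach_height - scatter) >= min_abs_gap

    def collect(node: int, attach_height: float) -> list[int]:
        """Cluster branches detected inside ``node`` (attached at ``attach_height``)."""
        if tree.is_leaf(node):
            return []
        h = tree.node_height(node)
        left, right = tree.children(node)
        found = []
        for child in (left, right):
            sub = collect(child, h)
            if sub:
                found.extend(sub)
            elif qualifies(child, h):
                found.append(child)
        if found:
            return found
        return [node] if qualifies(node, attach_height) else []

    # static cut: subtree roots whose own merge is below cut_height but
    # whose parent merge (if any) lies above it
    roots = []
    total = n + Z.shape[0]
    for node in range(total):
        if tree.node_height(node) > cut_height:
            continue
        par = tree.parent[node]
        if par == -1 or tree.node_height(par) > cut_height:
            roots.append(node)

    clusters: list[list[int]] = []
    for root in roots:
        par = tree.parent[root]
        attach = tree.node_height(par) if par != -1 else cut_height
        for branch in collect(root, attach):
            clusters.append(tree.leaves[branch])

    labels = np.zeros(n, dtype=int)
    for ci, members in enumerate(clusters, start=1):
        labels[members] = ci

    if pam_stage and clusters:
        limit = cut_height if pam_max_dissimilarity is None else pam_max_dissimilarity
        unassigned = np.where(labels == 0)[0]
        assign = {}
        for i in unassigned:
            dists = [D[i, members].mean() for members in clusters]
            best = int(np.argmin(dists))
            if dists[best] <= limit:
                assign[i] = best + 1
        for i, ci in assign.items():
            labels[i] = ci

    return _relabel_by_size(labels)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber positive labels by decreasing cluster size (ties: old label)."""
    out = np.zeros_like(labels)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    order = sorted(zip(-counts, ids))
    for new, (_, old) in enumerate(order, start=1):
        out[labels == old] = new
    return out


# -------------------------------------------------------------- eigengenes


def compute_eigengenes(
    data: pd.DataFrame,
    labels,
    prefix: str = "C",
) -> pd.DataFrame:
    """Cluster eigengenes: first principal component of the standardized
    member profiles, unit variance, sign-oriented to correlate positively
    with the mean member profile. Singleton clusters return their own
    standardized profile. Columns are named ``<prefix>-<label>``.
    """
    df = pd.DataFrame(data).astype(float)
    labels = np.asarray(labels)
    out = {}
    for cid in sorted(set(labels[labels > 0])):
        members = df.loc[:, labels == cid]
        std = (members - members.mean()) / members.std(ddof=1).replace(0.0, 1.0)
        if std.shape[1] == 1:
            e = std.iloc[:, 0].to_numpy()
        else:
            u, s, _ = np.linalg.svd(std.to_numpy(), full_matrices=False)
            e = u[:, 0] * s[0]
        sd = e.std(ddof=1)
        if sd > 0:
            e = (e - e.mean()) / sd
        mean_profile = std.mean(axis=1).to_numpy()
        if np.dot(e, mean_profile) < 0:
            e = -e
        out[f"{prefix}-{cid}"] = e
    return pd.DataFrame(out, index=df.index)


# --------------------------------------------------------------- utilities


def log_transform(values: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """Natural-log transform for positive-valued omics tables.

    ``pseudocount`` defaults to half the smallest nonzero value of the table.
    """
    df = pd.DataFrame(values).astype(float)
    if (df < 0).any().any():
        raise ValueError("log transform requires non-negative data")
    if pseudocount is None:
        nonzero = df.to_numpy()[df.to_numpy() > 0]
        pseudocount = nonzero.min() / 2.0 if nonzero.size else 1.0
    return np.log(df + pseudocount)


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Newick text for an inspection-friendly dump of the dendrogram."""
    names = list(leaf_names)
    n = len(names)

    def build(node: int) -> str:
        if node < n:
            return names[node]
        row = Z[node - n]
        h = row[2]
        l, r = build(int(row[0])), build(int(row[1]))
        hl = 0.0 if int(row[0]) < n else Z[int(row[0]) - n, 2]
        hr = 0.0 if int(row[1]) < n else Z[int(row[1]) - n, 2]
        return f"({l}:{h - hl:.6g},{r}:{h - hr:.6g})"

    return build(n + Z.shape[0] - 1) + ";"


# ---------------------------------------------------------------- estimator


class CoabundanceClusterer(BaseEstimator, ClusterMixin):
    """Co-abundance clustering of features as a scikit-learn estimator.

    ``fit(X)`` takes a samples x features table and clusters the *features*
    (not the samples): biweight midcorrelation -> signed soft-threshold
    adjacency -> TOM dissimilarity -> average linkage -> dynamic hybrid cut
    -> eigengenes.

    Attributes set by ``fit``: ``labels_`` (per-feature cluster ids, 0 =
    unassigned), ``eigengenes_`` (samples x clusters, unit variance),
    ``correlation_``, ``adjacency_``, ``dissimilarity_``, ``linkage_``,
    ``scale_free_r2_``.
    """

    def __init__(
        self,
        beta: int = 6,
        min_cluster_size: int = 5,
        deep_split: int = 2,
        dissimilarity: str = "tom",
        log_transform: bool = False,
        pseudocount: float | None = None,
        cut_height: float | None = None,
        pam_stage: bool = True,
        cluster_prefix: str = "C",
    ):
        self.beta = beta
        self.min_cluster_size = min_cluster_size
        self.deep_split = deep_split
        self.dissimilarity = dissimilarity
        self.log_transform = log_transform
        self.pseudocount = pseudocount
        self.cut_height = cut_height
        self.pam_stage = pam_stage
        self.cluster_prefix = cluster_prefix

    def fit(self, X, y=None):
        df = pd.DataFrame(X).astype(float)
        if df.shape[0] < 4:
            raise ValueError("need at least 4 samples")
        work = log_transform(df, self.pseudocount) if self.log_transform else df
        self.correlation_ = bicor_matrix(work)
        self.adjacency_ = signed_adjacency(self.correlation_, self.beta)
        self.dissimilarity_ = tom_dissimilarity(self.adjacency_, mode=self.dissimilarity)
        self.labels_ = cut_dynamic_hybrid(
            self.dissimilarity_,
            min_cluster_size=self.min_cluster_size,
            deep_split=self.deep_split,
            cut_height=self.cut_height,
            pam_stage=self.pam_stage,
        )
        self.eigengenes_ = compute_eigengenes(work, self.labels_, self.cluster_prefix)
        self.linkage_ = hierarchy.linkage(
            squareform(self.dissimilarity_.to_numpy(), checks=False), method="average"
        )
        self.feature_names_in_ = np.asarray(df.columns)
        try:
            self.scale_free_r2_ = scale_free_fit(self.adjacency_)
        except ValueError:
            self.scale_free_r2_ = float("nan")
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def labels_series(self) -> pd.Series:
        return pd.Series(self.labels_, index=self.feature_names_in_, name="cluster")

    def dendrogram_newick(self) -> str:
        return linkage_to_newick(self.linkage_, self.feature_names_in_)
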
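"""Eigengene-host correlation, significance tiers, and the staged
metabolite reduction cascade.

All associations are Spearman rank correlations; each correlation family
(one heat map or network input) is Benjamini-Hochberg adjusted on its own,
and FDR tiers are marked ``*`` (< 0.05), ``†`` (< 0.01), ``‡`` (< 0.001).

The reduction cascade mirrors the study design: from the retention > 35 s
metabolite universe inside deprivation-associated clusters, keep features
whose correlation with the duration of feed deprivation survives FDR < 0.01,
then keep features with an absolute log2 fed/deprived fold change of at
least ``fc_log2`` (1 = twofold, 2 = fourfold).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import CORR_COLUMNS, FeatureMatrix
from .preprocess import adjust_bh

__all__ = [
    "spearman",
    "star_tier",
    "correlate_eigengenes_hosts",
    "deprivation_associated",
    "reduce_metabolites",
    "correlate_molecular",
    "CascadeReport",
    "heatmap_matrix",
]


# ---------------------------------------------------------------- spearman


@lru_cache(maxsize=4)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int64)


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with a two-sided p-value.

    Missing pairs are dropped pairwise. For n <= ``exact_max_n`` the
    p-value is an exact permutation probability (all n! pairings);
    otherwise the usual t approximation is used. Constant input yields
    ``(nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_pearson(rx, ry)
    if n <= exact_max_n:
        perms = _all_permutations(n)
        rho_null = _rank_pearson_many(rx, ry[perms])
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
    else:
        t = rho * np.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return float(rho), min(p, 1.0)


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def _rank_pearson_many(rx: np.ndarray, ry_rows: np.ndarray) -> np.ndarray:
    rx = rx - rx.mean()
    ry = ry_rows - ry_rows.mean(axis=1, keepdims=True)
    num = ry @ rx
    den = np.sqrt((rx @ rx) * (ry**2).sum(axis=1))
    return num / den


def star_tier(fdr: float) -> str:
    """FDR significance tier: ``‡`` < 0.001, ``†`` < 0.01, ``*`` < 0.05."""
    if np.isnan(fdr):
        return ""
    if fdr < 0.001:
        return "‡"
    if fdr < 0.01:
        return "†"
    if fdr < 0.05:
        return "*"
    return ""


def _corr_family(
    pairs: list[tuple[str, str, str, str]],
    col_a: pd.DataFrame,
    col_b: pd.DataFrame,
    exact_max_n: int = 9,
) -> pd.DataFrame:
    """Long-form Spearman table over ``pairs`` with one BH family."""
    rows = []
    for a, ta, b, tb in pairs:
        rho, p = spearman(col_a[a], col_b[b], exact_max_n=exact_max_n)
        rows.append((a, ta, b, tb, rho, p))
    table = pd.DataFrame(rows, columns=list(CORR_COLUMNS[:6]))
    valid = table["p"].notna()
    fdr = np.full(len(table), np.nan)
    if valid.any():
        fdr[valid.to_numpy()] = adjust_bh(table.loc[valid, "p"].to_numpy())
    table["fdr"] = fdr
    table["star"] = [star_tier(f) for f in table["fdr"]]
    return table


# ----------------------------------------------- eigengene-host correlation


def correlate_eigengenes_hosts(
    eigengenes: pd.DataFrame,
    host_params: pd.DataFrame,
) -> pd.DataFrame:
    """All pairwise eigengene x host Spearman correlations, one BH family.

    ``host_params`` should include the duration of feed deprivation as a
    column if it is to be treated as a host parameter. The returned table
    carries the hierarchical host ordering (average linkage on correlation
    distance between the hosts' correlation profiles) in
    ``table.attrs["host_order"]``.
    """
    shared = eigengenes.index.intersection(host_params.index)
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    eg = eigengenes.loc[shared]
    hp = host_params.loc[shared]
    pairs = [
        (c, "cluster", h, "host") for c in eg.columns for h in hp.columns
    ]
    table = _corr_family(pairs, eg, hp)
    table.attrs["host_order"] = _cluster_order(
        heatmap_matrix(table, index="entity_b", columns="entity_a")
    )
    table.attrs["family"] = "eigengene_host"
    return table


def heatmap_matrix(
    table: pd.DataFrame, index: str = "entity_b", columns: str = "entity_a"
) -> pd.DataFrame:
    """Pivot a long-form correlation table into a rho matrix."""
    return table.pivot_table(index=index, columns=columns, values="rho")


def _cluster_order(mat: pd.DataFrame) -> list[str]:
    """Row ordering by average-linkage clustering on correlation distance."""
    if mat.shape[0] < 3:
        return list(mat.index)
    filled = mat.fillna(0.0)
    cor = np.corrcoef(filled.to_numpy())
    dist = np.clip(1.0 - cor, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return [mat.index[i] for i in hierarchy.leaves_list(Z)]


def deprivation_associated(
    table: pd.DataFrame, duration_id: str = "duration_min", fdr: float = 0.05
) -> list[str]:
    """Cluster ids whose eigengene-duration correlation is FDR-significant."""
    sub = table[(table["entity_b"] == duration_id) & (table["fdr"] < fdr)]
    return sorted(sub["entity_a"].tolist())


# -------------------------------------------------------- reduction cascade


@dataclass
class CascadeReport:
    """Stage-by-stage record of the metabolite reduction cascade."""

    n_universe: int
    n_after_duration_filter: int
    n_after_fc_filter: int
    universe_ids: list[str]
    duration_ids: list[str]
    fc_ids: list[str]
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (
            self.n_universe >= self.n_after_duration_filter >= self.n_after_fc_filter
        ):
            raise ValueError("cascade stages must be nested")

    def to_dict(self) -> dict:
        return {
            "n_universe": self.n_universe,
            "n_after_duration_filter": self.n_after_duration_filter,
            "n_after_fc_filter": self.n_after_fc_filter,
            "universe_ids": self.universe_ids,
            "duration_ids": self.duration_ids,
            "fc_ids": self.fc_ids,
            "thresholds": self.thresholds,
        }


def reduce_metabolites(
    metabolites: FeatureMatrix,
    cluster_labels: pd.Series,
    flagged_clusters,
    retention_min_s: float = 35.0,
    duration_fdr: float = 0.01,
    fc_log2: float = 1.0,
    duration_scope: str = "all",
) -> CascadeReport:
    """Staged reduction of the metabolite universe.

    Stage 0: metabolite features with retention time strictly above
    ``retention_min_s`` that belong to one of the ``flagged_clusters``
    (the deprivation-associated co-abundance clusters). Stage 1: features
    whose Spearman correlation with duration of feed deprivation survives
    BH FDR < ``duration_fdr``, the FDR family being the stage-0 universe.
    ``duration_scope`` is ``'all'`` (both groups; fed coded as duration 0)
    or ``'deprived'`` (deprived animals only). Stage 2: features whose
    absolute log2 (deprived mean / fed mean) fold change is >= ``fc_log2``
    (boundary included). Retained sets are nested by construction.
    """
    rts = metabolites.feature_meta["retention_time_s"]
    if rts.isna().any():
        raise ValueError("retention times are required for all metabolites")
    flagged = set(flagged_clusters)
    labels = cluster_labels.reindex(metabolites.features)
    universe = [
        f
        for f in metabolites.features
        if rts[f] > retention_min_s and labels[f] in flagged
    ]

    duration = metabolites.duration()
    groups = metabolites.groups()
    values = metabolites.values
    if duration_scope == "deprived":
        mask = (groups == "deprived").to_numpy()
    elif duration_scope == "all":
        mask = np.ones(len(groups), dtype=bool)
    else:
        raise ValueError("duration_scope must be 'all' or 'deprived'")

    pvals = []
    for f in universe:
        _, p = spearman(values[f].to_numpy()[mask], duration.to_numpy()[mask])
        pvals.append(p)
    keep_duration = []
    if universe:
        arr = np.asarray(pvals)
        valid = ~np.isnan(arr)
        fdr = np.full(arr.size, np.nan)
        if valid.any():
            fdr[valid] = adjust_bh(arr[valid])
        keep_duration = [f for f, q in zip(universe, fdr) if q < duration_fdr]

    fed = values.loc[groups == "fed"]
    dep = values.loc[groups == "deprived"]
    keep_fc = []
    for f in keep_duration:
        mf, md = fed[f].mean(), dep[f].mean()
        if mf <= 0 or md <= 0:
            pc = values[f][values[f] > 0].min() / 2.0 if (values[f] > 0).any() else 1.0
            warnings.warn(f"nonpositive group mean for {f!r}; pseudocount applied")
            mf, md = mf + pc, md + pc
        # boundary is inclusive; the 1e-9 slack keeps the >= rule robust to
        # floating-point summation when the true fold change sits exactly
        # at the threshold
        if abs(np.log2(md / mf)) >= fc_log2 - 1e-9:
            keep_fc.append(f)

    return CascadeReport(
        n_universe=len(universe),
        n_after_duration_filter=len(keep_duration),
        n_after_fc_filter=len(keep_fc),
        universe_ids=list(universe),
        duration_ids=list(keep_duration),
        fc_ids=list(keep_fc),
        thresholds={
            "retention_min_s": retention_min_s,
            "duration_fdr": duration_fdr,
            "fc_log2": fc_log2,
            "duration_scope": duration_scope,
        },
    )


# ------------------------------------------------- molecular correlations


def correlate_molecular(
    molecular: pd.DataFrame,
    molecular_types: pd.Series,
    host_params: pd.DataFrame,
    include_host_host: bool = True,
) -> pd.DataFrame:
    """Cross-type Spearman correlations of molecular features (retained
    metabolites, OTUs of deprivation-associated clusters, lipid cluster
    members) against host parameters, plus host-host pairs, in one BH
    family. Entity types travel with each row so the network layer can
    apply per-tier thresholds. Self-pairings are excluded.
    """
    shared = molecular.index.intersection(host_params.index)
    mol = molecular.loc[shared]
    hp = host_params.loc[shared]
    pairs = [
        (h, "host", m, str(molecular_types[m]))
        for h in hp.columns
        for m in mol.columns
    ]
    if include_host_host:
        pairs += [
            (a, "host", b, "host")
            for i, a in enumerate(hp.columns)
            for b in hp.columns[i + 1 :]
        ]
    both = pd.concat([hp, mol], axis=1)
    table = _corr_family(pairs, both, both)
    table.attrs["family"] = "molecular_host"
    return table
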
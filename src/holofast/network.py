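"""Tiered-threshold correlation networks and graph export.

Edges come from a long-form Spearman correlation table and must pass both
an FDR gate (< 0.05) and a tier-specific absolute-rho cut that depends on
the endpoint types: host-metabolite |rho| > 0.8, host-OTU and host-lipid
|rho| > 0.7, host-host |rho| > 0.6 (strict inequalities). Edge sign is the
sign of rho (red = positive, blue = negative by convention). Molecular-
molecular pairs (e.g. metabolite-OTU) are excluded from the default
network; a flag admits them at a configurable cut.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_TIER_CUTS",
    "edge_tier",
    "build_host_subnetwork",
    "build_tiered_network",
    "detect_modules",
    "export_graph",
]

DEFAULT_TIER_CUTS = {
    "host_metabolite": 0.8,
    "host_otu": 0.7,
    "host_lipid": 0.7,
    "host_host": 0.6,
}

_CANONICAL = {"otu_ileum": "otu", "otu_cecum": "otu", "otu_colon": "otu"}


def _canonical_type(t: str) -> str:
    return _CANONICAL.get(str(t), str(t))


def edge_tier(type_a: str, type_b: str) -> str | None:
    """Tier name for an endpoint-type pair; None for untiered pairs."""
    a, b = _canonical_type(type_a), _canonical_type(type_b)
    if a == b == "host":
        return "host_host"
    if "host" in (a, b):
        other = b if a == "host" else a
        tier = f"host_{other}"
        return tier if tier in DEFAULT_TIER_CUTS else None
    return None


def _add_edges(
    graph: nx.Graph,
    table: pd.DataFrame,
    cuts: dict[str, float],
    fdr: float,
    molecular_cut: float | None,
) -> None:
    skipped = 0
    for row in table.itertuples(index=False):
        a, b = row.entity_a, row.entity_b
        if a == b:
            continue
        rho, q = row.rho, row.fdr
        if np.isnan(rho) or np.isnan(q):
            continue
        tier = edge_tier(row.type_a, row.type_b)
        if tier is None:
            if molecular_cut is None:
                skipped += 1
                continue
            tier = "molecular"
            cut = molecular_cut
        else:
            cut = cuts[tier]
        if abs(rho) > cut and q < fdr:
            graph.add_node(a, type=_canonical_type(row.type_a))
            graph.add_node(b, type=_canonical_type(row.type_b))
            graph.add_edge(
                a,
                b,
                rho=float(rho),
                fdr=float(q),
                sign=int(np.sign(rho)),
                color="red" if rho > 0 else "blue",
                tier=tier,
            )
    if skipped:
        logger.info("excluded %d untiered (molecular-molecular) pairs", skipped)


def build_host_subnetwork(
    host_table: pd.DataFrame, rho_cut: float = 0.6, fdr: float = 0.05
) -> nx.Graph:
    """Host-host correlation subnetwork: edges with |rho| > ``rho_cut`` and
    FDR below ``fdr``."""
    graph = nx.Graph()
    sub = host_table[
        (host_table["type_a"].map(_canonical_type) == "host")
        & (host_table["type_b"].map(_canonical_type) == "host")
    ]
    _add_edges(graph, sub, {"host_host": rho_cut}, fdr, molecular_cut=None)
    detect_modules(graph)
    return graph


def build_tiered_network(
    table: pd.DataFrame,
    cuts: dict[str, float] | None = None,
    fdr: float = 0.05,
    molecular_cut: float | None = None,
) -> nx.Graph:
    """Multi-omics network with per-tier |rho| cuts (strict) and an FDR gate.

    ``molecular_cut`` admits molecular-molecular edges at the given cut;
    by default they are excluded.
    """
    merged = dict(DEFAULT_TIER_CUTS)
    if cuts:
        unknown = set(cuts) - set(merged)
        if unknown:
            raise ValueError(f"unknown tier(s): {sorted(unknown)}")
        merged.update(cuts)
    graph = nx.Graph()
    _add_edges(graph, table, merged, fdr, molecular_cut)
    detect_modules(graph)
    return graph


def detect_modules(graph: nx.Graph, method: str = "components") -> dict:
    """Module labels, numbered by decreasing module size (ties broken by the
    lexicographically smallest member for determinism). Stored on the nodes
    as the ``module`` attribute and returned as a dict."""
    if method == "components":
        groups = [sorted(c) for c in nx.connected_components(graph)]
    elif method == "greedy":
        groups = [sorted(c) for c in nx.community.greedy_modularity_communities(graph)]
    else:
        raise ValueError(f"unknown module detection method {method!r}")
    groups.sort(key=lambda g: (-len(g), g[0] if g else ""))
    modules = {}
    for i, members in enumerate(groups, start=1):
        for node in members:
            modules[node] = i
    nx.set_node_attributes(graph, modules, "module")
    return modules


def export_graph(graph: nx.Graph, path: str, fmt: str = "graphml") -> str:
    """Write the graph as GraphML (lossless attributes), SIF
    (``source pos_corr|neg_corr target``), or an edge TSV."""
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for a, b, data in graph.edges(data=True):
                rel = "pos_corr" if data.get("sign", 1) > 0 else "neg_corr"
                fh.write(f"{a}\t{rel}\t{b}\n")
    elif fmt == "edge_tsv":
        rows = [
            {
                "source": a,
                "target": b,
                "rho": d.get("rho"),
                "sign": d.get("sign"),
                "tier": d.get("tier"),
                "fdr": d.get("fdr"),
                "module": graph.nodes[a].get("module"),
            }
            for a, b, d in graph.edges(data=True)
        ]
        pd.DataFrame(
            rows, columns=["source", "target", "rho", "sign", "tier", "fdr", "module"]
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path
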
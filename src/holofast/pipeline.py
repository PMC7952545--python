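"""End-to-end pipeline orchestration from a single configuration.

Stages: synthetic cohort (or TSV input) -> preprocessing (OTU filter,
alpha diversity, per-feature group statistics) -> per-dataset co-abundance
clustering -> eigengene-host integration and the metabolite reduction
cascade -> tiered correlation networks -> optional butyrate-capacity
calls. Every intermediate table is written as TSV/JSON and declared in a
provenance manifest; identical config + seed reproduces identical bytes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .butyrate import best_hits, classify_pathways, cv_similarity_cutoff
from .coabundance import CoabundanceClusterer
from .containers import Cohort
from .integrate import (
    correlate_eigengenes_hosts,
    correlate_molecular,
    deprivation_associated,
    reduce_metabolites,
)
from .network import build_host_subnetwork, build_tiered_network, export_graph
from .preprocess import adjust_bh, alpha_diversity, compare_groups_table, filter_otus, zscore
from .synthetic import CohortConfig, PlantedCluster, generate_cohort, generate_hit_table

logger = logging.getLogger(__name__)

OMICS_DATASETS = ("metabolite", "lipid", "otu_ileum", "otu_cecum", "otu_colon")

#: per-dataset soft-threshold powers
DEFAULT_BETA = {
    "metabolite": 8,
    "lipid": 6,
    "otu_ileum": 14,
    "otu_cecum": 7,
    "otu_colon": 9,
}
#: per-dataset minimum cluster sizes (lipid panel is small)
DEFAULT_MIN_SIZE = {
    "metabolite": 5,
    "lipid": 3,
    "otu_ileum": 5,
    "otu_cecum": 5,
    "otu_colon": 5,
}
#: per-dataset branch-split sensitivity
DEFAULT_DEEP_SPLIT = {
    "metabolite": 4,
    "lipid": 4,
    "otu_ileum": 2,
    "otu_cecum": 2,
    "otu_colon": 2,
}
#: cluster naming prefixes per dataset, by decreasing cluster size
CLUSTER_PREFIX = {
    "metabolite": "Me",
    "lipid": "Lipids",
    "otu_ileum": "Ileum-OTU",
    "otu_cecum": "Cecum-OTU",
    "otu_colon": "Colon-OTU",
}
#: datasets log-transformed before the biweight midcorrelation
LOG_TRANSFORMED = ("metabolite", "lipid")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Single-file configuration for :func:`run_pipeline`."""

    outdir: str = "holofast_out"
    seed: int = 0
    synthetic: bool = True
    cohort: CohortConfig | None = None
    input_dir: str | None = None
    otu_min_mean_fraction: float = 0.0002
    otu_min_prevalence: float = 0.5
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    min_cluster_size: dict = field(default_factory=lambda: dict(DEFAULT_MIN_SIZE))
    deep_split: dict = field(default_factory=lambda: dict(DEFAULT_DEEP_SPLIT))
    eigengene_fdr: float = 0.05
    retention_min_s: float = 35.0
    duration_fdr: float = 0.01
    fc_log2: float = 1.0
    molecular_fdr: float = 0.05
    tier_cuts: dict | None = None
    hits_path: str | None = None
    hit_labels_path: str | None = None
    butyrate_folds: int = 5
    synthetic_hits: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", None)
        cfg = cls(**raw)
        if cohort_raw is not None:
            planted = cohort_raw.pop("planted_clusters", None)
            cohort = CohortConfig(**cohort_raw)
            if planted is not None:
                cohort = cohort.replace(
                    planted_clusters=tuple(PlantedCluster(**p) for p in planted)
                )
            cfg.cohort = cohort
        if seed is not None:
            cfg.seed = seed
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort is not None:
            d["cohort"] = dataclasses.asdict(self.cohort)
            d["cohort"]["planted_clusters"] = [
                dataclasses.asdict(p) for p in self.cohort.planted_clusters
            ]
        return d


def run_pipeline(config: PipelineConfig) -> str:
    """Execute all stages; returns the output directory."""
    os.makedirs(config.outdir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log_path = os.path.join(config.outdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("holofast")
    root.addHandler(handler)

    outputs: list[str] = [log_path]
    captured: list[str] = []
    manifest: dict = {
        "seed": config.seed,
        "parameters": config.to_jsonable(),
        "versions": _versions(),
        "fdr_families": [],
        "warnings": captured,
        "outputs": outputs,
    }
    stage = "setup"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            stage = "cohort"
            if config.synthetic:
                cohort_cfg = (config.cohort or CohortConfig()).replace(seed=config.seed)
                cohort, truth = generate_cohort(cohort_cfg)
                outputs += hio.write_cohort(cohort, os.path.join(config.outdir, "cohort"))
                outputs += hio.write_ground_truth(
                    truth, os.path.join(config.outdir, "cohort")
                )
            else:
                if not config.input_dir:
                    raise ValueError("input_dir is required when synthetic mode is off")
                datasets = [
                    ds
                    for ds in OMICS_DATASETS + ("host",)
                    if os.path.exists(os.path.join(config.input_dir, f"{ds}.tsv"))
                ]
                missing = {"metabolite", "lipid", "host"} - set(datasets)
                if missing:
                    raise ValueError(f"missing input matrices: {sorted(missing)}")
                cohort = hio.read_cohort(config.input_dir, datasets)

            stage = "preprocess"
            for ds in list(cohort.matrices):
                if ds.startswith("otu_"):
                    cohort.matrices[ds] = filter_otus(
                        cohort.matrices[ds],
                        config.otu_min_mean_fraction,
                        config.otu_min_prevalence,
                    )
                    div = alpha_diversity(cohort.matrices[ds])
                    p = os.path.join(config.outdir, f"{ds}.alpha_diversity.tsv")
                    div.to_csv(p, sep="\t", index_label="sample")
                    outputs.append(p)
            host_stats = compare_groups_table(cohort["host"])
            manifest["fdr_families"].append(
                {"family": "host_group_comparison", "n_tests": int(len(host_stats))}
            )
            p = os.path.join(config.outdir, "host.group_stats.tsv")
            host_stats.to_csv(p, sep="\t")
            outputs.append(p)

            stage = "coabundance"
            eigengene_frames = []
            labels_frames = []
            models: dict[str, CoabundanceClusterer] = {}
            for ds in OMICS_DATASETS:
                if ds not in cohort:
                    continue
                fm = cohort[ds]
                model = CoabundanceClusterer(
                    beta=config.beta[ds],
                    min_cluster_size=config.min_cluster_size[ds],
                    deep_split=config.deep_split[ds],
                    log_transform=ds in LOG_TRANSFORMED,
                    cluster_prefix=CLUSTER_PREFIX[ds],
                ).fit(fm.values)
                models[ds] = model
                eigengene_frames.append(model.eigengenes_)
                lab = model.labels_series().to_frame()
                lab.insert(0, "dataset", ds)
                lab["cluster_name"] = [
                    f"{CLUSTER_PREFIX[ds]}-{c}" if c > 0 else ""
                    for c in model.labels_
                ]
                labels_frames.append(lab)
                p = os.path.join(config.outdir, f"{ds}.dendrogram.nwk")
                with open(p, "w") as fh:
                    fh.write(model.dendrogram_newick() + "\n")
                outputs.append(p)
            eigengenes = pd.concat(eigengene_frames, axis=1)
            labels = pd.concat(labels_frames)
            p = os.path.join(config.outdir, "cluster_labels.tsv")
            labels.to_csv(p, sep="\t", index_label="feature")
            outputs.append(p)
            p = os.path.join(config.outdir, "eigengenes.tsv")
            eigengenes.to_csv(p, sep="\t", index_label="sample")
            outputs.append(p)

            stage = "integrate"
            host_fm = cohort["host"]
            hosts = host_fm.values.copy()
            hosts["duration_min"] = host_fm.duration()
            eg_table = correlate_eigengenes_hosts(eigengenes, hosts)
            manifest["fdr_families"].append(
                {"family": "eigengene_host", "n_tests": int(len(eg_table))}
            )
            p = os.path.join(config.outdir, "eigengene_host_correlations.tsv")
            eg_table.to_csv(p, sep="\t", index=False)
            outputs.append(p)
            p = os.path.join(config.outdir, "eigengene_host_heatmap.tsv")
            hm = eg_table.pivot_table(index="entity_b", columns="entity_a", values="rho")
            hm = hm.reindex(eg_table.attrs["host_order"])
            hm.to_csv(p, sep="\t")
            outputs.append(p)
            p = os.path.join(config.outdir, "host_zscores.tsv")
            zscore(hosts).to_csv(p, sep="\t", index_label="sample")
            outputs.append(p)

            flagged = deprivation_associated(eg_table, fdr=config.eigengene_fdr)
            met_labels = labels.loc[labels["dataset"] == "metabolite", "cluster_name"]
            cascade = reduce_metabolites(
                cohort["metabolite"],
                met_labels,
                [c for c in flagged if c.startswith("Me-")],
                retention_min_s=config.retention_min_s,
                duration_fdr=config.duration_fdr,
                fc_log2=config.fc_log2,
            )
            manifest["fdr_families"].append(
                {"family": "metabolite_duration", "n_tests": cascade.n_universe}
            )
            manifest["deprivation_associated_clusters"] = flagged
            p = os.path.join(config.outdir, "cascade.json")
            with open(p, "w") as fh:
                json.dump(cascade.to_dict(), fh, indent=1, sort_keys=True)
            outputs.append(p)

            molecular_cols: dict[str, str] = {
                f: "metabolite" for f in cascade.fc_ids
            }
            for ds in OMICS_DATASETS[2:]:  # OTU sites
                if ds not in cohort:
                    continue
                sub = labels[(labels["dataset"] == ds) & (labels["cluster"] > 0)]
                flagged_ds = sub["cluster_name"].isin(flagged)
                molecular_cols.update({f: "otu" for f in sub.index[flagged_ds]})
            lip = labels[(labels["dataset"] == "lipid") & (labels["cluster"] > 0)]
            molecular_cols.update(
                {f: "lipid" for f in lip.index[lip["cluster_name"].isin(flagged)]}
            )
            molecular = pd.concat(
                [cohort[ds].values for ds in OMICS_DATASETS if ds in cohort], axis=1
            )[list(molecular_cols)]

            # host response parameters associated with feed deprivation:
            # hosts whose duration correlation is FDR-significant (own family)
            from .integrate import spearman  # local import avoids cycle confusion

            dur = host_fm.duration().to_numpy()
            host_p = {
                h: spearman(host_fm.values[h].to_numpy(), dur)[1]
                for h in host_fm.values.columns
            }
            hp_ids = list(host_p)
            host_fdr = adjust_bh(np.array([host_p[h] for h in hp_ids]))
            sel_hosts = [h for h, q in zip(hp_ids, host_fdr) if q < 0.05]
            manifest["fdr_families"].append(
                {"family": "host_duration_screen", "n_tests": len(hp_ids)}
            )
            if not sel_hosts:
                captured.append("no duration-associated hosts; using all hosts")
                sel_hosts = hp_ids
            manifest["deprivation_associated_hosts"] = sel_hosts

            mol_table = correlate_molecular(
                molecular,
                pd.Series(molecular_cols),
                host_fm.values[sel_hosts],
            )
            manifest["fdr_families"].append(
                {"family": "molecular_host", "n_tests": int(len(mol_table))}
            )
            p = os.path.join(config.outdir, "molecular_host_correlations.tsv")
            mol_table.to_csv(p, sep="\t", index=False)
            outputs.append(p)

            stage = "network"
            host_net = build_host_subnetwork(mol_table, fdr=config.molecular_fdr)
            tiered = build_tiered_network(
                mol_table, cuts=config.tier_cuts, fdr=config.molecular_fdr
            )
            for name, graph in (("host_subnetwork", host_net), ("tiered_network", tiered)):
                for fmt, ext in (("graphml", "graphml"), ("sif", "sif"), ("edge_tsv", "edges.tsv")):
                    p = os.path.join(config.outdir, f"{name}.{ext}")
                    export_graph(graph, p, fmt)
                    outputs.append(p)

            stage = "butyrate"
            if config.hits_path or config.synthetic_hits:
                if config.hits_path:
                    hits = hio.read_hit_table(config.hits_path)
                    if not config.hit_labels_path:
                        raise ValueError("hit_labels_path is required with hits_path")
                    lab = pd.read_csv(config.hit_labels_path, sep="\t", index_col=0)
                else:
                    hits, lab = generate_hit_table(120, 0.5, 0.5, seed=config.seed)
                    outputs.append(
                        hio.write_hit_table(hits, os.path.join(config.outdir, "hits.tsv"))
                    )
                best = best_hits(hits)
                merged = best.join(lab, how="inner")
                sims = np.concatenate(
                    [merged["ptb"].fillna(0), merged["buk"].fillna(0), merged["but"].fillna(0)]
                )
                labels_cv = np.concatenate(
                    [
                        merged["kinase_positive"],
                        merged["kinase_positive"],
                        merged["transferase_positive"],
                    ]
                )
                cutoff = cv_similarity_cutoff(
                    sims, labels_cv, folds=config.butyrate_folds, random_state=config.seed
                )
                calls = classify_pathways(hits, cutoff)
                p = os.path.join(config.outdir, "butyrate_calls.tsv")
                calls.to_csv(p, sep="\t")
                outputs.append(p)
                manifest["butyrate_cutoff"] = cutoff

        captured.extend(str(w.message) for w in caught)
    except Exception as exc:  # noqa: BLE001 - stage name is part of the contract
        root.removeHandler(handler)
        handler.close()
        raise StageError(stage, exc) from exc

    manifest_path = os.path.join(config.outdir, "manifest.json")
    outputs.append(manifest_path)
    manifest["outputs"] = sorted(os.path.relpath(p, config.outdir) for p in outputs)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    root.removeHandler(handler)
    handler.close()
    return config.outdir


def _versions() -> dict:
    import networkx
    import scipy
    import sklearn
    import statsmodels

    from . import __version__

    return {
        "holofast": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
        "networkx": networkx.__version__,
    }
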
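"""Plain-text (TSV) readers and writers for the pipeline's tables.

Feature matrices are written feature-major (features as rows, samples as
columns, header row of sample ids), the orientation bioinformatics tools
conventionally exchange; in memory the package works samples x features.
"""

from __future__ import annotations

import os

import pandas as pd

from .containers import Cohort, FeatureMatrix, GroundTruth


def write_feature_matrix(fm: FeatureMatrix, prefix: str) -> list[str]:
    """Write ``<prefix>.tsv`` (features x samples) and ``<prefix>.features.tsv``."""
    values_path = f"{prefix}.tsv"
    meta_path = f"{prefix}.features.tsv"
    fm.values.T.to_csv(values_path, sep="\t", index_label="feature")
    fm.feature_meta.to_csv(meta_path, sep="\t", index_label="feature")
    return [values_path, meta_path]


def read_feature_matrix(prefix: str, sample_meta: pd.DataFrame) -> FeatureMatrix:
    values = pd.read_csv(f"{prefix}.tsv", sep="\t", index_col="feature").T
    meta = pd.read_csv(
        f"{prefix}.features.tsv", sep="\t", index_col="feature", keep_default_na=False
    )
    if "retention_time_s" in meta.columns:
        meta["retention_time_s"] = pd.to_numeric(
            meta["retention_time_s"], errors="coerce"
        )
    return FeatureMatrix(values, meta, sample_meta)


def write_sample_meta(sample_meta: pd.DataFrame, path: str) -> str:
    sample_meta.to_csv(path, sep="\t", index_label="sample")
    return path


def read_sample_meta(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_cohort(cohort: Cohort, outdir: str) -> list[str]:
    """Write every dataset of a cohort plus the sample metadata; return paths."""
    os.makedirs(outdir, exist_ok=True)
    written = [write_sample_meta(cohort.sample_meta, os.path.join(outdir, "samples.tsv"))]
    for name, fm in cohort.matrices.items():
        written += write_feature_matrix(fm, os.path.join(outdir, name))
    return written


def read_cohort(outdir: str, datasets) -> Cohort:
    sample_meta = read_sample_meta(os.path.join(outdir, "samples.tsv"))
    matrices = {
        name: read_feature_matrix(os.path.join(outdir, name), sample_meta)
        for name in datasets
    }
    return Cohort(matrices, sample_meta)


def write_ground_truth(truth: GroundTruth, outdir: str) -> list[str]:
    os.makedirs(outdir, exist_ok=True)
    paths = []
    p = os.path.join(outdir, "truth_membership.tsv")
    pd.Series(truth.cluster_membership, name="cluster").rename_axis("feature").to_csv(
        p, sep="\t"
    )
    paths.append(p)
    p = os.path.join(outdir, "truth_latents.tsv")
    lat = truth.cluster_latents.copy()
    lat.insert(0, "deprivation_factor", truth.latent_factor)
    lat.to_csv(p, sep="\t", index_label="sample")
    paths.append(p)
    p = os.path.join(outdir, "truth_edges.tsv")
    pd.DataFrame(
        [(a, b, s, m) for (a, b), s, m in truth.planted_edges],
        columns=["entity_a", "entity_b", "sign", "magnitude"],
    ).to_csv(p, sep="\t", index=False)
    paths.append(p)
    p = os.path.join(outdir, "truth_differential.tsv")
    pd.Series(sorted(truth.differential_features), name="feature").to_csv(
        p, sep="\t", index=False
    )
    paths.append(p)
    return paths


def write_hit_table(hits: pd.DataFrame, path: str) -> str:
    """3-column homology-hit TSV: enzyme_class, taxon, percent_similarity."""
    hits.to_csv(path, sep="\t", index=False)
    return path


def read_hit_table(path: str) -> pd.DataFrame:
    hits = pd.read_csv(path, sep="\t")
    expected = ["enzyme_class", "taxon", "percent_similarity"]
    if list(hits.columns[:3]) != expected:
        raise ValueError(f"hit table must have columns {expected}, got {list(hits.columns)}")
    return hits
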
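"""Shared in-memory containers for the multi-omics bundle.

The pipeline moves four kinds of tables around: per-dataset feature
matrices (samples x features, with per-feature metadata such as taxonomy or
chromatographic retention time), a shared sample-metadata table (feeding
group and duration of feed deprivation), long-form correlation tables, and
the ground-truth ledger emitted by the synthetic cohort generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: canonical dataset labels used throughout the package
DATASETS = ("otu_ileum", "otu_cecum", "otu_colon", "metabolite", "lipid", "host")

#: entity types used by the correlation/network layers
ENTITY_TYPES = ("host", "metabolite", "otu", "lipid")

#: columns of a long-form correlation table
CORR_COLUMNS = ("entity_a", "type_a", "entity_b", "type_b", "rho", "p", "fdr", "star")


@dataclass
class FeatureMatrix:
    """A samples x features table plus feature- and sample-level metadata.

    Parameters
    ----------
    values : DataFrame, shape (n_samples, n_features)
        Numeric measurements; rows are samples, columns features.
    feature_meta : DataFrame indexed by feature id
        Must carry a ``dataset`` column (one of :data:`DATASETS`); may carry
        ``taxonomy``, ``retention_time_s`` (seconds) and ``tissue``.
    sample_meta : DataFrame indexed by sample id
        Must carry ``group`` (``fed``/``deprived``) and ``duration_min``.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        if not self.feature_meta.index.equals(self.values.columns):
            self.feature_meta = self.feature_meta.reindex(self.values.columns)
        missing = self.values.index.difference(self.sample_meta.index)
        if len(missing):
            raise ValueError(f"samples missing from sample_meta: {list(missing)}")

    @property
    def features(self) -> pd.Index:
        return self.values.columns

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def dataset(self) -> str:
        ds = self.feature_meta["dataset"].unique()
        return ds[0] if len(ds) == 1 else "mixed"

    def subset_features(self, ids) -> "FeatureMatrix":
        ids = [i for i in self.values.columns if i in set(ids)]  # keep order
        return FeatureMatrix(
            self.values[ids], self.feature_meta.loc[ids], self.sample_meta
        )

    def groups(self) -> pd.Series:
        return self.sample_meta.loc[self.values.index, "group"]

    def duration(self) -> pd.Series:
        return self.sample_meta.loc[self.values.index, "duration_min"]


@dataclass
class Cohort:
    """Bundle of per-dataset feature matrices sharing one sample-metadata table."""

    matrices: dict[str, FeatureMatrix]
    sample_meta: pd.DataFrame

    def __getitem__(self, dataset: str) -> FeatureMatrix:
        return self.matrices[dataset]

    def __contains__(self, dataset: str) -> bool:
        return dataset in self.matrices

    @property
    def samples(self) -> pd.Index:
        return self.sample_meta.index


@dataclass
class GroundTruth:
    """Ledger of everything the synthetic generator planted.

    ``latent_factor`` is the per-sample deprivation factor (a monotone
    function of feed-deprivation duration); ``cluster_latents`` holds the
    per-cluster latent variables the planted features load on.
    """

    cluster_membership: dict[str, str]
    latent_factor: pd.Series
    cluster_latents: pd.DataFrame
    planted_edges: list[tuple[tuple[str, str], int, float]]
    differential_features: set[str] = field(default_factory=set)

    def members(self, cluster_id: str) -> list[str]:
        return [f for f, c in self.cluster_membership.items() if c == cluster_id]

    def __post_init__(self) -> None:
        planted = set(self.cluster_membership.values())
        missing = planted.difference(self.cluster_latents.columns)
        if missing:
            raise ValueError(f"planted cluster ids without a latent: {sorted(missing)}")
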
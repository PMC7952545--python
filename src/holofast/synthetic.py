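"""Seeded synthetic cohorts with planted multi-omics structure.

The generator emulates a two-group feed-deprivation study in obese mice:
``n_fed`` ad-libitum animals and ``n_deprived`` animals deprived of feed for
a known duration (minutes). A per-sample latent *deprivation factor* is a
monotone (standardized) function of duration; planted co-abundance clusters
are noisy linear loadings on cluster-specific latent variables, a stated
subset of which load on the deprivation factor. Every planted signal is
recorded in a :class:`~holofast.containers.GroundTruth` ledger so recovery
can be scored exactly.

Data models per dataset
-----------------------
* OTU tables (ileum/cecum/colon): log-normal intensities closed to relative
  abundances (rows sum to 1), reproducing compositionality and heavy tails.
* Metabolites: strictly positive log-normal features with chromatographic
  retention times; a configurable fraction exceeds 35 s. Group effects are
  planted multiplicatively after equalizing pre-effect group means, so
  log2 fold changes are exact by construction.
* Lipids: a small log-normal panel with one planted cluster.
* Host parameters: gaussian markers, a subset loading on the deprivation
  factor and/or shifted between groups in SD units.

Loading calibration: a cluster member is ``sqrt(r)*latent + sqrt(1-r)*noise``
with unit-variance pieces, so the expected pairwise Pearson correlation of
two members equals the configured within-cluster target ``r`` exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Cohort, FeatureMatrix, GroundTruth

_TISSUES = ("liver", "eWAT", "ileum", "colon", "plasma", "cecum")
_FAMILIES = (
    "Porphyromonadaceae",
    "Lachnospiraceae",
    "Rikenellaceae;Alistipes",
    "Bacteroidales",
    "Enterococcaceae",
    "Staphylococcaceae",
    "Ruminococcaceae",
)

#: enzyme classes of the butyrate-production screen
ENZYMES = ("ptb", "buk", "but", "4hbt")


@dataclass(frozen=True)
class PlantedCluster:
    """One planted co-abundance cluster.

    ``within_corr`` is the target pairwise correlation of members (0, 1);
    ``latent_loading`` is the loading of the cluster latent on the
    deprivation factor (0 = deprivation-independent cluster); ``log2_fc``
    plants a multiplicative fed/deprived group effect on every member
    (meaningful for positive-valued datasets).
    """

    dataset: str
    n_members: int
    within_corr: float
    latent_loading: float
    log2_fc: float = 0.0


def _default_planted() -> tuple[PlantedCluster, ...]:
    """Default planted structure: 17 metabolite clusters (5 loading opposite
    to deprivation, echoing fed-associated clusters), one ileal and one cecal
    OTU cluster, four colonic OTU clusters, one lipid cluster."""
    met = []
    for i in range(17):
        if i < 5:
            loading, fc = -0.75, 0.0  # fed-associated clusters
        elif i < 9:
            loading, fc = 0.75, 2.0
        elif i < 11:
            loading, fc = 0.75, -2.0
        else:
            loading, fc = 0.7, 0.0
        met.append(PlantedCluster("metabolite", 12, 0.8, loading, fc))
    otus = [
        PlantedCluster("otu_ileum", 15, 0.7, 0.8),
        PlantedCluster("otu_cecum", 20, 0.7, 0.8),
        PlantedCluster("otu_colon", 16, 0.7, 0.85),
        PlantedCluster("otu_colon", 16, 0.7, 0.75),
        PlantedCluster("otu_colon", 16, 0.7, 0.7),
        PlantedCluster("otu_colon", 16, 0.7, 0.65),
    ]
    lip = [PlantedCluster("lipid", 5, 0.8, -0.8)]
    return tuple(met + otus + lip)


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated study: 10 fed + 9 feed-deprived animals,
    deprivation spanning 496-692 min (8 h 16 min to 11 h 32 min), ~300
    metabolite features of which ~92% have retention time above 35 s, a
    small liver-lipid panel and ~100 host markers.
    """

    n_fed: int = 10
    n_deprived: int = 9
    duration_range_min: tuple[float, float] = (496.0, 692.0)
    n_otus_per_site: dict[str, int] = field(
        default_factory=lambda: {"ileum": 60, "cecum": 60, "colon": 80}
    )
    n_metabolites: int = 300
    n_lipids: int = 12
    n_host_params: int = 100
    planted_clusters: tuple[PlantedCluster, ...] = field(default_factory=_default_planted)
    effect_sizes: dict[str, float] | None = None
    n_deprivation_hosts: int = 10
    n_fed_hosts: int = 6
    host_latent_loading: float = 0.8
    host_group_shift_sd: float = 1.5
    noise_sd: float = 0.5
    retention_fraction_above_35s: float = 0.92
    seed: int = 0

    def validate(self) -> None:
        if self.n_fed < 3 or self.n_deprived < 3:
            raise ValueError("need at least 3 samples per group")
        lo, hi = self.duration_range_min
        if not lo < hi:
            raise ValueError("duration range lower bound must be below upper bound")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.retention_fraction_above_35s <= 1:
            raise ValueError("retention fraction must be in [0, 1]")
        counts = {
            "metabolite": self.n_metabolites,
            "lipid": self.n_lipids,
            "host": self.n_host_params,
        }
        for site, n in self.n_otus_per_site.items():
            counts[f"otu_{site}"] = n
        for pc in self.planted_clusters:
            if not 0 < pc.within_corr < 1:
                raise ValueError("within-cluster correlation target must be in (0, 1)")
            if pc.dataset not in counts:
                raise ValueError(f"planted cluster references unknown dataset {pc.dataset!r}")
        for ds, n in counts.items():
            planted = sum(p.n_members for p in self.planted_clusters if p.dataset == ds)
            if planted > n:
                raise ValueError(
                    f"{ds}: planted members ({planted}) exceed feature count ({n})"
                )

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)


def _loaded_members(rng, factor, n_samples, cluster: PlantedCluster):
    """Cluster latent + member matrix in standard-normal space."""
    lam = cluster.latent_loading
    latent = lam * factor + np.sqrt(1.0 - lam**2) * rng.standard_normal(n_samples)
    a = np.sqrt(cluster.within_corr)
    noise = rng.standard_normal((n_samples, cluster.n_members))
    members = a * latent[:, None] + np.sqrt(1.0 - cluster.within_corr) * noise
    return latent, members


def _plant_exact_fc(values: np.ndarray, is_deprived: np.ndarray, log2_fc: float) -> np.ndarray:
    """Equalize pre-effect group means, then shift the deprived group so the
    empirical deprived/fed mean ratio equals 2**log2_fc exactly."""
    out = values.copy()
    fed_mean = out[~is_deprived].mean()
    dep_mean = out[is_deprived].mean()
    out[is_deprived] *= (fed_mean / dep_mean) * 2.0**log2_fc
    return out


def generate_cohort(config: CohortConfig) -> tuple[Cohort, GroundTruth]:
    """Generate one seeded cohort plus its ground-truth ledger."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_fed + config.n_deprived

    sample_ids = [f"fed_{i + 1:02d}" for i in range(config.n_fed)] + [
        f"dep_{i + 1:02d}" for i in range(config.n_deprived)
    ]
    lo, hi = config.duration_range_min
    durations = np.concatenate(
        [np.zeros(config.n_fed), np.sort(rng.uniform(lo, hi, config.n_deprived))]
    )
    is_deprived = np.array([s.startswith("dep") for s in sample_ids])
    sample_meta = pd.DataFrame(
        {
            "group": np.where(is_deprived, "deprived", "fed"),
            "duration_min": durations,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    # deprivation factor: standardized duration (monotone in duration;
    # fed animals share the minimum, coded as duration 0)
    factor = (durations - durations.mean()) / durations.std(ddof=0)
    latent_factor = pd.Series(factor, index=sample_meta.index, name="deprivation_factor")

    membership: dict[str, str] = {}
    latents: dict[str, np.ndarray] = {}
    edges: list[tuple[tuple[str, str], int, float]] = []
    differential: set[str] = set()

    sizes = {
        "metabolite": config.n_metabolites,
        "lipid": config.n_lipids,
        "host": config.n_host_params,
    }
    for site, n_otus in config.n_otus_per_site.items():
        sizes[f"otu_{site}"] = n_otus

    # standard-normal latent space per dataset, planted clusters first
    zspace: dict[str, np.ndarray] = {}
    fc_plan: dict[str, dict[int, float]] = {ds: {} for ds in sizes}
    cluster_counter: dict[str, int] = {}
    for ds, total in sizes.items():
        z = rng.standard_normal((n, total))
        col = 0
        for pc in config.planted_clusters:
            if pc.dataset != ds:
                continue
            cluster_counter[ds] = cluster_counter.get(ds, 0) + 1
            cid = f"{ds}-pc{cluster_counter[ds]}"
            latent, members = _loaded_members(rng, factor, n, pc)
            z[:, col : col + pc.n_members] = members
            latents[cid] = latent
            for j in range(col, col + pc.n_members):
                fc_plan[ds][j] = pc.log2_fc
            for j in range(pc.n_members):
                membership[f"{ds}_{col + j + 1:03d}"] = cid
            if pc.latent_loading != 0.0:
                edges.append(
                    ((cid, "duration_min"), int(np.sign(pc.latent_loading)), abs(pc.latent_loading))
                )
            col += pc.n_members
        zspace[ds] = z

    sigma = config.noise_sd
    matrices: dict[str, FeatureMatrix] = {}

    def _feature_ids(ds, total):
        return [f"{ds}_{j + 1:03d}" for j in range(total)]

    # ---- OTU tables: log-normal intensities closed to relative abundances
    for site in config.n_otus_per_site:
        ds = f"otu_{site}"
        total = sizes[ds]
        mu = rng.normal(0.0, 1.5, total)  # heavy-tailed baseline abundances
        intens = np.exp(mu[None, :] + sigma * zspace[ds])
        rel = intens / intens.sum(axis=1, keepdims=True)
        ids = _feature_ids(ds, total)
        meta = pd.DataFrame(
            {
                "dataset": ds,
                "taxonomy": rng.choice(_FAMILIES, total),
                "retention_time_s": np.nan,
                "tissue": site,
            },
            index=pd.Index(ids, name="feature"),
        )
        matrices[ds] = FeatureMatrix(
            pd.DataFrame(rel, index=sample_meta.index, columns=ids), meta, sample_meta
        )

    # ---- metabolites: log-normal with retention times and exact planted FC
    total = sizes["metabolite"]
    mu = rng.uniform(np.log(1e3), np.log(1e5), total)
    vals = np.exp(mu[None, :] + sigma * zspace["metabolite"])
    ids = _feature_ids("metabolite", total)
    for j, fc in fc_plan["metabolite"].items():
        if fc != 0.0:
            vals[:, j] = _plant_exact_fc(vals[:, j], is_deprived, fc)
            differential.add(ids[j])
    n_above = int(round(config.retention_fraction_above_35s * total))
    rts = np.concatenate(
        [rng.uniform(36.0, 600.0, n_above), rng.uniform(5.0, 35.0, total - n_above)]
    )
    rng.shuffle(rts)
    # keep planted clusters inside the retention>35 s universe
    planted_idx = set(fc_plan["metabolite"]) | {
        j for j, f in enumerate(ids) if f in membership
    }
    free_high = [j for j in np.argsort(-rts) if j not in planted_idx and rts[j] > 35.0]
    for j in sorted(planted_idx):
        if rts[j] <= 35.0 and free_high:
            swap = free_high.pop(0)
            rts[j], rts[swap] = rts[swap], rts[j]
    meta = pd.DataFrame(
        {"dataset": "metabolite", "taxonomy": "", "retention_time_s": rts, "tissue": "urine"},
        index=pd.Index(ids, name="feature"),
    )
    matrices["metabolite"] = FeatureMatrix(
        pd.DataFrame(vals, index=sample_meta.index, columns=ids), meta, sample_meta
    )

    # ---- lipids: small log-normal panel
    total = sizes["lipid"]
    mu = rng.uniform(np.log(10.0), np.log(1e3), total)
    vals = np.exp(mu[None, :] + sigma * zspace["lipid"])
    ids = _feature_ids("lipid", total)
    meta = pd.DataFrame(
        {"dataset": "lipid", "taxonomy": "", "retention_time_s": np.nan, "tissue": "liver"},
        index=pd.Index(ids, name="feature"),
    )
    matrices["lipid"] = FeatureMatrix(
        pd.DataFrame(vals, index=sample_meta.index, columns=ids), meta, sample_meta
    )

    # ---- host parameters: gaussian markers, subset loading on the factor
    total = sizes["host"]
    ids = _feature_ids("host", total)
    z = zspace["host"]
    use_default_effects = config.effect_sizes is None
    effect = dict(config.effect_sizes or {})
    k_dep, k_fed = config.n_deprivation_hosts, config.n_fed_hosts
    lam = config.host_latent_loading
    for j in range(total):
        fid = ids[j]
        if j < k_dep:
            load = lam
        elif j < k_dep + k_fed:
            load = -0.8 * lam
        else:
            load = 0.0
        if load != 0.0:
            z[:, j] = load * factor + np.sqrt(1 - load**2) * z[:, j]
            edges.append(((fid, "duration_min"), int(np.sign(load)), abs(load)))
        if use_default_effects and j < k_dep and config.host_group_shift_sd:
            effect[fid] = config.host_group_shift_sd
    for fid, shift in effect.items():
        j = ids.index(fid)
        z[is_deprived, j] += shift
        differential.add(fid)
    meta = pd.DataFrame(
        {
            "dataset": "host",
            "taxonomy": "",
            "retention_time_s": np.nan,
            "tissue": [_TISSUES[j % len(_TISSUES)] for j in range(total)],
        },
        index=pd.Index(ids, name="feature"),
    )
    matrices["host"] = FeatureMatrix(
        pd.DataFrame(z, index=sample_meta.index, columns=ids), meta, sample_meta
    )

    truth = GroundTruth(
        cluster_membership=membership,
        latent_factor=latent_factor,
        cluster_latents=pd.DataFrame(latents, index=sample_meta.index),
        planted_edges=edges,
        differential_features=differential,
    )
    return Cohort(matrices, sample_meta), truth


def make_planted_blocks(
    n_samples: int,
    n_blocks: int = 5,
    block_size: int = 10,
    within_corr: float = 0.85,
    rng: np.random.Generator | int | None = 0,
):
    """Gaussian feature matrix of well-separated co-abundance blocks.

    Returns ``(data, labels, latents)``: samples x features DataFrame,
    1-based block labels per feature, and the per-block latent variables.
    Cross-block correlation is zero in expectation.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    a = np.sqrt(within_corr)
    latents = rng.standard_normal((n_samples, n_blocks))
    cols, labels = [], []
    for b in range(n_blocks):
        noise = rng.standard_normal((n_samples, block_size))
        cols.append(a * latents[:, [b]] + np.sqrt(1 - within_corr) * noise)
        labels += [b + 1] * block_size
    data = pd.DataFrame(
        np.hstack(cols),
        columns=[f"f{j + 1:03d}" for j in range(n_blocks * block_size)],
    )
    lat = pd.DataFrame(latents, columns=[f"block{b + 1}" for b in range(n_blocks)])
    return data, np.array(labels), lat


def make_cascade_fixture(
    n_features: int = 300,
    n_planted: int = 40,
    n_samples: int = 100,
    duration_loading: float = 0.9,
    fold_change: float = 4.0,
    rng: np.random.Generator | int | None = 0,
):
    """Metabolite fixture for the reduction cascade: ``n_planted`` features
    carry both a strong duration correlation and an exact multiplicative
    group shift; the rest are pure log-normal noise. All features sit in one
    flagged cluster with retention time above the 35 s gate.

    Returns ``(FeatureMatrix, cluster_labels, planted_ids)``.
    """
    from .containers import FeatureMatrix  # local to avoid import cycle at module load

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    half = n_samples // 2
    groups = np.array(["fed"] * half + ["deprived"] * (n_samples - half))
    is_dep = groups == "deprived"
    durations = np.concatenate(
        [np.zeros(half), np.sort(rng.uniform(496.0, 692.0, n_samples - half))]
    )
    factor = (durations - durations.mean()) / durations.std(ddof=0)
    lam = duration_loading
    ids = [f"m{j + 1:03d}" for j in range(n_features)]
    cols = {}
    for j, fid in enumerate(ids):
        z = rng.standard_normal(n_samples)
        if j < n_planted:
            z = lam * factor + np.sqrt(1.0 - lam**2) * z
        vals = np.exp(4.0 + 0.5 * z)
        if j < n_planted:
            vals = _plant_exact_fc(vals, is_dep, np.log2(fold_change))
        cols[fid] = vals
    index = pd.Index([f"s{i + 1:03d}" for i in range(n_samples)], name="sample")
    values = pd.DataFrame(cols, index=index)
    sample_meta = pd.DataFrame(
        {"group": groups, "duration_min": durations}, index=index
    )
    meta = pd.DataFrame(
        {
            "dataset": "metabolite",
            "taxonomy": "",
            "retention_time_s": rng.uniform(40.0, 600.0, n_features),
            "tissue": "urine",
        },
        index=pd.Index(ids, name="feature"),
    )
    fm = FeatureMatrix(values, meta, sample_meta)
    labels = pd.Series("Me-1", index=fm.features)
    return fm, labels, ids[:n_planted]


def generate_hit_table(
    n_taxa: int,
    fraction_kinase: float,
    fraction_transferase: float,
    seed: int,
    high_band: tuple[float, float] = (75.0, 95.0),
    low_band: tuple[float, float] = (20.0, 55.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic protein-homology hit table for the butyrate screen.

    Every taxon gets one row per enzyme class; true positives draw percent
    similarity from ``high_band``, decoys from ``low_band``. The 4hbt
    false-positive control is always drawn strictly below the taxon's
    ``but`` similarity for transferase-positive taxa. Label counts are exact
    (``round(n_taxa * fraction)``).
    """
    for frac in (fraction_kinase, fraction_transferase):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    taxa = [f"taxon_{i + 1:03d}" for i in range(n_taxa)]
    n_kin = int(round(n_taxa * fraction_kinase))
    n_tra = int(round(n_taxa * fraction_transferase))
    kin_pos = np.zeros(n_taxa, bool)
    kin_pos[rng.permutation(n_taxa)[:n_kin]] = True
    tra_pos = np.zeros(n_taxa, bool)
    tra_pos[rng.permutation(n_taxa)[:n_tra]] = True

    def draw(band):
        return rng.uniform(*band)

    rows = []
    for i, taxon in enumerate(taxa):
        ptb = draw(high_band if kin_pos[i] else low_band)
        buk = draw(high_band if kin_pos[i] else low_band)
        but = draw(high_band if tra_pos[i] else low_band)
        hbt = draw(low_band)
        if tra_pos[i]:
            while hbt >= but:  # control must not shadow a true transferase hit
                hbt = draw(low_band)
        for enzyme, sim in zip(ENZYMES, (ptb, buk, but, hbt)):
            rows.append((enzyme, taxon, round(float(sim), 2)))
    hits = pd.DataFrame(rows, columns=["enzyme_class", "taxon", "percent_similarity"])
    labels = pd.DataFrame(
        {"kinase_positive": kin_pos, "transferase_positive": tra_pos},
        index=pd.Index(taxa, name="taxon"),
    )
    return hits, labels
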
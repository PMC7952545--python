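"""Spearman machinery, eigengene-host correlation families, and the
staged metabolite reduction cascade."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from holofast.containers import FeatureMatrix
from holofast.integrate import (
    correlate_eigengenes_hosts,
    correlate_molecular,
    deprivation_associated,
    reduce_metabolites,
    spearman,
    star_tier,
)
from holofast.synthetic import CohortConfig, PlantedCluster, generate_cohort


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.arange(1.0, 13.0)
        rho, p = spearman(x, x**3)
        assert rho == pytest.approx(1.0)
        assert p < 1e-6

    def test_reversed_ranks(self):
        x = np.arange(10.0)
        rho, _ = spearman(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_tie_corrected_matches_rank_pearson_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 30))
            x = rng.integers(0, 5, n).astype(float)  # heavy ties
            y = rng.integers(0, 5, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman(x, y)
            oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_matches_scipy_large_n(self, rng):
        x, y = rng.standard_normal((2, 40))
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_small_n_p_matches_enumeration(self, rng):
        # independent brute-force enumeration of all pairings at n=5
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        rho, p = spearman(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = np.corrcoef(rx, ry)[0, 1]
        null = [
            np.corrcoef(rx, np.asarray(perm))[0, 1]
            for perm in itertools.permutations(ry)
        ]
        expected = np.mean([abs(r) >= abs(obs) - 1e-12 for r in null])
        assert rho == pytest.approx(obs)
        assert p == pytest.approx(expected)

    def test_missing_pairs_dropped(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([1.0, 2.0, 3.0, np.nan, 5.0, 6.0])
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(1.0)

    def test_constant_vector_missing(self):
        rho, p = spearman(np.ones(8), np.arange(8.0))
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


def test_star_tier_partition():
    assert star_tier(0.0005) == "‡"
    assert star_tier(0.001) == "†"
    assert star_tier(0.009999) == "†"
    assert star_tier(0.01) == "*"
    assert star_tier(0.049999) == "*"
    assert star_tier(0.05) == ""
    assert star_tier(float("nan")) == ""


class TestEigengeneHostCorrelation:
    def _null_frames(self, rng, n=19, k=5, h=6):
        idx = [f"s{i}" for i in range(n)]
        eg = pd.DataFrame(
            rng.standard_normal((n, k)), index=idx, columns=[f"Me-{j+1}" for j in range(k)]
        )
        hosts = pd.DataFrame(
            rng.standard_normal((n, h)), index=idx, columns=[f"host_{j}" for j in range(h)]
        )
        return eg, hosts

    def test_planted_loading_detected(self, rng):
        n = 100
        idx = [f"s{i}" for i in range(n)]
        duration = np.sort(rng.uniform(0, 600, n))
        factor = (duration - duration.mean()) / duration.std()
        eg = pd.DataFrame(
            {
                "Me-1": 0.9 * factor + np.sqrt(1 - 0.81) * rng.standard_normal(n),
                "Me-2": rng.standard_normal(n),
            },
            index=idx,
        )
        hosts = pd.DataFrame(
            {"duration_min": duration, "h1": rng.standard_normal(n)}, index=idx
        )
        table = correlate_eigengenes_hosts(eg, hosts)
        row = table[(table.entity_a == "Me-1") & (table.entity_b == "duration_min")]
        assert row["rho"].iloc[0] > 0.7
        assert row["fdr"].iloc[0] < 0.05
        assert deprivation_associated(table) == ["Me-1"]

    def test_duplicated_host_gives_perfect_rho(self, rng):
        eg, hosts = self._null_frames(rng)
        eg["dup"] = hosts["host_0"]
        table = correlate_eigengenes_hosts(eg, hosts)
        row = table[(table.entity_a == "dup") & (table.entity_b == "host_0")]
        assert row["rho"].iloc[0] == pytest.approx(1.0)
        assert row["star"].iloc[0] == "‡"

    def test_null_fdr_control(self, rng):
        fractions = []
        for _ in range(200):
            eg, hosts = self._null_frames(rng)
            table = correlate_eigengenes_hosts(eg, hosts)
            fractions.append((table["fdr"] < 0.05).mean())
        mc_se = np.std(fractions) / np.sqrt(len(fractions))
        assert np.mean(fractions) <= 0.05 + 2 * mc_se + 1e-9

    def test_too_few_shared_samples(self, rng):
        eg, hosts = self._null_frames(rng, n=6)
        with pytest.raises(ValueError):
            correlate_eigengenes_hosts(eg.iloc[:3], hosts)

    def test_host_order_attribute(self, rng):
        eg, hosts = self._null_frames(rng)
        table = correlate_eigengenes_hosts(eg, hosts)
        assert sorted(table.attrs["host_order"]) == sorted(hosts.columns)


def _metabolite_fixture(rng, n=60, planted=8, n_samples=100):
    """Small cascade fixture: ``planted`` features carry duration rho ~0.9
    and an exact 4-fold shift; the rest are noise."""
    idx = [f"s{i}" for i in range(n_samples)]
    half = n_samples // 2
    groups = ["fed"] * half + ["deprived"] * (n_samples - half)
    duration = np.concatenate([np.zeros(half), np.sort(rng.uniform(496, 692, n_samples - half))])
    factor = (duration - duration.mean()) / duration.std()
    is_dep = np.array(groups) == "deprived"
    cols = {}
    for j in range(n):
        z = rng.standard_normal(n_samples)
        if j < planted:
            z = 0.9 * factor + np.sqrt(1 - 0.81) * z
        vals = np.exp(3.0 + 0.5 * z)
        if j < planted:
            fed_mean = vals[~is_dep].mean()
            dep_mean = vals[is_dep].mean()
            vals[is_dep] *= (fed_mean / dep_mean) * 4.0
        cols[f"m{j:03d}"] = vals
    values = pd.DataFrame(cols, index=idx)
    sample_meta = pd.DataFrame(
        {"group": groups, "duration_min": duration}, index=values.index
    )
    meta = pd.DataFrame(
        {
            "dataset": "metabolite",
            "taxonomy": "",
            "retention_time_s": 100.0,
            "tissue": "urine",
        },
        index=values.columns,
    )
    labels = pd.Series("Me-1", index=values.columns)
    return FeatureMatrix(values, meta, sample_meta), labels


class TestReduceMetabolites:
    def test_planted_recovery_and_nesting(self, rng):
        fm, labels = _metabolite_fixture(rng)
        report = reduce_metabolites(fm, labels, ["Me-1"], fc_log2=1.0)
        planted = {f"m{j:03d}" for j in range(8)}
        assert set(report.fc_ids) == planted
        assert set(report.fc_ids) <= set(report.duration_ids) <= set(report.universe_ids)
        assert report.n_universe >= report.n_after_duration_filter >= report.n_after_fc_filter

    def test_retention_gate(self, rng):
        fm, labels = _metabolite_fixture(rng)
        fm.feature_meta.loc["m000", "retention_time_s"] = 30.0
        report = reduce_metabolites(fm, labels, ["Me-1"])
        assert "m000" not in report.universe_ids

    def test_cluster_gate(self, rng):
        fm, labels = _metabolite_fixture(rng)
        labels = labels.copy()
        labels["m001"] = "Me-other"
        report = reduce_metabolites(fm, labels, ["Me-1"])
        assert "m001" not in report.universe_ids

    def test_fold_change_boundary_retained(self, rng):
        # planted effect is exactly 4-fold: log2 FC exactly 2 -> kept at fc_log2=2
        fm, labels = _metabolite_fixture(rng)
        report = reduce_metabolites(fm, labels, ["Me-1"], fc_log2=2.0)
        assert set(report.fc_ids) == {f"m{j:03d}" for j in range(8)}

    def test_missing_retention_errors(self, rng):
        fm, labels = _metabolite_fixture(rng)
        fm.feature_meta.loc["m000", "retention_time_s"] = np.nan
        with pytest.raises(ValueError):
            reduce_metabolites(fm, labels, ["Me-1"])


class TestCorrelateMolecular:
    def test_planted_edge_recovered(self, rng):
        n = 100
        idx = [f"s{i}" for i in range(n)]
        latent = rng.standard_normal(n)
        otu = 0.92 * latent + np.sqrt(1 - 0.92**2) * rng.standard_normal(n)
        host = 0.92 * latent + np.sqrt(1 - 0.92**2) * rng.standard_normal(n)
        mol = pd.DataFrame(
            {"otu_1": otu, "noise": rng.standard_normal(n)}, index=idx
        )
        hosts = pd.DataFrame({"h1": host}, index=idx)
        table = correlate_molecular(mol, pd.Series({"otu_1": "otu", "noise": "otu"}), hosts)
        row = table[(table.entity_b == "otu_1")]
        assert row["rho"].iloc[0] > 0.7
        assert row["fdr"].iloc[0] < 0.05

    def test_no_self_pairs(self, rng):
        mol = pd.DataFrame(rng.standard_normal((20, 3)), columns=["a", "b", "c"])
        hosts = pd.DataFrame(rng.standard_normal((20, 2)), columns=["h1", "h2"])
        table = correlate_molecular(mol, pd.Series("otu", index=mol.columns), hosts)
        assert not (table.entity_a == table.entity_b).any()

    def test_host_host_pairs_present_once(self, rng):
        mol = pd.DataFrame(rng.standard_normal((20, 1)), columns=["m"])
        hosts = pd.DataFrame(rng.standard_normal((20, 3)), columns=["h1", "h2", "h3"])
        table = correlate_molecular(mol, pd.Series({"m": "metabolite"}), hosts)
        hh = table[(table.type_a == "host") & (table.type_b == "host")]
        assert len(hh) == 3  # unordered pairs of 3 hosts


def test_cohort_end_to_end_integration(default_cohort):
    """Eigengene-duration association is recovered from the default cohort."""
    from holofast.coabundance import CoabundanceClusterer

    cohort, truth = default_cohort
    fm = cohort["metabolite"]
    model = CoabundanceClusterer(
        beta=8, min_cluster_size=5, deep_split=4, log_transform=True, cluster_prefix="Me"
    ).fit(fm.values)
    hosts = cohort["host"].values.copy()
    hosts["duration_min"] = cohort.sample_meta["duration_min"]
    table = correlate_eigengenes_hosts(model.eigengenes_, hosts)
    assert len(deprivation_associated(table)) >= 1
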
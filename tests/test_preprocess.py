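"""Filtering, normalization, outlier screening, two-group statistics and
diversity, each checked against an independent oracle where one exists."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from holofast.containers import FeatureMatrix
from holofast.preprocess import (
    OTUAbundanceFilter,
    adjust_bh,
    alpha_diversity,
    filter_otus,
    group_compare,
    grubbs_critical_value,
    grubbs_screen,
    normalize_relative_expression,
    zscore,
)

from conftest import naive_bh


def _otu_matrix(values, groups, feature_ids=None):
    values = pd.DataFrame(values)
    if feature_ids is not None:
        values.columns = feature_ids
    values.index = [f"s{i}" for i in range(len(values))]
    sample_meta = pd.DataFrame(
        {"group": groups, "duration_min": 0.0}, index=values.index
    )
    meta = pd.DataFrame(
        {"dataset": "otu_cecum", "taxonomy": "", "retention_time_s": np.nan, "tissue": ""},
        index=values.columns,
    )
    return FeatureMatrix(values, meta, sample_meta)


class TestFilterOtus:
    def test_abundant_feature_retained(self):
        fm = _otu_matrix(
            {"A": [0.001, 0.001, 0.001, 0.001], "B": [0.0, 0.0, 0.0, 0.0]},
            ["fed", "fed", "deprived", "deprived"],
        )
        out = filter_otus(fm)
        assert "A" in out.features  # mean 0.001 >= 0.0002 in both groups
        assert "B" not in out.features  # absent everywhere

    def test_brute_force_equivalence(self, rng):
        n, m = 12, 50
        values = rng.uniform(0, 0.004, (n, m)) * rng.integers(0, 2, (n, m))
        groups = ["fed"] * 6 + ["deprived"] * 6
        fm = _otu_matrix(values, groups, [f"otu{j}" for j in range(m)])
        out = filter_otus(fm, 0.0002, 0.5)
        kept = set(out.features)
        for j, fid in enumerate(fm.features):
            expected_remove = True
            for g in ("fed", "deprived"):
                sub = values[np.array(groups) == g, j]
                low_ab = sub.mean() < 0.0002
                low_prev = (sub > 0).mean() < 0.5
                if not (low_ab and low_prev):
                    expected_remove = False
            assert (fid not in kept) == expected_remove

    def test_idempotent(self, rng):
        values = rng.uniform(0, 0.001, (10, 30)) * rng.integers(0, 2, (10, 30))
        fm = _otu_matrix(values, ["fed"] * 5 + ["deprived"] * 5)
        once = filter_otus(fm)
        twice = filter_otus(once)
        assert list(once.features) == list(twice.features)

    def test_retains_feature_order(self, rng):
        values = rng.uniform(0.001, 0.01, (8, 10))
        fm = _otu_matrix(values, ["fed"] * 4 + ["deprived"] * 4)
        out = filter_otus(fm)
        assert list(out.features) == list(fm.features)

    def test_empty_group_errors(self):
        fm = _otu_matrix({"A": [0.1, 0.2]}, ["fed", "fed"])
        with pytest.raises(ValueError, match="deprived"):
            filter_otus(fm)

    def test_sklearn_transformer_agrees(self, rng):
        values = pd.DataFrame(rng.uniform(0, 0.001, (10, 20)) * rng.integers(0, 2, (10, 20)))
        groups = np.array(["fed"] * 5 + ["deprived"] * 5)
        fm = _otu_matrix(values.to_numpy(), groups)
        est = OTUAbundanceFilter().fit(fm.values, groups)
        assert list(est.transform(fm.values).columns) == list(filter_otus(fm).features)


class TestRelativeExpression:
    def _fm(self, values, groups):
        values = pd.DataFrame(values)
        values.index = [f"s{i}" for i in range(len(values))]
        sm = pd.DataFrame({"group": groups, "duration_min": 0.0}, index=values.index)
        meta = pd.DataFrame({"dataset": "host"}, index=values.columns)
        return FeatureMatrix(values, meta, sm)

    def test_constant_references_and_target(self):
        fm = self._fm(
            {"B2m": [1, 1, 1, 1], "Gapdh": [1, 1, 1, 1], "Ucp1": [2, 2, 2, 2]},
            ["fed", "fed", "deprived", "deprived"],
        )
        out = normalize_relative_expression(fm, ("B2m", "Gapdh"), "fed")
        assert np.allclose(out.values["Ucp1"], 1.0)

    def test_geometric_mean_divisor(self):
        fm = self._fm(
            {"r1": [4.0, 1.0, 1.0], "r2": [9.0, 1.0, 1.0], "t": [12.0, 1.0, 1.0]},
            ["fed", "fed", "deprived"],
        )
        out = normalize_relative_expression(fm, ("r1", "r2"), "fed")
        # sample 0 divisor: sqrt(4*9) = 6 exactly -> 12/6 = 2; fed mean = (2+1)/2
        assert out.values.loc["s0", "t"] == pytest.approx(2.0 / 1.5)

    def test_matches_two_step_hand_computation(self, rng):
        raw = pd.DataFrame(
            rng.uniform(0.5, 4.0, (5, 5)),
            columns=["r1", "r2", "a", "b", "c"],
            index=[f"s{i}" for i in range(5)],
        )
        groups = ["fed", "fed", "fed", "deprived", "deprived"]
        fm = self._fm(raw, groups)
        out = normalize_relative_expression(fm, ("r1", "r2"), "fed")
        for target in ("a", "b", "c"):
            step1 = raw[target] / np.sqrt(raw["r1"] * raw["r2"])
            expected = step1 / step1.iloc[:3].mean()
            assert np.allclose(out.values[target], expected)

    def test_baseline_mean_exactly_one(self, rng):
        raw = pd.DataFrame(
            rng.uniform(0.1, 10, (8, 4)), columns=["r1", "r2", "x", "y"],
            index=[f"s{i}" for i in range(8)],
        )
        fm = self._fm(raw, ["fed"] * 4 + ["deprived"] * 4)
        out = normalize_relative_expression(fm, ("r1", "r2"), "fed")
        base = out.values.iloc[:4].mean()
        assert np.allclose(base, 1.0, atol=1e-12)

    def test_nonpositive_reference_names_sample(self):
        fm = self._fm(
            {"r1": [1.0, 0.0, 1.0], "r2": [1.0, 1.0, 1.0], "t": [1.0, 1.0, 1.0]},
            ["fed", "fed", "deprived"],
        )
        with pytest.raises(ValueError, match="s1"):
            normalize_relative_expression(fm, ("r1", "r2"), "fed")


class TestGrubbs:
    def test_flags_extreme_point(self):
        x = [8.0, 9.0, 10.0, 11.0, 50.0]
        # brute-force oracle: G and critical value from the t formula
        arr = np.array(x)
        g = np.max(np.abs(arr - arr.mean())) / arr.std(ddof=1)
        n = arr.size
        t2 = stats.t.ppf(1 - 0.05 / (2 * n), n - 2) ** 2
        crit = (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))
        assert g > crit
        assert grubbs_screen(x) == 4

    def test_zero_variance_flags_nothing(self):
        assert grubbs_screen([1.0, 1.0, 1.0, 1.0]) is None

    def test_decision_matches_formula_oracle(self, rng):
        for _ in range(200):
            x = rng.standard_normal(rng.integers(3, 15))
            dev = np.abs(x - x.mean())
            g = dev.max() / x.std(ddof=1)
            expected = int(np.argmax(dev)) if g > grubbs_critical_value(x.size) else None
            assert grubbs_screen(x) == expected

    def test_never_flags_more_than_one(self, rng):
        # two symmetric extremes: at most the single largest is flagged
        x = np.array([0.0, 0.1, -0.1, 0.05, 30.0, -30.000001])
        assert grubbs_screen(x) in (None, 5)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            grubbs_screen([1.0, 2.0])


class TestGroupCompare:
    def test_extreme_separation(self):
        values = pd.Series([1, 2, 3, 101, 102, 103], index=list("abcdef"), dtype=float)
        groups = pd.Series(["fed"] * 3 + ["deprived"] * 3, index=values.index)
        res = group_compare(values, groups)
        assert res.p < 0.01

    def test_heavy_tailed_routes_to_mann_whitney(self, rng):
        heavy = np.exp(3.0 * np.concatenate([rng.standard_normal(15), rng.standard_normal(15)]))
        values = pd.Series(heavy, index=[f"s{i}" for i in range(30)])
        groups = pd.Series(["fed"] * 15 + ["deprived"] * 15, index=values.index)
        res = group_compare(values, groups, grubbs_alpha=None)
        assert res.test_used == "mann_whitney"

    def test_constant_data_degenerate(self):
        values = pd.Series([5.0] * 8, index=[f"s{i}" for i in range(8)])
        groups = pd.Series(["fed"] * 4 + ["deprived"] * 4, index=values.index)
        res = group_compare(values, groups)
        assert res.p == 1.0 and res.degenerate

    def test_null_type_one_error(self, rng):
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            values = pd.Series(rng.standard_normal(12), index=[f"s{i}" for i in range(12)])
            groups = pd.Series(["fed"] * 6 + ["deprived"] * 6, index=values.index)
            if group_compare(values, groups, grubbs_alpha=None).p < 0.05:
                hits += 1
        assert hits / n_sim <= 0.06  # not significant in >= 94% of null draws

    def test_grubbs_outlier_recorded(self):
        values = pd.Series(
            [1.0, 1.1, 0.9, 1.05, 50.0, 2.0, 2.1, 1.9, 2.05, 2.02],
            index=[f"s{i}" for i in range(10)],
        )
        groups = pd.Series(["fed"] * 5 + ["deprived"] * 5, index=values.index)
        res = group_compare(values, groups)
        assert res.outliers_removed == ("s4",)


class TestAdjustBH:
    def test_worked_vector(self):
        out = adjust_bh([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(out, 0.05)

    def test_single_p_unchanged(self):
        assert adjust_bh([0.037])[0] == pytest.approx(0.037)

    def test_oracle_equivalence(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            assert np.allclose(adjust_bh(p), naive_bh(p), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_dominates_input_and_capped(self, p):
        out = adjust_bh(p)
        assert (out >= np.asarray(p) - 1e-15).all()
        assert (out <= 1.0).all()

    def test_order_preserving_under_permutation(self, rng):
        p = rng.uniform(0, 1, 20)
        perm = rng.permutation(20)
        assert np.allclose(adjust_bh(p)[perm], adjust_bh(p[perm]))


class TestAlphaDiversity:
    def test_single_otu_zero_entropy(self):
        out = alpha_diversity(pd.DataFrame({"a": [5.0], "b": [0.0]}))
        assert out["shannon"].iloc[0] == 0.0
        assert out["richness"].iloc[0] == 1

    def test_uniform_case(self):
        out = alpha_diversity(pd.DataFrame([[1.0, 1.0, 1.0, 1.0]]))
        assert out["shannon"].iloc[0] == pytest.approx(np.log(4))

    def test_matches_skbio_oracle(self, rng):
        from skbio.diversity.alpha import shannon

        counts = rng.integers(0, 50, (6, 12))
        ours = alpha_diversity(pd.DataFrame(counts))
        for i in range(6):
            assert ours["shannon"].iloc[i] == pytest.approx(
                shannon(counts[i], base=np.e), abs=1e-12
            )

    def test_all_zero_sample_warns(self):
        with pytest.warns(UserWarning):
            out = alpha_diversity(pd.DataFrame([[0.0, 0.0]]))
        assert out["shannon"].iloc[0] == 0.0 and out["richness"].iloc[0] == 0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            alpha_diversity(pd.DataFrame([[-1.0, 2.0]]))


class TestZscore:
    def test_basic(self):
        out = zscore(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert out["x"].mean() == pytest.approx(0.0)
        assert out["x"].std(ddof=1) == pytest.approx(1.0)

    def test_constant_feature_zeroed_with_warning(self):
        with pytest.warns(UserWarning):
            out = zscore(pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]}))
        assert (out["c"] == 0).all()

    def test_column_means_vanish(self, rng):
        out = zscore(pd.DataFrame(rng.uniform(0, 9, (20, 8))))
        assert (out.mean().abs() < 1e-12).all()
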
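"""Feature filtering, normalization, outlier screening and two-group statistics.

The screening conventions follow the emulated study protocol: OTUs are
dropped only when they fail both an abundance and a prevalence criterion in
both groups; at most one outlier per group is removed by a two-sided Grubbs
test (alpha = 0.05) before group comparison; features pass a per-group
Shapiro-Wilk normality check to choose between Student's t and Mann-Whitney;
p-values are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .containers import FeatureMatrix

__all__ = [
    "filter_otus",
    "OTUAbundanceFilter",
    "normalize_relative_expression",
    "grubbs_screen",
    "grubbs_critical_value",
    "group_compare",
    "compare_groups_table",
    "adjust_bh",
    "alpha_diversity",
    "zscore",
    "GroupStatResult",
]


# ---------------------------------------------------------------- OTU filter


def _otu_keep_mask(
    values: pd.DataFrame,
    groups: pd.Series,
    min_mean_fraction: float,
    min_prevalence: float,
    join: str,
) -> pd.Series:
    """Per-feature keep mask. A feature is removed when it is both rare
    (group mean relative abundance below ``min_mean_fraction``) and sparse
    (present, i.e. abundance strictly > 0, in fewer than ``min_prevalence``
    of samples) in *both* groups; ``join='or'`` removes when either
    criterion alone holds in both groups."""
    low_abund = pd.DataFrame(index=values.columns)
    low_prev = pd.DataFrame(index=values.columns)
    for g in ("fed", "deprived"):
        sub = values.loc[groups == g]
        if sub.empty:
            raise ValueError(f"group {g!r} has no samples")
        low_abund[g] = sub.mean(axis=0) < min_mean_fraction
        low_prev[g] = (sub > 0).mean(axis=0) < min_prevalence
    if join == "and":
        remove = low_abund.all(axis=1) & low_prev.all(axis=1)
    elif join == "or":
        remove = low_abund.all(axis=1) | low_prev.all(axis=1)
    else:
        raise ValueError(f"join must be 'and' or 'or', got {join!r}")
    return ~remove


def filter_otus(
    otu: FeatureMatrix,
    min_mean_fraction: float = 0.0002,
    min_prevalence: float = 0.5,
    join: str = "and",
) -> FeatureMatrix:
    """Drop rare-and-sparse OTUs (defaults: 0.02% mean abundance, 50% prevalence)."""
    keep = _otu_keep_mask(
        otu.values, otu.groups(), min_mean_fraction, min_prevalence, join
    )
    if not keep.any():
        warnings.warn("all OTU features removed by the abundance/prevalence filter")
    return otu.subset_features(keep.index[keep])


class OTUAbundanceFilter(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping :func:`filter_otus`.

    ``fit(X, y)`` takes a samples x features DataFrame and the per-sample
    group labels; ``transform`` keeps the selected columns.
    """

    def __init__(self, min_mean_fraction: float = 0.0002, min_prevalence: float = 0.5,
                 join: str = "and"):
        self.min_mean_fraction = min_mean_fraction
        self.min_prevalence = min_prevalence
        self.join = join

    def fit(self, X: pd.DataFrame, y=None):
        if y is None:
            raise ValueError("group labels are required to fit the OTU filter")
        keep = _otu_keep_mask(
            pd.DataFrame(X),
            pd.Series(np.asarray(y), index=pd.DataFrame(X).index),
            self.min_mean_fraction,
            self.min_prevalence,
            self.join,
        )
        self.keep_mask_ = keep.to_numpy()
        self.selected_features_ = keep.index[keep]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X).loc[:, self.keep_mask_]


# -------------------------------------------------- relative expression


def normalize_relative_expression(
    raw: FeatureMatrix,
    reference_ids: tuple[str, str],
    baseline_group: str = "fed",
) -> FeatureMatrix:
    """Reference-gene normalization of expression data.

    Each target feature is divided per-sample by the geometric mean of the
    two reference features, then scaled so the baseline-group mean equals 1
    exactly. Reference features are dropped from the output.
    """
    ref_a, ref_b = reference_ids
    for ref in (ref_a, ref_b):
        if ref not in raw.values.columns:
            raise ValueError(f"reference feature {ref!r} not present")
        bad = raw.values.index[raw.values[ref] <= 0]
        if len(bad):
            raise ValueError(
                f"nonpositive reference value for {ref!r} in sample {bad[0]!r}"
            )
    divisor = np.sqrt(raw.values[ref_a] * raw.values[ref_b])
    targets = [c for c in raw.values.columns if c not in (ref_a, ref_b)]
    rel = raw.values[targets].div(divisor, axis=0)
    base = rel.loc[raw.groups() == baseline_group].mean(axis=0)
    if (base == 0).any():
        raise ValueError("baseline-group mean of zero; cannot scale to 1")
    rel = rel.div(base, axis=1)
    return FeatureMatrix(rel, raw.feature_meta.loc[targets], raw.sample_meta)


# ------------------------------------------------------------ Grubbs screen


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided single-outlier Grubbs critical value from the t distribution."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_screen(values, alpha: float = 0.05) -> int | None:
    """Index of the single most extreme point if it fails the two-sided
    Grubbs test at ``alpha``; ``None`` otherwise. Never flags more than one
    point. Zero-variance input flags nothing."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs screening requires at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        return None
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = dev[idx] / sd
    return idx if g > grubbs_critical_value(n, alpha) else None


# ------------------------------------------------------- group comparison


@dataclass
class GroupStatResult:
    """Outcome of one two-group feature comparison."""

    feature: str
    test_used: str  # "t" or "mann_whitney"
    statistic: float
    p: float
    fdr: float = np.nan
    outliers_removed: tuple[str, ...] = field(default_factory=tuple)
    degenerate: bool = False


def group_compare(
    values: pd.Series,
    groups: pd.Series,
    normality_alpha: float = 0.05,
    grubbs_alpha: float | None = 0.05,
    feature: str = "",
) -> GroupStatResult:
    """Two-sided t test (if both groups pass Shapiro-Wilk at
    ``normality_alpha``) or Mann-Whitney test, after removing at most one
    Grubbs outlier per group."""
    values = pd.Series(values).astype(float)
    groups = pd.Series(groups, index=values.index)
    samples = {g: values[groups == g] for g in pd.unique(groups)}
    if len(samples) != 2:
        raise ValueError("exactly two groups are required")
    removed = []
    if grubbs_alpha is not None:
        for g, s in samples.items():
            if len(s) >= 3:
                flag = grubbs_screen(s.to_numpy(), grubbs_alpha)
                if flag is not None:
                    removed.append(str(s.index[flag]))
                    samples[g] = s.drop(s.index[flag])
    a, b = (s.to_numpy() for s in samples.values())
    if min(a.size, b.size) < 3:
        raise ValueError("need at least 3 observations per group")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return GroupStatResult(feature, "t", 0.0, 1.0,
                               outliers_removed=tuple(removed), degenerate=True)
    normal = True
    for s in (a, b):
        if np.ptp(s) == 0:
            normal = False
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if stats.shapiro(s).pvalue < normality_alpha:
                normal = False
                break
    if normal:
        res = stats.ttest_ind(a, b)
        test = "t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann_whitney"
    return GroupStatResult(
        feature, test, float(res.statistic), float(res.pvalue),
        outliers_removed=tuple(removed),
    )


def compare_groups_table(fm: FeatureMatrix, **kwargs) -> pd.DataFrame:
    """Per-feature group comparison with one BH family over the matrix."""
    results = [
        group_compare(fm.values[f], fm.groups(), feature=f, **kwargs)
        for f in fm.values.columns
    ]
    table = pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "test": [r.test_used for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p for r in results],
            "outliers": [";".join(r.outliers_removed) for r in results],
        }
    )
    table["fdr"] = adjust_bh(table["p"].to_numpy())
    return table.set_index("feature")


# ---------------------------------------------------------------- BH FDR


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------- alpha diversity


def alpha_diversity(otu: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-sample Shannon index (natural log) and observed richness."""
    values = otu.values if isinstance(otu, FeatureMatrix) else pd.DataFrame(otu)
    if (values < 0).any().any():
        raise ValueError("abundances must be non-negative")
    out = {}
    for sample, row in values.iterrows():
        x = row.to_numpy(dtype=float)
        total = x.sum()
        if total == 0:
            warnings.warn(f"sample {sample!r} is all-zero; diversity set to 0")
            out[sample] = (0.0, 0)
            continue
        p = x[x > 0] / total
        out[sample] = (float(-(p * np.log(p)).sum()), int((x > 0).sum()))
    return pd.DataFrame(out, index=["shannon", "richness"]).T.astype(
        {"richness": int}
    )


# ------------------------------------------------------------------ zscore


def zscore(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-feature (column) standardization to mean 0, sd 1; zero-variance
    features pass through as all zeros with a warning."""
    matrix = pd.DataFrame(matrix).astype(float)
    sd = matrix.std(ddof=ddof)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance feature(s) set to 0 in z-scoring"
        )
    sd = sd.where(~constant, 1.0)
    out = (matrix - matrix.mean()) / sd
    out.loc[:, constant] = 0.0
    return out
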
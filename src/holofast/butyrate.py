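"""In-silico butyrate-production-capacity classification.

Taxa are called from tabular protein-homology hits (enzyme class, taxon,
percent similarity) for four enzymes: phosphate butyryltransferase (ptb),
butyrate kinase (buk), butyryl-CoA:acetate CoA-transferase (but), and
4-hydroxybutyrate CoA-transferase (4hbt). A taxon is positive for the
*kinase* pathway when both ptb and buk hits reach the similarity cutoff,
and positive for the *transferase* pathway when its but hit does; 4hbt
hits act as a false-positive control for but (a taxon whose best 4hbt
similarity matches or exceeds its best but similarity has its transferase
call suppressed). The similarity cutoff is chosen by stratified five-fold
cross-validation on a user-supplied labeled set, maximizing balanced
accuracy per fold and averaging the per-fold optima (ties broken toward
the higher, more conservative cutoff).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from .synthetic import ENZYMES

logger = logging.getLogger(__name__)

__all__ = [
    "best_hits",
    "cv_similarity_cutoff",
    "classify_pathways",
    "SimilarityCutoffClassifier",
]


def best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Reduce multiple hits per (taxon, enzyme) to the maximum similarity.

    Returns a taxon x enzyme-class table of best percent similarities
    (NaN where a taxon has no hit for an enzyme).
    """
    sims = hits["percent_similarity"].astype(float)
    if ((sims < 0) | (sims > 100)).any():
        raise ValueError("percent_similarity must lie in [0, 100]")
    unknown = set(hits["enzyme_class"]) - set(ENZYMES)
    if unknown:
        raise ValueError(f"unknown enzyme class(es): {sorted(unknown)}")
    return hits.pivot_table(
        index="taxon", columns="enzyme_class", values="percent_similarity", aggfunc="max"
    ).reindex(columns=list(ENZYMES))


def _fold_optimum(sim: np.ndarray, labels: np.ndarray, grid: np.ndarray) -> float:
    """Grid cutoff maximizing balanced accuracy; ties go to the highest cutoff."""
    best_score, best_cut = -1.0, grid[0]
    for cut in grid:
        score = balanced_accuracy_score(labels, sim >= cut)
        if score >= best_score:  # >= walks ties toward the higher cutoff
            best_score, best_cut = score, cut
    return float(best_cut)


def cv_similarity_cutoff(
    similarity,
    labels,
    folds: int = 5,
    grid_step: float = 1.0,
    random_state: int = 0,
) -> float:
    """Cross-validated percent-similarity cutoff.

    Stratified ``folds``-fold CV over (similarity, label) points; for each
    fold, the cutoff on a uniform grid maximizing balanced accuracy on the
    held-out fold is recorded, and the returned cutoff is the mean of the
    per-fold optima.
    """
    sim = np.asarray(similarity, dtype=float)
    y = np.asarray(labels).astype(bool)
    if sim.shape != y.shape:
        raise ValueError("similarity and labels must have the same length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both positive and negative labels are required")
    if min(n_pos, n_neg) < folds:
        raise ValueError(
            f"need at least {folds} examples of each class for {folds}-fold CV"
        )
    grid = np.arange(
        np.floor(sim.min()), np.ceil(sim.max()) + grid_step, grid_step
    )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
    optima = [
        _fold_optimum(sim[test], y[test], grid) for _, test in cv.split(sim, y)
    ]
    return float(np.mean(optima))


def classify_pathways(
    hits: pd.DataFrame, cutoff: float, control_rule: bool = True
) -> pd.DataFrame:
    """Per-taxon pathway calls at a similarity cutoff.

    kinase_positive: ptb AND buk hits >= cutoff. transferase_positive:
    but hit >= cutoff. With ``control_rule`` (default), a taxon whose best
    4hbt similarity is >= its best but similarity has ``control_hit`` set
    and its transferase call suppressed.
    """
    if not 0.0 <= cutoff <= 100.0:
        raise ValueError("cutoff must lie in [0, 100]")
    if hits.empty:
        return pd.DataFrame(
            columns=["kinase_positive", "transferase_positive", "control_hit", "cutoff_used"]
        ).rename_axis("taxon")
    best = best_hits(hits)
    passes = best.ge(cutoff).fillna(False)
    kinase = passes["ptb"] & passes["buk"]
    transferase = passes["but"].copy()
    control = (
        best["4hbt"].notna()
        & best["but"].notna()
        & (best["4hbt"] >= best["but"])
    )
    if control_rule:
        suppressed = transferase & control
        if suppressed.any():
            logger.info(
                "transferase call suppressed by 4hbt control for: %s",
                list(best.index[suppressed]),
            )
        transferase &= ~control
    return pd.DataFrame(
        {
            "kinase_positive": kinase,
            "transferase_positive": transferase,
            "control_hit": control,
            "cutoff_used": cutoff,
        },
        index=best.index,
    )


class SimilarityCutoffClassifier(BaseEstimator, ClassifierMixin):
    """Threshold-on-similarity classifier with a CV-fitted cutoff.

    ``fit(X, y)`` takes percent similarities (1-d or single-column) and
    boolean labels, cross-validates the cutoff, and stores it as
    ``cutoff_``; ``predict`` thresholds new similarities at the fitted
    cutoff.
    """

    def __init__(self, folds: int = 5, grid_step: float = 1.0, random_state: int = 0):
        self.folds = folds
        self.grid_step = grid_step
        self.random_state = random_state

    def fit(self, X, y):
        sim = np.asarray(X, dtype=float).reshape(-1)
        self.cutoff_ = cv_similarity_cutoff(
            sim,
            np.asarray(y),
            folds=self.folds,
            grid_step=self.grid_step,
            random_state=self.random_state,
        )
        self.classes_ = np.array([False, True])
        return self

    def predict(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float).reshape(-1) >= self.cutoff_
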
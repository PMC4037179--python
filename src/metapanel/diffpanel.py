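"""Nested logistic-regression panels over VIP-ranked differential
metabolites, scored by ROC AUC.

Given the differential metabolites of one comparison sorted by descending
VIP, a logistic regression is fitted to the top-k metabolites for
k = 1..k_max and each panel is scored by the area under its ROC curve on
the fitted data. The best panel is the one with the highest AUC, ties
resolved toward the smaller (cheaper to assay) panel.

A small L2 penalty (1e-4 on the slopes, none on the intercept) keeps the
fit defined under complete separation — common at these effect sizes —
without affecting the score ranking, hence the AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve

from .groups import Comparison, validate_comparison
from .sample_table import PanelDefinition, SampleTable

_L2_LAMBDA = 1e-4


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float


@dataclass(frozen=True)
class PanelEvaluation:
    panel: PanelDefinition
    k: int
    auc: float
    fitted_coefficients: np.ndarray  # intercept first, then slopes


def fit_logistic(
    table: SampleTable, panel: PanelDefinition, comparison: Comparison
) -> tuple[Callable[[np.ndarray], np.ndarray], np.ndarray]:
    """Penalized-ML logistic fit of the comparison on the panel metabolites.

    Returns ``(score, coefficients)`` where ``score`` maps rows (in panel
    order) to the linear predictor and ``coefficients`` is
    ``[intercept, slopes...]``.
    """
    comparison = validate_comparison(comparison)
    X, y, _ = table.comparison_arrays(comparison, metabolites=panel.metabolites)
    if len(np.unique(y)) < 2:
        raise ValueError("both comparison groups must be present")
    variances = X.var(axis=0)
    zero = np.flatnonzero(variances == 0)
    if zero.size:
        raise ValueError(f"zero-variance predictor {panel.metabolites[zero[0]]!r}")
    clf = LogisticRegression(C=1.0 / _L2_LAMBDA, solver="lbfgs", max_iter=5000, tol=1e-10)
    clf.fit(X, y)
    coef = np.concatenate([clf.intercept_, clf.coef_.ravel()])

    def score(rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        return coef[0] + rows @ coef[1:]

    return score, coef


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve and trapezoidal AUC.

    The AUC equals the Mann–Whitney concordance: the probability that a
    random case outscores a random control, ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        thresholds=thresholds,
        sensitivities=tpr,
        specificities=1.0 - fpr,
        auc=auc,
    )


def build_nested_panels(
    table: SampleTable,
    differential: PanelDefinition,
    comparison: Comparison,
    k_max: int,
) -> list[PanelEvaluation]:
    """Evaluate the top-k prefixes (k = 1..k_max) of a VIP-ordered
    differential panel by fitted-data ROC AUC."""
    if not 1 <= k_max <= len(differential.metabolites):
        raise ValueError(f"k_max must be in [1, {len(differential.metabolites)}], got {k_max}")
    comparison = validate_comparison(comparison)
    _, y, _ = table.comparison_arrays(comparison, metabolites=differential.metabolites)
    out = []
    for k in range(1, k_max + 1):
        sub = PanelDefinition(
            comparison=comparison,
            method="differential",
            metabolites=differential.metabolites[:k],
        )
        score, coef = fit_logistic(table, sub, comparison)
        X, _, _ = table.comparison_arrays(comparison, metabolites=sub.metabolites)
        curve = roc_auc(score(X), y)
        out.append(PanelEvaluation(panel=sub, k=k, auc=curve.auc, fitted_coefficients=coef))
    return out


def best_panel(evaluations: Sequence[PanelEvaluation]) -> PanelEvaluation:
    """Highest-AUC evaluation; AUC ties go to the smallest panel."""
    if not evaluations:
        raise ValueError("no evaluations given")
    return max(evaluations, key=lambda e: (e.auc, -e.k))
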
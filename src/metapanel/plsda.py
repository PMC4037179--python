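"""PCA/PLS-DA profiling and VIP-based differential-metabolite selection.

PLS-DA here is PLS1 regression of a centered 0/1 class indicator on the
column-standardized (unit-variance, "UV"-scaled) metabolite matrix, fitted
by NIPALS with sequential deflation. A metabolite's VIP (variable
importance in projection) summarizes its weight across components,
normalized so the mean squared VIP is 1; metabolites with VIP strictly
greater than 1.0 are called differential.

For A components with weights w_a, response sums of squares SSY_a and
p features:

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )

so that sum_j VIP_j^2 = p always.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .groups import Comparison, validate_comparison
from .sample_table import PanelDefinition, SampleTable

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


class DegenerateDataError(ValueError):
    pass


def _standardize(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(scale == 0)
    if zero.size:
        raise DegenerateDataError(f"constant column {names[zero[0]]!r} cannot be unit-variance scaled")
    return (X - mean) / scale, mean, scale


def fit_pca(table: SampleTable, n_components: int):
    """PCA scores of the standardized table and explained-variance fractions."""
    n, p = table.values.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}], got {n_components}")
    Z, _, _ = _standardize(table.values, table.metabolite_names)
    pca = _SkPCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z)
    return scores, pca.explained_variance_ratio_


@dataclass
class PLSDAResults:
    """A fitted PLS-DA model (weights, scores, loadings, per-component
    explained response sums of squares, and the column preprocessing)."""

    comparison: Comparison
    metabolite_names: list[str]
    n_components: int
    x_weights: np.ndarray  # p × A, columns unit norm
    x_scores: np.ndarray  # n × A
    x_loadings: np.ndarray  # p × A
    y_loadings: np.ndarray  # A
    y_variance_explained: np.ndarray  # SSY_a per component
    column_means: np.ndarray
    column_scales: np.ndarray
    truncated: bool = False  # fewer components extractable than requested

    def vip(self) -> "VIPResult":
        return compute_vip(self)

    def select_differential(self, threshold: float = 1.0) -> PanelDefinition:
        return select_differential(self.vip(), threshold=threshold, comparison=self.comparison)

    def summary(self) -> str:
        vip = self.vip()
        lines = [
            f"PLS-DA  {self.comparison[0]} vs {self.comparison[1]}",
            f"components: {self.n_components}" + ("  (truncated)" if self.truncated else ""),
            f"{'metabolite':<28}{'VIP':>8}",
        ]
        order = np.argsort(vip.vip)[::-1]
        for j in order:
            lines.append(f"{vip.metabolite_names[j]:<28}{vip.vip[j]:>8.3f}")
        return "\n".join(lines)


@dataclass(frozen=True)
class VIPResult:
    metabolite_names: tuple[str, ...]
    vip: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.metabolite_names, self.vip))


class PLSDA:
    """Two-group PLS-DA model over a labeled sample table.

    Parameters
    ----------
    table : SampleTable with group labels
    comparison : (control_group, case_group)
    n_components : latent components to extract (default 2, matching the
        2-D score plots conventional in metabonomics)
    """

    def __init__(self, table: SampleTable, comparison: Comparison, n_components: int = 2):
        self.table = table
        self.comparison = validate_comparison(comparison)
        self.n_components = int(n_components)

    def fit(self) -> PLSDAResults:
        return fit_plsda(self.table, self.comparison, self.n_components)


def fit_plsda(table: SampleTable, comparison: Comparison, n_components: int = 2) -> PLSDAResults:
    """NIPALS PLS1 on the standardized table against the centered 0/1
    group indicator.

    If the residual is exhausted before ``n_components`` are extracted the
    model is returned with fewer components and ``truncated=True`` (a
    warning is emitted).
    """
    comparison = validate_comparison(comparison)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    X_raw, y01, _ = table.comparison_arrays(comparison)
    if (y01 == 0).sum() < 2 or (y01 == 1).sum() < 2:
        raise ValueError("each comparison group needs at least 2 samples")
    X, mean, scale = _standardize(X_raw, table.metabolite_names)
    y = y01.astype(float) - y01.mean()

    p = X.shape[1]
    W, T, P, Q, SSY = [], [], [], [], []
    Xr, yr = X.copy(), y.copy()
    for _ in range(n_components):
        w = Xr.T @ yr
        norm = np.linalg.norm(w)
        if norm < 1e-12 or np.linalg.norm(yr) < 1e-12:
            break
        w = w / norm
        # PLS1 NIPALS: the weight update is a fixed point after one pass,
        # but iterate per the general recipe for robustness
        for _ in range(_NIPALS_MAX_ITER):
            t = Xr @ w
            q = float(t @ yr) / float(t @ t)
            w_new = Xr.T @ yr
            w_new = w_new / np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                w = w_new
                break
            w = w_new
        t = Xr @ w
        tt = float(t @ t)
        q = float(t @ yr) / tt
        pl = Xr.T @ t / tt
        ssy = q * q * tt  # response sum of squares captured by this component
        W.append(w)
        T.append(t)
        P.append(pl)
        Q.append(q)
        SSY.append(ssy)
        Xr = Xr - np.outer(t, pl)
        yr = yr - q * t

    if not W:
        raise DegenerateDataError("response carries no variance explainable by the data")
    truncated = len(W) < n_components
    if truncated:
        warnings.warn(
            f"only {len(W)} of {n_components} requested PLS components extractable",
            RuntimeWarning,
            stacklevel=2,
        )
    return PLSDAResults(
        comparison=comparison,
        metabolite_names=list(table.metabolite_names),
        n_components=len(W),
        x_weights=np.column_stack(W),
        x_scores=np.column_stack(T),
        x_loadings=np.column_stack(P),
        y_loadings=np.asarray(Q),
        y_variance_explained=np.asarray(SSY),
        column_means=mean,
        column_scales=scale,
        truncated=truncated,
    )


def compute_vip(model: PLSDAResults) -> VIPResult:
    """VIP scores of a fitted PLS-DA model; sum of squared VIPs equals p."""
    ssy = model.y_variance_explained
    if not np.any(ssy > 0):
        raise DegenerateDataError("all components explain zero response variance")
    W = model.x_weights
    p = W.shape[0]
    wn2 = (W / np.linalg.norm(W, axis=0)) ** 2
    vip = np.sqrt(p * (wn2 @ ssy) / ssy.sum())
    return VIPResult(metabolite_names=tuple(model.metabolite_names), vip=vip)


def select_differential(
    vip: VIPResult, threshold: float = 1.0, comparison: Comparison | None = None
) -> PanelDefinition | None:
    """Metabolites with VIP strictly above ``threshold``, ordered by
    descending VIP. Returns ``None`` when nothing passes (a panel cannot be
    empty)."""
    if comparison is None:
        raise ValueError("a comparison is required to define a panel")
    order = np.argsort(vip.vip)[::-1]
    chosen = [vip.metabolite_names[j] for j in order if vip.vip[j] > threshold]
    if not chosen:
        return None
    return PanelDefinition(
        comparison=comparison,
        method="differential",
        metabolites=tuple(chosen),
    )
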
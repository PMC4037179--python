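"""The Tclass system: forward feature selection under LOOCV, resampling
stability validation, and 1000-classifier majority-vote ensembles.

The system searches metabolite combinations directly, without pre-selecting
differential metabolites, using one of two Gaussian base learners:

* ``fisher`` — linear discriminant classification functions: per-class
  affine scores g_k(x) = mu_k' S^-1 x - mu_k' S^-1 mu_k / 2 + ln pi_k with
  the pooled within-class covariance S (ridge-stabilized) and equal priors.
  These are exactly the published per-class ``C``/``MDD`` score equations.
* ``naive_bayes`` — Gaussian class-conditionals with per-class per-feature
  mean and variance (variance floored), equal priors.

Selection is greedy: at each step the metabolite whose addition maximizes
leave-one-out cross-validated accuracy joins the panel, ties breaking to
the lower catalog index. Because selection optimizes LOOCV on the full
cohort, its accuracy is optimistic; the stability index — the mean test
accuracy over 1000 random stratified 85%/15% train/test partitions — is
the procedure's own less-biased estimate of practical performance. The
1000 per-partition classifiers are retained as an ensemble: a new sample's
vote fraction P for the case class calls the case when P > 0.5 strictly
(exactly half the votes is a control call).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .catalog import catalog_order_key
from .groups import Comparison, validate_comparison
from .sample_table import (
    SCHEMA_VERSION,
    LinearClassifierPair,
    PanelDefinition,
    SampleTable,
)

LEARNERS = ("fisher", "naive_bayes")

_RIDGE_START = 1e-6
_RIDGE_MAX = 1e-2
_VAR_FLOOR_REL = 1e-9
_VAR_FLOOR_ABS = 1e-12


# ---------------------------------------------------------------------------
# base learners
# ---------------------------------------------------------------------------


@dataclass
class TrainedClassifier:
    """One fitted two-class base learner over a fixed panel."""

    learner: str
    class_labels: tuple[str, str]
    panel: PanelDefinition
    linear: LinearClassifierPair | None = None  # fisher
    means: np.ndarray | None = None  # naive_bayes, (2, p)
    variances: np.ndarray | None = None  # naive_bayes, (2, p)
    log_priors: np.ndarray = field(default_factory=lambda: np.log([0.5, 0.5]))

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        """Per-class scores, shape (n, 2): column 0 control, column 1 case."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.panel.metabolites):
            raise ValueError(
                f"feature vector of length {X.shape[1]} does not match "
                f"panel of {len(self.panel.metabolites)}"
            )
        if self.learner == "fisher":
            lin = self.linear
            a = lin.control_intercept + X @ np.asarray(lin.control_coefficients)
            b = lin.case_intercept + X @ np.asarray(lin.case_coefficients)
            return np.column_stack([a, b])
        # gaussian naive bayes log-posteriors (up to the shared evidence term)
        out = np.empty((X.shape[0], 2))
        for k in range(2):
            mu, var = self.means[k], self.variances[k]
            out[:, k] = self.log_priors[k] - 0.5 * np.sum(
                np.log(2 * np.pi * var) + (X - mu) ** 2 / var, axis=1
            )
        return out

    def predict01(self, X: np.ndarray) -> np.ndarray:
        s = self.score_matrix(X)
        # strict inequality: a tie is a control call
        return (s[:, 1] > s[:, 0]).astype(int)

    def to_dict(self) -> dict:
        d: dict = {"learner": self.learner}
        if self.learner == "fisher":
            d["linear"] = self.linear.to_dict()
        else:
            d["means"] = self.means.tolist()
            d["variances"] = self.variances.tolist()
            d["log_priors"] = self.log_priors.tolist()
        return d

    @classmethod
    def from_dict(
        cls, d: Mapping, class_labels: tuple[str, str], panel: PanelDefinition
    ) -> "TrainedClassifier":
        if d["learner"] == "fisher":
            return cls(
                learner="fisher",
                class_labels=class_labels,
                panel=panel,
                linear=LinearClassifierPair.from_dict(d["linear"]),
            )
        return cls(
            learner="naive_bayes",
            class_labels=class_labels,
            panel=panel,
            means=np.asarray(d["means"]),
            variances=np.asarray(d["variances"]),
            log_priors=np.asarray(d["log_priors"]),
        )


def _class_split(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X0, X1 = X[y == 0], X[y == 1]
    if len(X0) == 0 or len(X1) == 0:
        raise ValueError("a training class has no samples")
    return X0, X1


def _fit_fisher_arrays(
    X: np.ndarray, y: np.ndarray, class_labels: tuple[str, str], panel: PanelDefinition
) -> TrainedClassifier:
    X0, X1 = _class_split(X, y)
    p = X.shape[1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    dof = max(len(X0) + len(X1) - 2, 1)
    S = np.zeros((p, p))
    for Xk in (X0, X1):
        if len(Xk) >= 2:
            d = Xk - Xk.mean(axis=0)
            S += d.T @ d
    S /= dof
    trace = np.trace(S)
    base = trace / p if trace > 0 else 1.0
    lam = _RIDGE_START
    inv = None
    while lam <= _RIDGE_MAX * (1 + 1e-12):
        Sr = S + lam * base * np.eye(p)
        try:
            inv = np.linalg.inv(Sr)
            if np.isfinite(inv).all() and np.linalg.cond(Sr) < 1e12:
                break
            inv = None
        except np.linalg.LinAlgError:
            inv = None
        lam *= 10
    if inv is None:
        raise np.linalg.LinAlgError("pooled covariance singular even after ridge stabilization")
    log_pi = np.log(0.5)
    coef0, coef1 = inv @ mu0, inv @ mu1
    lin = LinearClassifierPair(
        class_labels=class_labels,
        feature_names=panel.metabolites,
        control_intercept=float(-0.5 * mu0 @ coef0 + log_pi),
        case_intercept=float(-0.5 * mu1 @ coef1 + log_pi),
        control_coefficients=tuple(coef0),
        case_coefficients=tuple(coef1),
    )
    return TrainedClassifier(learner="fisher", class_labels=class_labels, panel=panel, linear=lin)


def _fit_nb_arrays(
    X: np.ndarray, y: np.ndarray, class_labels: tuple[str, str], panel: PanelDefinition
) -> TrainedClassifier:
    X0, X1 = _class_split(X, y)
    overall_var = X.var(axis=0, ddof=0)
    floor = np.maximum(_VAR_FLOOR_REL * overall_var, _VAR_FLOOR_ABS)
    means = np.vstack([X0.mean(axis=0), X1.mean(axis=0)])
    var_rows = []
    floored = False
    for Xk in (X0, X1):
        v = Xk.var(axis=0, ddof=1) if len(Xk) >= 2 else np.zeros(X.shape[1])
        if np.any(v < floor):
            floored = True
        var_rows.append(np.maximum(v, floor))
    if floored and np.all(overall_var == 0):
        warnings.warn("zero within-class variance on all features; variance floored", RuntimeWarning)
    return TrainedClassifier(
        learner="naive_bayes",
        class_labels=class_labels,
        panel=panel,
        means=means,
        variances=np.vstack(var_rows),
    )


_FITTERS = {"fisher": _fit_fisher_arrays, "naive_bayes": _fit_nb_arrays}


def _check_learner(learner: str) -> None:
    if learner not in LEARNERS:
        raise ValueError(f"unknown learner {learner!r}; expected one of {LEARNERS}")


def _panel_arrays(
    table: SampleTable, panel: PanelDefinition, comparison: Comparison
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    return table.comparison_arrays(comparison, metabolites=panel.metabolites)


def train_fisher(table: SampleTable, panel: PanelDefinition, comparison: Comparison) -> TrainedClassifier:
    """Fisher linear discriminant classification functions on a panel."""
    comparison = validate_comparison(comparison)
    X, y, _ = _panel_arrays(table, panel, comparison)
    _require_two_each(y)
    return _fit_fisher_arrays(X, y, comparison, panel)


def train_naive_bayes(table: SampleTable, panel: PanelDefinition, comparison: Comparison) -> TrainedClassifier:
    """Gaussian naive Bayes with equal priors on a panel."""
    comparison = validate_comparison(comparison)
    X, y, _ = _panel_arrays(table, panel, comparison)
    _require_two_each(y)
    return _fit_nb_arrays(X, y, comparison, panel)


def _require_two_each(y: np.ndarray) -> None:
    if (y == 0).sum() < 2 or (y == 1).sum() < 2:
        raise ValueError("each class needs at least 2 samples")


def classify(model: TrainedClassifier, sample: Sequence[float]) -> tuple[str, tuple[float, float]]:
    """Label of one sample plus both class scores; ties go to the control."""
    s = model.score_matrix(np.asarray(sample, dtype=float)[None, :])[0]
    label = model.class_labels[1] if s[1] > s[0] else model.class_labels[0]
    return label, (float(s[0]), float(s[1]))


# ---------------------------------------------------------------------------
# LOOCV and forward selection
# ---------------------------------------------------------------------------


def _loocv01(X: np.ndarray, y: np.ndarray, learner: str, class_labels, panel) -> float:
    fit = _FITTERS[learner]
    n = len(y)
    correct = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = fit(X[mask], y[mask], class_labels, panel)
        correct += int(clf.predict01(X[i : i + 1])[0] == y[i])
        mask[i] = True
    return correct / n


def loocv_accuracy(
    table: SampleTable, panel: PanelDefinition, comparison: Comparison, learner: str
) -> float:
    """Leave-one-out accuracy: each sample predicted by a model retrained on
    all others. Folds that leave a class tiny go through the same
    ridge/variance-floor path as any other fit."""
    _check_learner(learner)
    comparison = validate_comparison(comparison)
    X, y, _ = _panel_arrays(table, panel, comparison)
    if len(y) < 3 or len(np.unique(y)) < 2:
        raise ValueError("LOOCV needs n >= 3 with both classes present")
    return _loocv01(X, y, learner, comparison, panel)


@dataclass(frozen=True)
class SelectionStep:
    added: str
    panel: tuple[str, ...]
    loocv_accuracy: float


@dataclass
class SelectionTrace:
    """Forward-selection path: the grown panel and its LOOCV accuracy at
    every step, plus the chosen (smallest maximal-accuracy) panel."""

    steps: list[SelectionStep]
    chosen: PanelDefinition
    learner: str

    @property
    def accuracies(self) -> np.ndarray:
        return np.asarray([s.loocv_accuracy for s in self.steps])

    @property
    def chosen_accuracy(self) -> float:
        return float(self.accuracies.max())


def forward_select(
    table: SampleTable, comparison: Comparison, learner: str, k_max: int
) -> SelectionTrace:
    """Greedy forward selection with LOOCV accuracy as the objective.

    At each step the candidate metabolite maximizing the augmented panel's
    LOOCV accuracy is added (ties to the lower catalog index); the search
    stops at ``k_max`` metabolites or as soon as accuracy reaches 1. The
    chosen panel is the smallest prefix attaining the maximum accuracy seen.
    """
    _check_learner(learner)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    comparison = validate_comparison(comparison)
    candidates = sorted(table.metabolite_names, key=catalog_order_key)
    X_all, y, _ = table.comparison_arrays(comparison, metabolites=candidates)
    col = {m: j for j, m in enumerate(candidates)}

    steps: list[SelectionStep] = []
    current: list[str] = []
    remaining = list(candidates)
    while remaining and len(current) < k_max:
        best_name, best_acc = None, -1.0
        for m in remaining:
            cols = [col[x] for x in current] + [col[m]]
            trial_panel = PanelDefinition(
                comparison=comparison, method="tclass",
                metabolites=tuple(current + [m]), learner=learner,
            )
            acc = _loocv01(X_all[:, cols], y, learner, comparison, trial_panel)
            if acc > best_acc:
                best_name, best_acc = m, acc
        current.append(best_name)
        remaining.remove(best_name)
        steps.append(SelectionStep(added=best_name, panel=tuple(current), loocv_accuracy=best_acc))
        if best_acc >= 1.0:
            break

    accs = [s.loocv_accuracy for s in steps]
    best_idx = int(np.argmax(accs))  # first occurrence -> smallest panel
    chosen = PanelDefinition(
        comparison=comparison,
        method="tclass",
        metabolites=steps[best_idx].panel,
        learner=learner,
    )
    return SelectionTrace(steps=steps, chosen=chosen, learner=learner)


# ---------------------------------------------------------------------------
# stability index and ensemble
# ---------------------------------------------------------------------------


@dataclass
class StabilityResult:
    """Per-split test accuracies over random stratified train/test
    partitions; the stability index is their mean."""

    n_splits: int
    train_fraction: float
    split_accuracies: np.ndarray
    seed: int

    @property
    def stability_index(self) -> float:
        return float(np.mean(self.split_accuracies))


def _stratified_split_setup(
    X: np.ndarray, y: np.ndarray, ids: list[str], train_fraction: float
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Per-class index pools in a canonical (sample-id-sorted) order and the
    per-class test sizes, so split draws are invariant to row order."""
    order = np.argsort(np.asarray(ids))
    idx0 = order[y[order] == 0]
    idx1 = order[y[order] == 1]
    test_frac = 1.0 - train_fraction
    k0 = max(1, int(np.floor(test_frac * len(idx0) + 0.5)))
    k1 = max(1, int(np.floor(test_frac * len(idx1) + 0.5)))
    if len(idx0) - k0 < 1 or len(idx1) - k1 < 1:
        raise ValueError(
            "a class is too small for stratified train/test partitioning "
            f"(class sizes {len(idx0)}/{len(idx1)})"
        )
    return idx0, idx1, k0, k1


def _iter_splits(rng: np.random.Generator, idx0, idx1, k0, k1, n_splits):
    for _ in range(n_splits):
        p0 = rng.permutation(idx0)
        p1 = rng.permutation(idx1)
        test = np.concatenate([p0[:k0], p1[:k1]])
        train = np.concatenate([p0[k0:], p1[k1:]])
        yield train, test


Trainer = Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]]


def stability_index(
    table: SampleTable,
    panel: PanelDefinition,
    comparison: Comparison,
    learner: str,
    n_splits: int = 1000,
    train_fraction: float = 0.85,
    seed: int = 0,
    _trainer: Trainer | None = None,
) -> StabilityResult:
    """Mean test-set accuracy over ``n_splits`` random stratified
    train/test partitions (default 85%/15%, 1000 splits).

    ``_trainer`` is a test hook replacing the base learner: a callable
    ``(X_train, y_train) -> predict`` with ``predict(X_test) -> 0/1``.
    """
    _check_learner(learner)
    comparison = validate_comparison(comparison)
    X, y, ids = _panel_arrays(table, panel, comparison)
    idx0, idx1, k0, k1 = _stratified_split_setup(X, y, ids, train_fraction)
    rng = np.random.default_rng(seed)
    fit = _FITTERS[learner]
    accs = np.empty(n_splits)
    for s, (train, test) in enumerate(_iter_splits(rng, idx0, idx1, k0, k1, n_splits)):
        if _trainer is not None:
            predict = _trainer(X[train], y[train])
            pred = np.asarray(predict(X[test]))
        else:
            pred = fit(X[train], y[train], comparison, panel).predict01(X[test])
        accs[s] = float(np.mean(pred == y[test]))
    return StabilityResult(
        n_splits=n_splits, train_fraction=train_fraction, split_accuracies=accs, seed=seed
    )


@dataclass
class EnsembleModel:
    """1000 (by default) base classifiers, one per stability-analysis
    training set; prediction is by case-vote fraction P with P > 0.5
    calling the case."""

    classifiers: list[TrainedClassifier]
    panel: PanelDefinition
    class_labels: tuple[str, str]
    train_fraction: float
    seed: int

    @property
    def n_splits(self) -> int:
        return len(self.classifiers)

    @property
    def case_label(self) -> str:
        return self.class_labels[1]

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "class_labels": list(self.class_labels),
            "panel": self.panel.to_dict(),
            "train_fraction": self.train_fraction,
            "seed": self.seed,
            "classifiers": [c.to_dict() for c in self.classifiers],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EnsembleModel":
        panel = PanelDefinition.from_dict(d["panel"])
        labels = tuple(d["class_labels"])
        return cls(
            classifiers=[TrainedClassifier.from_dict(c, labels, panel) for c in d["classifiers"]],
            panel=panel,
            class_labels=labels,
            train_fraction=float(d["train_fraction"]),
            seed=int(d["seed"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class EnsemblePrediction:
    vote_fraction: float  # P, the fraction of classifiers voting the case
    predicted_label: str


def build_ensemble(
    table: SampleTable,
    panel: PanelDefinition,
    comparison: Comparison,
    learner: str,
    n_splits: int = 1000,
    train_fraction: float = 0.85,
    seed: int = 0,
) -> EnsembleModel:
    """Train one classifier per stability split; the split stream is the
    same as :func:`stability_index` under the same seed."""
    _check_learner(learner)
    comparison = validate_comparison(comparison)
    X, y, ids = _panel_arrays(table, panel, comparison)
    idx0, idx1, k0, k1 = _stratified_split_setup(X, y, ids, train_fraction)
    rng = np.random.default_rng(seed)
    fit = _FITTERS[learner]
    classifiers = [
        fit(X[train], y[train], comparison, panel)
        for train, _ in _iter_splits(rng, idx0, idx1, k0, k1, n_splits)
    ]
    return EnsembleModel(
        classifiers=classifiers,
        panel=panel,
        class_labels=comparison,
        train_fraction=train_fraction,
        seed=seed,
    )


def ensemble_predict(model: EnsembleModel, sample: Sequence[float]) -> EnsemblePrediction:
    """Vote fraction P for the case label; the case is called iff P > 0.5
    strictly (exactly half the votes is a control call)."""
    x = np.asarray(sample, dtype=float)[None, :]
    votes = sum(int(c.predict01(x)[0]) for c in model.classifiers)
    p = votes / model.n_splits
    label = model.case_label if p > 0.5 else model.class_labels[0]
    return EnsemblePrediction(vote_fraction=p, predicted_label=label)


def ensemble_predict_table(model: EnsembleModel, table: SampleTable) -> list[EnsemblePrediction]:
    X = table.feature_matrix(model.panel.metabolites)
    votes = np.zeros(len(X), dtype=int)
    for c in model.classifiers:
        votes += c.predict01(X)
    out = []
    for v in votes:
        p = v / model.n_splits
        out.append(
            EnsemblePrediction(
                vote_fraction=float(p),
                predicted_label=model.case_label if p > 0.5 else model.class_labels[0],
            )
        )
    return out


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------


class Tclass:
    """Tclass model for one two-group comparison of a labeled cohort.

    ``fit`` runs forward selection, the stability analysis of the chosen
    panel, and trains the per-split ensemble.
    """

    def __init__(
        self,
        table: SampleTable,
        comparison: Comparison,
        learner: str = "naive_bayes",
        k_max: int = 10,
    ):
        _check_learner(learner)
        self.table = table
        self.comparison = validate_comparison(comparison)
        self.learner = learner
        self.k_max = int(k_max)

    def fit(
        self, n_splits: int = 1000, train_fraction: float = 0.85, seed: int = 0
    ) -> "TclassResults":
        trace = forward_select(self.table, self.comparison, self.learner, self.k_max)
        stab = stability_index(
            self.table, trace.chosen, self.comparison, self.learner,
            n_splits=n_splits, train_fraction=train_fraction, seed=seed,
        )
        ens = build_ensemble(
            self.table, trace.chosen, self.comparison, self.learner,
            n_splits=n_splits, train_fraction=train_fraction, seed=seed,
        )
        return TclassResults(model=self, trace=trace, stability=stab, ensemble=ens)


@dataclass
class TclassResults:
    model: Tclass
    trace: SelectionTrace
    stability: StabilityResult
    ensemble: EnsembleModel

    @property
    def panel(self) -> PanelDefinition:
        return self.trace.chosen

    @property
    def loocv_accuracy(self) -> float:
        return self.trace.chosen_accuracy

    @property
    def stability_index(self) -> float:
        return self.stability.stability_index

    def predict(self, table: SampleTable) -> list[EnsemblePrediction]:
        return ensemble_predict_table(self.ensemble, table)

    def summary(self) -> str:
        c = self.model.comparison
        lines = [
            f"Tclass  {c[0]} vs {c[1]}   learner: {self.model.learner}",
            f"selection path ({len(self.trace.steps)} steps):",
        ]
        for s in self.trace.steps:
            mark = " *" if s.panel == self.panel.metabolites else ""
            lines.append(f"  k={len(s.panel):<3d} +{s.added:<28s} LOOCV={s.loocv_accuracy:.4f}{mark}")
        lines += [
            f"chosen panel ({len(self.panel.metabolites)}): {', '.join(self.panel.metabolites)}",
            f"LOOCV accuracy:  {self.loocv_accuracy:.4f}",
            f"stability index: {self.stability_index:.4f} "
            f"({self.stability.n_splits} splits, {self.stability.train_fraction:.0%} train)",
        ]
        return "\n".join(lines)

    def plot_selection(self, ax=None):
        """Accuracy-vs-panel-size curve of the forward-selection path."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ks = [len(s.panel) for s in self.trace.steps]
        ax.plot(ks, self.trace.accuracies, marker="o")
        ax.axvline(len(self.panel.metabolites), ls="--", color="grey")
        ax.set_xlabel("panel size")
        ax.set_ylabel("LOOCV accuracy")
        ax.set_ylim(0, 1.05)
        ax.set_title(f"{self.model.comparison[0]} vs {self.model.comparison[1]} ({self.model.learner})")
        return ax


def select_learner(
    table: SampleTable,
    comparison: Comparison,
    k_max: int = 10,
    n_splits: int = 200,
    seed: int = 0,
) -> "TclassResults":
    """Run forward selection with both base learners and keep the one with
    the higher chosen-panel LOOCV accuracy, breaking ties by the higher
    stability index."""
    results = [
        Tclass(table, comparison, learner=lr, k_max=k_max).fit(n_splits=n_splits, seed=seed)
        for lr in LEARNERS
    ]
    return max(results, key=lambda r: (r.loocv_accuracy, r.stability_index))
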
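"""Sample-by-metabolite tables and the small record types shared across the
pipeline.

A :class:`SampleTable` is the ``X`` of every model in the package: a dense
real matrix of relative peak areas (RPA), one row per plasma sample, one
column per identified metabolite, with optional per-sample group labels.
On disk it is a plain CSV/TSV with a header row, the sample id in the first
column and an optional ``group`` column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .groups import COMPARISON_GROUPS, STORED_GROUPS, Comparison, group_members, validate_comparison

SCHEMA_VERSION = 1


class TableLoadError(ValueError):
    """Raised when a sample table on disk fails validation."""


@dataclass(frozen=True)
class PanelDefinition:
    """An ordered metabolite subset tied to one two-group comparison.

    ``method`` records how the panel was obtained: ``"differential"`` for
    VIP-ranked panels, ``"tclass"`` for forward-selection panels (which may
    additionally carry the base ``learner``).
    """

    comparison: Comparison
    method: str
    metabolites: tuple[str, ...]
    learner: str | None = None

    def __post_init__(self) -> None:
        if self.method not in ("differential", "tclass"):
            raise ValueError(f"unknown panel method {self.method!r}")
        if self.learner is not None and self.learner not in ("fisher", "naive_bayes"):
            raise ValueError(f"unknown learner {self.learner!r}")
        if not self.metabolites:
            raise ValueError("panel must contain at least one metabolite")
        if len(set(self.metabolites)) != len(self.metabolites):
            raise ValueError("panel contains duplicate metabolites")
        object.__setattr__(self, "comparison", validate_comparison(tuple(self.comparison)))
        object.__setattr__(self, "metabolites", tuple(self.metabolites))

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "comparison": list(self.comparison),
            "method": self.method,
            "metabolites": list(self.metabolites),
            "learner": self.learner,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelDefinition":
        return cls(
            comparison=tuple(d["comparison"]),
            method=d["method"],
            metabolites=tuple(d["metabolites"]),
            learner=d.get("learner"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PanelDefinition":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class LinearClassifierPair:
    """Per-class affine discriminant scores, the published ``C``/``MDD`` form.

    score_control(x) = control_intercept + control_coefficients · x
    score_case(x)    = case_intercept    + case_coefficients · x

    The class with the larger score wins; a tie goes to the control label.
    """

    class_labels: tuple[str, str]
    feature_names: tuple[str, ...]
    control_intercept: float
    case_intercept: float
    control_coefficients: tuple[float, ...]
    case_coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        p = len(self.feature_names)
        if len(self.control_coefficients) != p or len(self.case_coefficients) != p:
            raise ValueError("coefficient vectors must match the feature list length")
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "control_coefficients", tuple(float(c) for c in self.control_coefficients))
        object.__setattr__(self, "case_coefficients", tuple(float(c) for c in self.case_coefficients))

    def scores(self, x: Sequence[float]) -> tuple[float, float]:
        x = np.asarray(x, dtype=float)
        if x.shape != (len(self.feature_names),):
            raise ValueError(
                f"feature vector of length {x.size} does not match panel of {len(self.feature_names)}"
            )
        ctrl = self.control_intercept + float(np.dot(self.control_coefficients, x))
        case = self.case_intercept + float(np.dot(self.case_coefficients, x))
        return ctrl, case

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "class_labels": list(self.class_labels),
            "feature_names": list(self.feature_names),
            "control_intercept": self.control_intercept,
            "case_intercept": self.case_intercept,
            "control_coefficients": list(self.control_coefficients),
            "case_coefficients": list(self.case_coefficients),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinearClassifierPair":
        return cls(
            class_labels=tuple(d["class_labels"]),
            feature_names=tuple(d["feature_names"]),
            control_intercept=float(d["control_intercept"]),
            case_intercept=float(d["case_intercept"]),
            control_coefficients=tuple(d["control_coefficients"]),
            case_coefficients=tuple(d["case_coefficients"]),
        )


@dataclass
class SampleTable:
    """Dense samples × metabolites RPA matrix with optional group labels."""

    sample_ids: list[str]
    metabolite_names: list[str]
    values: np.ndarray
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = len(self.sample_ids), len(self.metabolite_names)
        if self.values.shape != (n, p):
            raise ValueError(f"values shape {self.values.shape} does not match {n} samples × {p} metabolites")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.metabolite_names)) != p:
            raise ValueError("duplicate metabolite names")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise TableLoadError(
                f"non-finite value for sample {self.sample_ids[bad[0]]!r}, "
                f"metabolite {self.metabolite_names[bad[1]]!r}"
            )
        if self.labels is not None:
            unknown = set(self.labels) - set(self.sample_ids)
            if unknown:
                raise ValueError(f"labels for unknown samples: {sorted(unknown)}")
            bad_groups = set(self.labels.values()) - set(STORED_GROUPS)
            if bad_groups:
                raise TableLoadError(f"unknown group labels: {sorted(bad_groups)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_names)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.metabolite_names)
        df.index.name = "sample_id"
        if self.labels is not None:
            df.insert(0, "group", [self.labels.get(s) for s in self.sample_ids])
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str | None = None) -> "SampleTable":
        df = df.copy()
        labels = None
        if label_column is not None:
            labels = {str(s): str(g) for s, g in df[label_column].items()}
            df = df.drop(columns=[label_column])
        return cls(
            sample_ids=[str(s) for s in df.index],
            metabolite_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            labels=labels,
        )

    # ---- selection helpers -------------------------------------------------

    def column_indices(self, names: Iterable[str]) -> np.ndarray:
        pos = {m: j for j, m in enumerate(self.metabolite_names)}
        missing = [m for m in names if m not in pos]
        if missing:
            raise KeyError(f"metabolites not in table: {missing}")
        return np.asarray([pos[m] for m in names], dtype=int)

    def feature_matrix(self, metabolites: Sequence[str]) -> np.ndarray:
        return self.values[:, self.column_indices(metabolites)]

    def group_mask(self, group: str) -> np.ndarray:
        if self.labels is None:
            raise ValueError("table carries no group labels")
        members = group_members(group)
        return np.asarray([self.labels.get(s) in members for s in self.sample_ids], dtype=bool)

    def comparison_arrays(
        self, comparison: Comparison, metabolites: Sequence[str] | None = None
    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Rows of the two comparison groups, with a 0/1 response.

        Returns ``(X, y, sample_ids)`` where ``y`` is 0 for the control
        (first) group and 1 for the case group. Row order follows the table.
        """
        control, case = validate_comparison(comparison)
        m_ctrl, m_case = self.group_mask(control), self.group_mask(case)
        keep = m_ctrl | m_case
        cols = (
            slice(None)
            if metabolites is None
            else self.column_indices(metabolites)
        )
        X = self.values[keep][:, cols] if metabolites is not None else self.values[keep]
        y = m_case[keep].astype(int)
        ids = [s for s, k in zip(self.sample_ids, keep) if k]
        return np.asarray(X, dtype=float), y, ids

    def subset_metabolites(self, metabolites: Sequence[str]) -> "SampleTable":
        idx = self.column_indices(metabolites)
        return replace(
            self,
            metabolite_names=list(metabolites),
            values=self.values[:, idx].copy(),
        )


# ---- disk I/O --------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_sample_table(path: str | Path, label_column: str | None = None) -> SampleTable:
    """Read a CSV/TSV sample table (first column sample id).

    Raises :class:`TableLoadError` naming the offending row/column on
    duplicate headers, empty or non-numeric cells, or unknown group labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path)
    header = path.read_text().splitlines()[0].split(sep)
    dupes = {h for h in header if header.count(h) > 1}
    if dupes:
        raise TableLoadError(f"duplicate column headers in {path.name}: {sorted(dupes)}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if label_column is not None and label_column not in df.columns:
        raise TableLoadError(f"label column {label_column!r} not found in {path.name}")
    labels = None
    if label_column is not None:
        labels = {str(s): str(g) for s, g in df[label_column].items()}
        df = df.drop(columns=[label_column])
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                raise TableLoadError(f"empty cell at sample {df.index[i]!r}, column {col!r}")
            try:
                values[i, j] = float(raw)
            except ValueError:
                raise TableLoadError(
                    f"non-numeric value {raw!r} at sample {df.index[i]!r}, column {col!r}"
                ) from None
    return SampleTable(
        sample_ids=[str(s) for s in df.index],
        metabolite_names=[str(c) for c in df.columns],
        values=values,
        labels=labels,
    )


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    """Write a table; numeric cells use repr precision so a round trip is
    lossless well below 1e-12."""
    path = Path(path)
    df = table.to_dataframe()
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")
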
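"""Hierarchical diagnosis: MDD screen, then subtype call requiring
agreement of two ensemble models.

A sample is first screened by the healthy-vs-MDD ensemble. Only if that
screen is positive is a subtype considered: the sample is called ELS/MDD
only when *both* the healthy-vs-ELS/MDD and the ELS-vs-non-ELS ensembles
vote ELS/MDD, and symmetrically non-ELS/MDD only when both the
healthy-vs-non-ELS/MDD and the ELS-vs-non-ELS ensembles vote non-ELS/MDD.
Any other vote pattern after a positive screen is INDETERMINATE — the
agreement rule deliberately refuses to force a subtype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .groups import ELS_MDD, NON_ELS_MDD
from .sample_table import SampleTable
from .tclass import EnsembleModel, ensemble_predict

MDD = "MDD"
NOT_MDD = "NOT_MDD"
INDETERMINATE = "INDETERMINATE"
NOT_APPLICABLE = "NOT_APPLICABLE"


@dataclass(frozen=True)
class SubtypeCall:
    mdd_call: str  # MDD | NOT_MDD
    subtype: str  # ELS_MDD | NON_ELS_MDD | INDETERMINATE | NOT_APPLICABLE
    component_votes: dict[str, tuple[float, str]]  # model name -> (P, label)


def _extract(sample: Mapping[str, float] | Sequence[float], model: EnsembleModel, all_names=None):
    panel = model.panel.metabolites
    if isinstance(sample, Mapping):
        missing = [m for m in panel if m not in sample]
        if missing:
            raise KeyError(f"sample is missing required metabolites: {missing}")
        return np.asarray([float(sample[m]) for m in panel])
    raise TypeError("sample must be a mapping of metabolite name -> RPA")


def predict_patient(
    sample: Mapping[str, float],
    model_mdd: EnsembleModel,
    model_hc_els: EnsembleModel,
    model_hc_nonels: EnsembleModel,
    model_els_nonels: EnsembleModel,
) -> SubtypeCall:
    """Screen for MDD, then call the subtype on two-model agreement."""
    votes: dict[str, tuple[float, str]] = {}
    preds = {}
    for name, model in (
        ("mdd", model_mdd),
        ("hc_els", model_hc_els),
        ("hc_nonels", model_hc_nonels),
        ("els_nonels", model_els_nonels),
    ):
        pred = ensemble_predict(model, _extract(sample, model))
        preds[name] = pred
        votes[name] = (pred.vote_fraction, pred.predicted_label)

    if preds["mdd"].predicted_label != model_mdd.case_label:
        return SubtypeCall(mdd_call=NOT_MDD, subtype=NOT_APPLICABLE, component_votes=votes)

    els_agree = (
        preds["hc_els"].predicted_label == ELS_MDD
        and preds["els_nonels"].predicted_label == ELS_MDD
    )
    nonels_agree = (
        preds["hc_nonels"].predicted_label == NON_ELS_MDD
        and preds["els_nonels"].predicted_label == NON_ELS_MDD
    )
    if els_agree:
        subtype = ELS_MDD
    elif nonels_agree:
        subtype = NON_ELS_MDD
    else:
        subtype = INDETERMINATE
    return SubtypeCall(mdd_call=MDD, subtype=subtype, component_votes=votes)


def predict_patients(
    table: SampleTable,
    model_mdd: EnsembleModel,
    model_hc_els: EnsembleModel,
    model_hc_nonels: EnsembleModel,
    model_els_nonels: EnsembleModel,
) -> dict[str, SubtypeCall]:
    """Hierarchical calls for every sample of a table, keyed by sample id."""
    calls = {}
    for i, sid in enumerate(table.sample_ids):
        sample = dict(zip(table.metabolite_names, table.values[i]))
        calls[sid] = predict_patient(
            sample, model_mdd, model_hc_els, model_hc_nonels, model_els_nonels
        )
    return calls
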
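"""Study-group vocabulary.

Three stored cohort labels: healthy controls, depressed patients with an
early-life-stress (ELS) history, and depressed patients without one.
``MDD_ALL`` is the pooled patient group — a derived union used only in
comparisons, never stored as a per-sample label.
"""

from __future__ import annotations

HEALTHY = "HEALTHY"
ELS_MDD = "ELS_MDD"
NON_ELS_MDD = "NON_ELS_MDD"
MDD_ALL = "MDD_ALL"

#: labels a sample may carry
STORED_GROUPS = (HEALTHY, ELS_MDD, NON_ELS_MDD)
#: labels usable in a two-group comparison
COMPARISON_GROUPS = STORED_GROUPS + (MDD_ALL,)

Comparison = tuple[str, str]


def group_members(group: str) -> frozenset[str]:
    """Stored labels belonging to ``group`` (unions expand)."""
    if group == MDD_ALL:
        return frozenset({ELS_MDD, NON_ELS_MDD})
    if group in STORED_GROUPS:
        return frozenset({group})
    raise ValueError(f"unknown group label {group!r}; expected one of {COMPARISON_GROUPS}")


def validate_comparison(comparison: Comparison) -> Comparison:
    control, case = comparison
    a, b = group_members(control), group_members(case)
    if a & b:
        raise ValueError(f"comparison groups overlap: {control!r} vs {case!r}")
    return (control, case)
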
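"""Internal-standard normalization of raw GC/MS peak intensities.

Every plasma sample is spiked with a fixed amount of ribitol before
derivatization; dividing each validated compound's peak intensity by the
ribitol peak intensity of the *same* sample cancels per-injection response
drift. The resulting quantity is the relative peak area (RPA), with the
internal standard itself at 1 by construction. Upstream spectral steps
(S/N filtering, deconvolution, alignment) are instrument-software territory
and are assumed done.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sample_table import SampleTable, read_sample_table

DEFAULT_IS_COLUMN = "ribitol"


@dataclass
class RawIntensityTable:
    """Aligned raw peak intensities plus the internal-standard column name."""

    table: SampleTable
    internal_standard_column: str = DEFAULT_IS_COLUMN

    def __post_init__(self) -> None:
        if self.internal_standard_column not in self.table.metabolite_names:
            raise ValueError(
                f"internal-standard column {self.internal_standard_column!r} not in table"
            )
        if (self.table.values < 0).any():
            i, j = np.argwhere(self.table.values < 0)[0]
            raise ValueError(
                f"negative raw intensity for sample {self.table.sample_ids[i]!r}, "
                f"column {self.table.metabolite_names[j]!r}"
            )


def read_raw_table(
    path: str | Path,
    label_column: str | None = None,
    internal_standard_column: str = DEFAULT_IS_COLUMN,
) -> RawIntensityTable:
    return RawIntensityTable(
        table=read_sample_table(path, label_column=label_column),
        internal_standard_column=internal_standard_column,
    )


def normalize_rpa(raw: RawIntensityTable) -> SampleTable:
    """Divide each sample's row by its internal-standard intensity and drop
    the internal-standard column.

    Raises ``ValueError`` naming the sample if its internal-standard
    intensity is not strictly positive.
    """
    t = raw.table
    is_idx = t.metabolite_names.index(raw.internal_standard_column)
    is_values = t.values[:, is_idx]
    bad = np.flatnonzero(is_values <= 0)
    if bad.size:
        raise ValueError(
            f"internal standard {raw.internal_standard_column!r} is not positive "
            f"for sample {t.sample_ids[bad[0]]!r}"
        )
    keep = [j for j in range(t.n_metabolites) if j != is_idx]
    values = t.values[:, keep] / is_values[:, None]
    return SampleTable(
        sample_ids=list(t.sample_ids),
        metabolite_names=[t.metabolite_names[j] for j in keep],
        values=values,
        labels=None if t.labels is None else dict(t.labels),
    )
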
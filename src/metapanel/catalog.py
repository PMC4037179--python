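"""Reference catalog of the 35 plasma metabolites detected by GC/MS.

The packaged catalog transcribes, per metabolite: GC retention time, the
per-group mean ± SD of its relative peak area (RPA, normalized to the
ribitol internal standard), and the VIP values from the four published
PLS-DA comparisons:

    a — healthy vs all MDD        b — healthy vs ELS/MDD
    c — healthy vs non-ELS/MDD    d — ELS/MDD vs non-ELS/MDD

An annotation is present only where the published table prints a VIP (its
cutoff was 1.0), so the annotation counts per comparison (15/16/12/13)
equal the published differential-metabolite counts.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .groups import ELS_MDD, HEALTHY, MDD_ALL, NON_ELS_MDD
from .sample_table import LinearClassifierPair, PanelDefinition

COMPARISON_TAGS = {
    "a": (HEALTHY, MDD_ALL),
    "b": (HEALTHY, ELS_MDD),
    "c": (HEALTHY, NON_ELS_MDD),
    "d": (ELS_MDD, NON_ELS_MDD),
}

CHEMICAL_CLASSES = (
    "amino acid",
    "fatty acid",
    "carbohydrate",
    "organic acid",
    "mineral acid",
    "sterol",
    "other",
)

# Canonical spellings for names that appear with variants in print.
# "glyceic acid" (the 9-metabolite feature panel listing) is taken to be the
# catalog's glyceric acid, its closest entry; "6-deoxidation mannopyrannose"
# is the catalog's 6-deoxy-mannopyrannose.
_ALIASES = {
    "glyceic acid": "Glyceric acid",
    "6-deoxidation mannopyrannose": "6-deoxy-mannopyrannose",
    "myo-inositol": "Myoinositol",
    "succinic acid": "Butanedioic acid",
    "tryptophan": "Tryptophane",
}


@dataclass(frozen=True)
class MetaboliteCatalogEntry:
    """One catalog row: identity, retention time, per-group RPA moments and
    VIP annotations keyed by comparison tag a–d."""

    index: int
    retention_time: float  # sort key, minutes
    retention_label: str  # verbatim label (aspartic acid has a compound one)
    name: str
    chemical_class: str
    group_moments: dict[str, tuple[float, float]]  # group -> (mean, sd)
    vip_annotations: dict[str, float]  # tag -> VIP

    def moments(self, group: str) -> tuple[float, float]:
        return self.group_moments[group]


@lru_cache(maxsize=1)
def load_reference_catalog() -> tuple[MetaboliteCatalogEntry, ...]:
    """The packaged 35-entry catalog, ordered by retention time."""
    text = resources.files("metapanel.data").joinpath("table2_catalog.tsv").read_text()
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    entries = []
    for row in rows:
        moments = {
            HEALTHY: (float(row["healthy_mean"]), float(row["healthy_sd"])),
            MDD_ALL: (float(row["mdd_mean"]), float(row["mdd_sd"])),
            ELS_MDD: (float(row["els_mean"]), float(row["els_sd"])),
            NON_ELS_MDD: (float(row["nonels_mean"]), float(row["nonels_sd"])),
        }
        vips = {
            tag: float(row[f"vip_{tag}"])
            for tag in COMPARISON_TAGS
            if row.get(f"vip_{tag}") not in (None, "")
        }
        if row["chemical_class"] not in CHEMICAL_CLASSES:
            raise ValueError(f"bad chemical class {row['chemical_class']!r}")
        for mean, sd in moments.values():
            if mean < 0 or sd < 0:
                raise ValueError(f"negative moment in catalog entry {row['name']!r}")
        entries.append(
            MetaboliteCatalogEntry(
                index=int(row["index"]),
                retention_time=float(row["rt_sort"]),
                retention_label=row["rt_label"],
                name=row["name"],
                chemical_class=row["chemical_class"],
                group_moments=moments,
                vip_annotations=vips,
            )
        )
    entries.sort(key=lambda e: e.index)
    if len(entries) != 35:
        raise ValueError(f"catalog must have 35 entries, found {len(entries)}")
    for prev, cur in zip(entries, entries[1:]):
        if not cur.retention_time > prev.retention_time:
            raise ValueError("catalog retention times must strictly increase with index")
    return tuple(entries)


def catalog_entry(name: str) -> MetaboliteCatalogEntry:
    name = canonical_name(name)
    for e in load_reference_catalog():
        if e.name == name:
            return e
    raise KeyError(f"metabolite {name!r} not in catalog")


def canonical_name(name: str) -> str:
    """Map a metabolite name to its canonical catalog spelling (identity for
    names not in the alias table; case-insensitive against the catalog)."""
    key = name.strip().lower()
    if key in _ALIASES:
        return _ALIASES[key]
    for e in load_reference_catalog():
        if e.name.lower() == key:
            return e.name
    return name


def catalog_order_key(name: str) -> tuple[int, str]:
    """Sort key: catalog index for known metabolites (ties in forward
    selection break toward the lower index), then name for unknowns."""
    try:
        return (catalog_entry(name).index, "")
    except KeyError:
        return (10**6, name)


def load_printed_model() -> tuple[LinearClassifierPair, PanelDefinition]:
    """The published example classifier (one member of the healthy-vs-MDD
    ensemble) and its 9-metabolite feature panel."""
    d = json.loads(resources.files("metapanel.data").joinpath("printed_model.json").read_text())
    pair = LinearClassifierPair.from_dict(d)
    panel = PanelDefinition(
        comparison=tuple(d["class_labels"]),
        method="tclass",
        metabolites=tuple(d["feature_names"]),
        learner="naive_bayes",
    )
    return pair, panel


@lru_cache(maxsize=1)
def load_printed_panels() -> tuple[PanelDefinition, ...]:
    """All eight published diagnostic panels (4 differential + 4 tclass)."""
    d = json.loads(resources.files("metapanel.data").joinpath("printed_panels.json").read_text())
    return tuple(
        PanelDefinition(
            comparison=tuple(p["comparison"]),
            method=p["method"],
            metabolites=tuple(p["metabolites"]),
            learner=p.get("learner"),
        )
        for p in d["panels"]
    )


def printed_panel(comparison: tuple[str, str], method: str) -> PanelDefinition:
    for p in load_printed_panels():
        if p.comparison == tuple(comparison) and p.method == method:
            return p
    raise KeyError(f"no packaged {method} panel for comparison {comparison}")
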
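"""Synthetic plasma cohorts with the statistical structure the analysis
assumes.

The study's per-sample data were never deposited; what is published are
the per-group mean ± SD of each metabolite's RPA. The generator draws each
metabolite independently from a Gaussian with those moments (``table2``
mode) at the study's group sizes (25 healthy, 23 ELS/MDD, 23 non-ELS/MDD
by default). Two further modes support calibration tests: ``null`` draws
every group from the healthy parameters (no signal), and ``separated``
shifts group means 10 pooled SDs apart on every metabolite (trivially
separable groups).

The default distribution is deliberately an *untruncated* Gaussian so the
generated moments match the catalog exactly; metabolites whose SD exceeds
their mean (e.g. sorbitol in healthy subjects) would otherwise acquire a
large truncation bias. The ``nonneg`` option resamples negative draws
(rejection at zero) for workflows that need physically valid RPAs, at the
cost of biased moments for those metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import catalog_entry, load_reference_catalog
from .groups import ELS_MDD, HEALTHY, NON_ELS_MDD, STORED_GROUPS
from .sample_table import SampleTable

MODES = ("table2", "null", "separated")
DISTRIBUTIONS = ("gaussian", "nonneg")

#: the study's group sizes
DEFAULT_N = {HEALTHY: 25, ELS_MDD: 23, NON_ELS_MDD: 23}

_GROUP_PREFIX = {HEALTHY: "H", ELS_MDD: "E", NON_ELS_MDD: "N"}
_SEPARATION_SDS = 10.0


@dataclass(frozen=True)
class GeneratorConfig:
    mode: str = "table2"
    n_per_group: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N))
    seed: int = 0
    distribution: str = "gaussian"
    metabolites: tuple[str, ...] | None = None  # default: full catalog

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(f"unknown distribution {self.distribution!r}")
        unknown = set(self.n_per_group) - set(STORED_GROUPS)
        if unknown:
            raise ValueError(f"unknown groups in n_per_group: {sorted(unknown)}")
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"need n >= 2 per group, got {n} for {g}")
        if self.metabolites is not None:
            object.__setattr__(self, "metabolites", tuple(self.metabolites))


def _group_params(config: GeneratorConfig, names: list[str]) -> dict[str, np.ndarray]:
    """(mean, sd) arrays per group, shaped (2, p), per the configured mode."""
    entries = [catalog_entry(m) for m in names]
    params: dict[str, np.ndarray] = {}
    if config.mode == "null":
        hp = np.asarray([e.moments(HEALTHY) for e in entries]).T
        for g in STORED_GROUPS:
            params[g] = hp
        return params
    if config.mode == "table2":
        for g in STORED_GROUPS:
            params[g] = np.asarray([e.moments(g) for e in entries]).T
        return params
    # separated: keep each group's catalog SDs, but space the means
    # _SEPARATION_SDS pooled SDs apart per metabolite
    sds = {g: np.asarray([e.moments(g)[1] for e in entries]) for g in STORED_GROUPS}
    pooled = np.sqrt(np.mean([sds[g] ** 2 for g in STORED_GROUPS], axis=0))
    pooled = np.maximum(pooled, 1e-12)
    base = np.asarray([e.moments(HEALTHY)[0] for e in entries])
    for k, g in enumerate(STORED_GROUPS):
        params[g] = np.vstack([base + k * _SEPARATION_SDS * pooled, sds[g]])
    return params


def generate_cohort(config: GeneratorConfig) -> SampleTable:
    """Draw a labeled cohort; identical configs give identical tables."""
    names = (
        [e.name for e in load_reference_catalog()]
        if config.metabolites is None
        else [catalog_entry(m).name for m in config.metabolites]
    )
    params = _group_params(config, names)
    rng = np.random.default_rng(config.seed)
    rows, ids, labels = [], [], []
    for g in STORED_GROUPS:  # fixed group order keeps the stream deterministic
        n = config.n_per_group.get(g, 0)
        if n == 0:
            continue
        mean, sd = params[g]
        draws = rng.normal(loc=mean, scale=sd, size=(n, len(names)))
        if config.distribution == "nonneg":
            # rejection at zero, one metabolite cell at a time
            bad = draws < 0
            while bad.any():
                draws[bad] = rng.normal(
                    loc=np.broadcast_to(mean, draws.shape)[bad],
                    scale=np.broadcast_to(sd, draws.shape)[bad],
                )
                bad = draws < 0
        rows.append(draws)
        prefix = _GROUP_PREFIX[g]
        ids.extend(f"{prefix}{i + 1:04d}" for i in range(n))
        labels.extend([g] * n)
    return SampleTable(
        sample_ids=ids,
        metabolite_names=names,
        values=np.vstack(rows),
        labels=dict(zip(ids, labels)),
    )
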
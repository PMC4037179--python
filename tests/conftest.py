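import numpy as np
import pytest

from metapanel import GeneratorConfig, SampleTable, generate_cohort
from metapanel.groups import HEALTHY, NON_ELS_MDD


def make_two_class_table(
    rng: np.random.Generator,
    n_per_class: int = 12,
    p: int = 3,
    shift: float = 0.0,
    feature_names=None,
) -> SampleTable:
    """Random two-group table: HEALTHY at 0, NON_ELS_MDD shifted by ``shift``
    on every feature."""
    names = feature_names or [f"m{j}" for j in range(p)]
    X0 = rng.normal(0.0, 1.0, size=(n_per_class, p))
    X1 = rng.normal(shift, 1.0, size=(n_per_class, p))
    ids = [f"a{i:03d}" for i in range(n_per_class)] + [f"b{i:03d}" for i in range(n_per_class)]
    labels = dict(zip(ids, [HEALTHY] * n_per_class + [NON_ELS_MDD] * n_per_class))
    return SampleTable(ids, list(names), np.vstack([X0, X1]), labels)


@pytest.fixture
def small_cohort():
    """Default-size synthetic cohort with the catalog's group moments."""
    return generate_cohort(GeneratorConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
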
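import numpy as np
import pytest

from ckdso import dataio, synth


@pytest.fixture
def toy_schema():
    """Three features (one numeric, one boolean, one categorical) + class."""
    return dataio.AttributeSchema(
        columns=(
            dataio.ColumnSpec("age", "numeric"),
            dataio.ColumnSpec("htn", "boolean", ("no", "yes")),
            dataio.ColumnSpec("appet", "categorical", ("good", "poor")),
        ),
        class_column="classification",
        positive_label="ckd",
        id_column="id",
        class_levels=("notckd", "ckd"),
    )


@pytest.fixture
def toy_table(toy_schema):
    rows = [
        ["0", "45", "yes", "good", "ckd"],
        ["1", "50", "no", "poor", "notckd"],
        ["2", None, "yes", None, "ckd"],
        ["3", "61", None, "good", "notckd"],
    ]
    return dataio.RawTable(schema=toy_schema, rows=rows, provenance="synthetic")


@pytest.fixture
def clean_cohort_matrix():
    """A 200-row cohort with planted signal and no injected artifacts."""
    spec = synth.SyntheticSpec(
        n=200, d_informative=5, d_noise=10, n_categorical=2,
        minority_fraction=0.4, missing_rate=0.0, typo_rate=0.0,
        duplicate_count=0, outlier_count=0, seed=11,
    )
    table, log = synth.generate_cohort(spec)
    return dataio.to_matrix(table), log


@pytest.fixture
def separable_matrix():
    """Tiny perfectly separable matrix: one feature splits the classes."""
    rng = np.random.default_rng(3)
    n = 60
    y = np.array([0] * 30 + [1] * 30)
    x0 = np.where(y == 1, 5.0, -5.0) + rng.normal(0, 0.1, n)
    x1 = rng.normal(0, 1, n)
    return dataio.DataMatrix(
        feature_names=["signal", "noise"],
        X=np.column_stack([x0, x1]),
        y=y,
        column_kinds=["numeric", "numeric"],
    )


class FakeRng:
    """Scripted RNG for exact-arithmetic checks of the swarm updates."""

    def __init__(self, integers=(), randoms=()):
        self._integers = list(integers)
        self._randoms = list(randoms)

    def integers(self, low, high=None, size=None):
        return self._integers.pop(0)

    def random(self, size=None):
        if size is None:
            return self._randoms.pop(0)
        n = size if isinstance(size, int) else int(np.prod(size))
        out = np.array([self._randoms.pop(0) for _ in range(n)])
        return out.reshape(size) if not isinstance(size, int) else out
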
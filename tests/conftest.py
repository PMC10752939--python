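import numpy as np
import pytest

from flda.datatypes import ExpressionMatrix, FactorDesign


def make_design(a=2, b=2, cells_per_type=2, features=("feature_i", "feature_j")):
    """Complete a x b design with the given number of cells per type."""
    labels, cells = [], []
    k = 0
    for i in range(a):
        for j in range(b):
            for _ in range(cells_per_type):
                cells.append(f"c{k}")
                labels.append((f"i{i + 1}", f"j{j + 1}"))
                k += 1
    return FactorDesign(cell_ids=cells, features=list(features), labels=labels)


def make_expression(values, layer_tag="log"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"g{k + 1}" for k in range(values.shape[0])],
        [f"c{k}" for k in range(values.shape[1])],
        layer_tag,
    )


@pytest.fixture
def small_design():
    return make_design(2, 2, 2)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
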
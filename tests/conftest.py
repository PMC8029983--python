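import numpy as np
import pandas as pd
import pytest

from panomix import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(values, kind="array", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), kind=kind)


def two_group_labels(n1, n2, a="tumor", b="normal", samples=None):
    samples = samples or [f"s{j}" for j in range(n1 + n2)]
    return pd.Series([a] * n1 + [b] * n2, index=samples, name="group")
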
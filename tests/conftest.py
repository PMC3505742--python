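import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from purelim import CountMatrix, DilutionDesign, ExpressionMatrix

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def design8():
    """The eight-point purity grid (0, 0.5, 1, 5, 10, 20, 30, 100 percent)."""
    return DilutionDesign.default()


@pytest.fixture
def design3():
    return DilutionDesign((0.0, 0.5, 1.0), ("blank", "half", "pure"))


@pytest.fixture
def tiny_intensity(design3):
    df = pd.DataFrame(
        [[10.0, 60.0, 110.0], [5.0, 5.0, 5.0], [0.0, 50.0, 100.0]],
        index=["gA", "gB", "gC"],
        columns=list(design3.sample_ids),
    )
    return ExpressionMatrix(df, design3)


@pytest.fixture
def tiny_counts(design3):
    df = pd.DataFrame(
        [[0, 30, 60], [2, 2, 2], [0, 0, 16]],
        index=["gA", "gB", "gC"],
        columns=list(design3.sample_ids),
    )
    return CountMatrix(df, design3)


@pytest.fixture
def pair_design():
    return DilutionDesign((1.0, 0.0), ("s1", "s2"))


def make_pair_counts(y1, y2, pair_design):
    genes = [f"g{i}" for i in range(len(y1))]
    df = pd.DataFrame(
        {"s1": np.asarray(y1), "s2": np.asarray(y2)}, index=genes
    )
    return CountMatrix(df, pair_design)


@pytest.fixture
def pair_counts_factory(pair_design):
    def _make(y1, y2):
        return make_pair_counts(y1, y2, pair_design)

    return _make
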
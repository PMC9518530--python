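import numpy as np
import pytest
from hypothesis import settings

from emresilience.core import IndicatorDefinition, IndicatorPanel

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_scheme(n, dimensions=None, attributes=None):
    dims = dimensions or ["resistance", "restore", "adaptability", "collaborative"]
    scheme = []
    for j in range(n):
        attr = attributes[j] if attributes else "positive"
        scheme.append(
            IndicatorDefinition(f"X{j+1:02d}", dims[j % len(dims)], attr)
        )
    return scheme


@pytest.fixture
def small_panel():
    """Well-formed 3-region, 2-indicator panel."""
    return IndicatorPanel(
        ["A", "B", "C"],
        make_scheme(2),
        np.array([[0.0, 10.0], [5.0, 20.0], [10.0, 30.0]]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid49():
    """Integer coordinates of a 7x7 lattice."""
    xx, yy = np.meshgrid(np.arange(7), np.arange(7))
    return np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
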
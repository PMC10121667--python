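import numpy as np
import pytest

from tmakit.spatial import DiscWindow, MarkedPointPattern


@pytest.fixture
def disc_window() -> DiscWindow:
    return DiscWindow(center=(0.0, 0.0), radius=300.0)


@pytest.fixture
def random_bivariate_pattern(disc_window) -> MarkedPointPattern:
    """25 + 25 random points of two types on a disc core."""
    rng = np.random.default_rng(42)
    pts = disc_window.sample_uniform(50, rng)
    marks = np.array(["CD8"] * 25 + ["CAIX"] * 25, dtype=object)
    return MarkedPointPattern(points=pts, marks=marks, window=disc_window)
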
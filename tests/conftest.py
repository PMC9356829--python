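import numpy as np
import pytest

from miforest import LabeledPanel, generate_panel, separability_preset


@pytest.fixture(scope="session")
def easy_panel():
    """Well-separated 5-class Gaussian panel (6 SD between adjacent classes)."""
    return generate_panel(separability_preset("easy"), n_per_class=100, seed=42)


@pytest.fixture(scope="session")
def easy_split(easy_panel):
    """Seeded 60/40 stratified split of the easy panel."""
    rng = np.random.default_rng(7)
    return easy_panel.stratified_split(0.6, rng)


@pytest.fixture()
def tiny_panel():
    """1-D two-class panel with an obvious perfect split at 6.0."""
    return LabeledPanel(
        np.array([[1.0], [2.0], [10.0], [11.0]]),
        np.array([0, 0, 1, 1]),
        ["a", "b"],
        ["x"],
    )
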
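import numpy as np
import pytest

from gbogwo import FSProblemSpec, SearchSettings, make_fs_problem


def sphere(x: np.ndarray) -> float:
    return float(np.sum(np.asarray(x) ** 2))


@pytest.fixture
def small_settings() -> SearchSettings:
    return SearchSettings(N=20, MaxIt=30, seed=1)


@pytest.fixture(scope="session")
def fs_problem():
    """Separable 5-informative / 45-noise problem with known ground truth."""
    table, truth = make_fs_problem(
        FSProblemSpec(n_instances=200, n_informative=5, n_noise=45,
                      n_classes=6, effect_size=3.0, seed=7))
    return table, truth
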
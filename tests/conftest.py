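import numpy as np
import pytest

from polysas import forward
from polysas.forward import BackgroundSpec, DistributionSet
from polysas.greens import ParameterGrid, QGrid, sphere_form_green
from polysas.inverse import IntensityData


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_sphere_problem():
    """A compact noise-free sphere inversion problem with known truth."""
    r = ParameterGrid("radius", np.linspace(50.0, 200.0, 30))
    q = QGrid((np.logspace(-3.0, 0.0, 120),))
    green = sphere_form_green(q, r, contrast=1.0)
    rv = r.values
    w = np.exp(-0.5 * ((rv - 120.0) / 20.0) ** 2)
    w /= w.sum()
    truth = DistributionSet([w], xi=1.5, background=BackgroundSpec("flat", b=0.0))
    mean = forward.intensity(green, truth)
    data = IntensityData(q=q, mean=mean, std=0.25 * mean)
    return green, truth, data


def random_simplex(rng, n):
    w = rng.uniform(0.05, 1.0, n)
    return w / w.sum()
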
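import numpy as np
import pytest

from gedmix import CensoredSample, GEDParams, MixtureParams, sample_mixture


@pytest.fixture
def omega0() -> MixtureParams:
    """The simulation study's reference parameter set."""
    return MixtureParams(GEDParams(0.50, 1.20), GEDParams(0.75, 1.50), 0.45)


@pytest.fixture
def labeled_sample(omega0):
    """A labelled complete sample of moderate size."""
    times, labels = sample_mixture(400, omega0, seed=123)
    return CensoredSample(times, np.ones(len(times), dtype=int), labels,
                          t_anchor=float(times.max()))


def make_complete_sample(omega, n, seed):
    times, labels = sample_mixture(n, omega, seed=seed)
    return CensoredSample(times, np.ones(n, dtype=int), labels,
                          t_anchor=float(times.max()))
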
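import numpy as np
import pytest

from galmod import InductionModel, simulate_profile
from galmod.simulate import Condition, PopulationSample


@pytest.fixture(scope="session")
def balanced_model():
    """Thresholds mid-grid and equal: transition centred in the titration."""
    return InductionModel(E10=0.0625, F90=0.0625)


@pytest.fixture(scope="session")
def bimodal_model():
    """E10 above F90: partially induced conditions express at high level."""
    return InductionModel(E10=0.125, F90=0.0625)


@pytest.fixture(scope="session")
def bimodal_profile(bimodal_model):
    return simulate_profile(bimodal_model, seed=42)


def make_two_component_sample(
    sep_mult: float, minor_weight: float, seed: int, n: int = 20_000,
    sd: float = 0.2, base: float = -3.0,
) -> PopulationSample:
    """Constructed mixture: minor mode at `base`, major `sep_mult*sd` above."""
    rng = np.random.default_rng(seed)
    n_minor = round(minor_weight * n)
    major_mean = base + sep_mult * sd
    values = np.concatenate(
        [rng.normal(base, sd, n_minor), rng.normal(major_mean, sd, n - n_minor)]
    )
    return PopulationSample(values, Condition(glucose=0.1, label="constructed"))
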
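import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dsbredox.synthetic import CftModel, cysteine_template, cystine_template, sample_cft_works


@pytest.fixture(scope="session")
def cys_template():
    return cysteine_template()


@pytest.fixture(scope="session")
def cys2_template():
    return cystine_template()


@pytest.fixture()
def cft_pair():
    """A well-behaved CFT-consistent work-set pair at known truth."""
    model = CftModel(dG_true=30.0, sigma=4.0, n_per_direction=500, seed=1234)
    fwd, bwd = sample_cft_works(model)
    return model, fwd, bwd


def moment_matched(samples: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Rescale samples to exact target mean and (ddof=1) sd."""
    z = (samples - samples.mean()) / samples.std(ddof=1)
    return mean + sd * z
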
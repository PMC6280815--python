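import warnings

import numpy as np
import pytest

import tsen


@pytest.fixture(scope="session")
def small_study() -> tsen.SyntheticStudy:
    """A 3-site x 4-time-point study, 40 genera, mild observation noise."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design = tsen.StudyDesign(n_sites=3, n_timepoints=4, seed=7)
        return tsen.generate_study(
            design, n_genera=40, rb_target=0.6, core_fraction=0.4,
            noise_sd=0.05, seed=7,
        )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_stable_model(n: int, seed: int) -> tuple[tsen.GLVModel, np.ndarray]:
    """Small random stable gLV model and its interior equilibrium."""
    r = np.random.default_rng(seed)
    x_star = r.uniform(0.1, 1.0, n)
    model = tsen.generate_glv_model(x_star, [f"t{i}" for i in range(n)], seed=seed)
    return model, x_star
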
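import logging

import numpy as np
import pytest

from scump.response_data import LabeledSample, ResponseMatrix
from scump.simulate import HumanModel, default_grm_params, generate_bots, generate_humans, uniform_bot

logging.getLogger("scump").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def human_model_32() -> HumanModel:
    """Default 32-item synthetic human population."""
    return HumanModel(variant="grm", grm=default_grm_params())


@pytest.fixture(scope="session")
def human_model_16() -> HumanModel:
    """Shorter 16-item instrument used for classifier-contrast runs."""
    return HumanModel(variant="grm", grm=default_grm_params(n_items=16))


def make_calibration(human_model: HumanModel, n_humans: int, n_bots: int,
                     seed: int) -> LabeledSample:
    rng = np.random.default_rng(seed)
    humans = generate_humans(human_model, n_humans, rng)
    bots = generate_bots(uniform_bot(), n_bots, human_model.n_items, rng,
                         human_model.categories)
    return LabeledSample(
        responses=ResponseMatrix(
            values=np.vstack([humans.values, bots.values]),
            categories=human_model.categories),
        labels=np.concatenate([np.zeros(n_humans, dtype=int),
                               np.ones(n_bots, dtype=int)]),
    )


@pytest.fixture(scope="session")
def calibration_16(human_model_16) -> LabeledSample:
    return make_calibration(human_model_16, 200, 500, seed=123)
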
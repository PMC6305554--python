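import numpy as np
import pytest

from perispace.body_model import standard_body
from perispace.synthetic_data import (
    GeneratorConfig,
    generate_rod_trial,
    generate_walk_trial,
)


@pytest.fixture(scope="session")
def model():
    return standard_body()


@pytest.fixture(scope="session")
def small_cfg():
    """Short trials keep the suite fast while exercising every stage."""
    return GeneratorConfig(duration_s=2.0)


@pytest.fixture(scope="session")
def walk_trial(model, small_cfg):
    return generate_walk_trial(model, small_cfg, seed=11)


@pytest.fixture(scope="session")
def rod_trial(model, small_cfg):
    return generate_rod_trial(model, small_cfg, seed=13, rod_height_mm=18.0)
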
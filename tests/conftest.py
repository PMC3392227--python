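import numpy as np
import pytest

from avtoj import schedules


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def exp2_bias_map():
    return {"low": "sound_first", "high": "light_first"}


@pytest.fixture(scope="session")
def exp4_adapt_map():
    return {"high": -235, "low": 235}


@pytest.fixture(scope="session")
def exp1_counts():
    return schedules.schedule_counts(1, "sound_first")
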
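import numpy as np
import pandas as pd
import pytest

from maximin_choice.core import ChoicePair, Lottery
from maximin_choice.gaze import Layout
from maximin_choice.synth import AgentSpec, DesignConfig, generate_lottery_set


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def lottery_set():
    return generate_lottery_set(DesignConfig(), np.random.default_rng(7))


@pytest.fixture
def agent():
    return AgentSpec()


@pytest.fixture
def layout():
    return Layout()


@pytest.fixture
def simple_pair():
    return ChoicePair(Lottery((300.0, 600.0, 900.0)), Lottery((450.0, 500.0, 550.0)))
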
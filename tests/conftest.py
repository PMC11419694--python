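"""Shared fixtures: model runners with response caches, reused across tests."""

import numpy as np
import pytest

from mocmask.experiments import ModelRunner

AUDIO_FS = 100_000.0
RATE_FS = 10_000.0


@pytest.fixture(scope="session")
def runner_ic_eff():
    return ModelRunner(stage="ic", efferents=True)


@pytest.fixture(scope="session")
def runner_ic_noeff():
    return ModelRunner(stage="ic", efferents=False)


@pytest.fixture(scope="session")
def runner_an_eff():
    return ModelRunner(stage="an", efferents=True)


@pytest.fixture(scope="session")
def runner_an_noeff():
    return ModelRunner(stage="an", efferents=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240365)
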
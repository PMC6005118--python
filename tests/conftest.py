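import numpy as np
import pytest

from neglectsim import RunConfig, build_flat_model, build_multiscale_model, generate_display


@pytest.fixture
def cfg():
    return RunConfig()


@pytest.fixture
def mcfg():
    return RunConfig(model_kind="multiscale")


@pytest.fixture
def display():
    return generate_display(16, "balanced", seed=7)


@pytest.fixture
def flat_model(cfg, display):
    return build_flat_model(display.targets, cfg)


@pytest.fixture
def multiscale_model(mcfg, display):
    return build_multiscale_model(display.targets, mcfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
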
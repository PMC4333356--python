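import pytest

import rdgrow as rg


@pytest.fixture(scope="session")
def scenarios():
    """Built-in scenarios keyed by name."""
    return {s.name: s for s in rg.builtin_scenarios()}


@pytest.fixture(scope="session")
def fig1e(scenarios):
    """Exponential growth, D = 1e-3, k = 0.105, beta = 0.2."""
    return scenarios["fig1e"]


@pytest.fixture(scope="session")
def fig1i(scenarios):
    """Exponential growth, D = 1e-2, k = 0.105, beta = 0.2."""
    return scenarios["fig1i"]
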
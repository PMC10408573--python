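import pytest

from selgram.constraints import configure_constraints, default_constraints


@pytest.fixture(autouse=True)
def _reset_active_constraints():
    """Tests that reconfigure the process-wide constraints must not leak."""
    configure_constraints(default_constraints())
    yield
    configure_constraints(default_constraints())


@pytest.fixture(scope="session")
def default_alphabet():
    from selgram.toolkit import get_semantic_robust_alphabet

    return sorted(get_semantic_robust_alphabet(default_constraints()))
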
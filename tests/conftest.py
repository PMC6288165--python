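import pytest

from droughtrings.synthetic import (DesignSpec, GeneratorParams,
                                    generate_design, simulate_measurements)


@pytest.fixture(scope="session")
def default_spec():
    return DesignSpec(seed=123)


@pytest.fixture(scope="session")
def design(default_spec):
    return generate_design(default_spec)


@pytest.fixture(scope="session")
def tables(default_spec, design):
    """One simulated trial shared across tests (read-only)."""
    return simulate_measurements(design, default_spec, GeneratorParams())
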
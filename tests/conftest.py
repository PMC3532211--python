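import pytest

from mixedfishery import build_default_params, solve_equilibrium


@pytest.fixture(scope="session")
def params():
    """Default parameter set (shipped configuration, validated)."""
    return build_default_params()


@pytest.fixture(scope="session")
def eq_nofishing(params):
    """Coexistence equilibrium with no overlap and no fishing."""
    return solve_equilibrium(params, omega=0.0, E=0.0)


@pytest.fixture(scope="session")
def eq_unit_effort(params):
    """Equilibrium at no overlap and unit effort (the calibration setting)."""
    return solve_equilibrium(params, omega=0.0, E=1.0)
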
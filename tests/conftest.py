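import pytest

from gastroloop.params import load_registry
from gastroloop.simulator import Scenario, simulate


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def parasym_traj(registry):
    """Parasympathetic reference run at V_tot = 0.6 L."""
    return simulate(Scenario(mode="fixed_volume", V_tot=0.6, g_cal=0.0,
                             O_sym=0, duration=200.0), registry)


@pytest.fixture(scope="session")
def sympathetic_traj(registry):
    """Sympathetic run at V_tot = 0.6 L."""
    return simulate(Scenario(mode="fixed_volume", V_tot=0.6, g_cal=0.0,
                             O_sym=1, duration=200.0), registry)


@pytest.fixture(scope="session")
def volume_trajs(registry):
    """Volume sweep runs at 0.2, 0.5 and 1.1 L."""
    return {
        v: simulate(Scenario(mode="fixed_volume", V_tot=v, g_cal=0.0,
                             O_sym=0, duration=200.0), registry)
        for v in (0.2, 0.5, 1.1)
    }


@pytest.fixture(scope="session")
def emptying_trajs(registry):
    """Emptying runs for the four studied caloric densities."""
    return {
        g: simulate(Scenario(mode="emptying", V_meal_0=0.3, g_cal=g,
                             O_sym=0, duration=440.0), registry)
        for g in (0.33, 0.38, 0.50, 0.67)
    }
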
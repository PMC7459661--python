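import pytest

from burnoutsim.engine import RunConfig
from burnoutsim.scenarios import PERSONA_IDS, run_persona
from burnoutsim.simplified import reference_run


@pytest.fixture(scope="session")
def reference():
    """The frozen simplified-model reference run (computed once)."""
    return reference_run()


@pytest.fixture(scope="session")
def persona_runs():
    """Default 100-week trajectories of all three personas."""
    return {pid: run_persona(pid) for pid in PERSONA_IDS}


@pytest.fixture(scope="session")
def persona_runs_fine():
    """Persona trajectories at half the default step size."""
    config = RunConfig(horizon=100.0, dt=0.0625)
    return {pid: run_persona(pid, config) for pid in PERSONA_IDS}
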
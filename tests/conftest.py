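import pytest
from hypothesis import HealthCheck, settings

import bmiburden as bb
from bmiburden.engine import RunContext, run_mslt
from bmiburden.scenarios import build_canonical_scenarios, tmrel_trajectory
from bmiburden.synthetic import SyntheticParams

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return SyntheticParams(seed=1)


@pytest.fixture(scope="session")
def inputs(params):
    return bb.generate_bundle(params)


@pytest.fixture(scope="session")
def context(inputs):
    return RunContext(inputs)


@pytest.fixture(scope="session")
def trajectories(inputs):
    return build_canonical_scenarios(inputs.config, inputs.bmi_baseline)


@pytest.fixture(scope="session")
def scenario_runs(inputs, trajectories, context):
    return {sid: run_mslt(inputs, traj, context) for sid, traj in trajectories.items()}


@pytest.fixture(scope="session")
def tmrel_run(inputs, context):
    traj = tmrel_trajectory(inputs.config, inputs.bmi_baseline)
    return run_mslt(inputs, traj, context)


@pytest.fixture(scope="session")
def reported():
    return bb.load_reported_burden()
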
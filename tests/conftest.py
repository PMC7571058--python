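import pytest
from hypothesis import HealthCheck, settings

from vigilband.fusion import fuse_session
from vigilband.series import StateSchedule
from vigilband.synthetic import generate_session

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scripted_schedule() -> StateSchedule:
    """90 s session with one agitation episode on [30, 60)."""
    return StateSchedule(((0.0, 30.0, "idle"), (30.0, 60.0, "agitated"),
                          (60.0, 90.0, "idle")))


@pytest.fixture(scope="session")
def scripted_session(scripted_schedule):
    return generate_session(scripted_schedule, 90.0, seed=3)


@pytest.fixture(scope="session")
def scripted_frames(scripted_session):
    return fuse_session(scripted_session)
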
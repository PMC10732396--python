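from datetime import datetime, timedelta

import pytest
from hypothesis import HealthCheck, settings

from abxcascade.episode import EpisodeTimestamps, PatientEpisode
from abxcascade.registry import default_registry
from abxcascade.susceptibility import FEATURE_NAMES, AgentModel, GNModelSet

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

T0 = datetime(2021, 11, 5, 12, 0)


def make_episode(**overrides) -> PatientEpisode:
    """Episode factory: an eligible 70-year-old undifferentiated-sepsis
    patient on piperacillin-tazobactam unless overridden."""
    ts = overrides.pop(
        "timestamps",
        EpisodeTimestamps(
            first_antibiotic_time=T0,
            blood_culture_order_time=T0 - timedelta(hours=2),
            assessment_time=T0 + timedelta(hours=4),
        ),
    )
    base = dict(
        episode_id="E1",
        patient_id="P1",
        age=70,
        female=False,
        admitted=True,
        qsofa=1,
        syndrome="undifferentiated",
        current_regimen={"piperacillin-tazobactam"},
        timestamps=ts,
    )
    base.update(overrides)
    return PatientEpisode(**base)


@pytest.fixture
def registry():
    return default_registry()


@pytest.fixture
def episode_factory():
    return make_episode


def flat_model_set(probabilities: dict[str, float]) -> GNModelSet:
    """Model set with zero coefficients and intercepts chosen so every
    patient gets exactly the given per-agent probability."""
    import math

    models = {
        agent: AgentModel(
            agent=agent,
            intercept=math.log(p / (1 - p)),
            coefficients={f: 0.0 for f in FEATURE_NAMES},
        )
        for agent, p in probabilities.items()
    }
    return GNModelSet(models=models)


@pytest.fixture
def flat_models():
    return flat_model_set
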
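import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from reacheval import (
    FeatureOptions,
    ReachTarget,
    SyntheticConfig,
    TrialTrajectory,
    extract_features,
    generate_normal_session,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_trial(
    t_s,
    x_cm,
    y_cm,
    v_mps=None,
    recorded_ms=None,
    target=None,
    arm="dominant",
    rate=75.0,
):
    return TrialTrajectory(
        subject="T01",
        arm=arm,
        target=target or ReachTarget(0, 0.0, 10.0, 2.0),
        t_s=np.asarray(t_s, float),
        x_cm=np.asarray(x_cm, float),
        y_cm=np.asarray(y_cm, float),
        v_mps=None if v_mps is None else np.asarray(v_mps, float),
        recorded_movement_time_ms=recorded_ms,
        sampling_rate_hz=rate,
    )


@pytest.fixture(scope="session")
def pilot_normal_session():
    """24-trial normal-law session (8 directions x 3 distances)."""
    cfg = SyntheticConfig(seed=11)
    return generate_normal_session(cfg)


@pytest.fixture(scope="session")
def validation_normal_features():
    """Extracted features of a 120-trial normal-law session."""
    cfg = SyntheticConfig.validation_experiment(seed=17)
    session, truth = generate_normal_session(cfg)
    ext = extract_features(session, FeatureOptions(compute_ns=False, window="full"))
    return cfg, truth, ext.features
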
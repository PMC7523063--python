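import numpy as np
import pytest

from meows_ri import DEFAULT_BANDS, study_replica_fixture


@pytest.fixture(scope="session")
def bands():
    return DEFAULT_BANDS


@pytest.fixture(scope="session")
def replica():
    """The deterministic 478-record study-replica cohort."""
    return study_replica_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_observation(rng, p_missing=0.15):
    """Random admission vitals dict over the admissible domains."""
    while True:
        obs = {
            "temperature": round(float(rng.uniform(25, 45)), 1),
            "systolic_bp": float(rng.integers(0, 321)),
            "diastolic_bp": float(rng.integers(0, 251)),
            "pulse": float(rng.integers(0, 321)),
            "respiratory_rate": float(rng.integers(0, 121)),
            "avpu": ["alert", "voice", "pain", "unconscious"][int(rng.integers(4))],
            "urine_output": (
                "not_measured" if rng.random() < 0.1 else float(rng.integers(0, 301))
            ),
        }
        for key in list(obs):
            if rng.random() < p_missing:
                obs[key] = None
        if any(v is not None for v in obs.values()):
            return obs
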
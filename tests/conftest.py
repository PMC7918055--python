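import numpy as np
import pytest

import emg2kin as ek


@pytest.fixture(scope="session")
def synergy():
    return ek.SynergyModel.default(seed=2)


@pytest.fixture(scope="session")
def quick_recording(synergy):
    """One Task_1 quick trial, shared read-only across tests."""
    return ek.generate_recording(
        ek.task_profile("Task_1"), "quick", trial_index=0,
        synergy=synergy, seed=3,
    )


@pytest.fixture(scope="session")
def processed(quick_recording):
    return ek.preprocess_recording(quick_recording)


@pytest.fixture(scope="session")
def small_experiment():
    """Reduced-scale experiment: 2 tasks x 2 speeds x 3 trials."""
    cfg = ek.ExperimentConfig(trials_per_condition=3, master_seed=1)
    return ek.generate_experiment(cfg)


@pytest.fixture(scope="session")
def segments_by_condition(small_experiment):
    out = {}
    for rec in small_experiment:
        key = (rec.task_id, rec.speed)
        out.setdefault(key, []).extend(
            ek.segment_cycles(ek.preprocess_recording(rec))
        )
    return out


def rng(seed):
    return np.random.default_rng(seed)
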
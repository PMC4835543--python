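import numpy as np
import pandas as pd
import pytest

import fscvda as f


@pytest.fixture(scope="session")
def default_config():
    return f.TaskConfig()


@pytest.fixture(scope="session")
def templates():
    return f.make_templates()


@pytest.fixture(scope="session")
def baseline_session():
    """One completed baseline session with its dopamine trace (noisy)."""
    sched = f.generate_schedule(f.TaskConfig(), "baseline_A", seed=11)
    sim = f.simulate_behavior(sched, f.ValueState(), seed=12)
    trace = f.simulate_concentration(sim, seed=13)
    return sim, trace


@pytest.fixture(scope="session")
def quiet_session():
    """A completed session with a noise-free, pH-free dopamine trace."""
    sched = f.generate_schedule(f.TaskConfig(), "baseline_A", seed=21)
    sim = f.simulate_behavior(sched, f.ValueState(), seed=22)
    kin = f.KineticsParams(noise_sd_nm=0.0, ph_drift_sd=0.0)
    trace = f.simulate_concentration(sim, kin, seed=23)
    return sim, trace


def make_aligned(n_trials=40, T=50, seed=0, labels=None, data=None):
    """Hand-built AlignedTraces for statistics tests."""
    rng = np.random.default_rng(seed)
    if data is None:
        data = rng.standard_normal((n_trials, T))
    time = np.linspace(-2, 5, data.shape[1])
    if labels is None:
        labels = pd.DataFrame({
            "index": np.arange(n_trials),
            "animal": "r00",
            "is_more": (np.arange(n_trials) % 5 == 0).astype(float),
            "is_food": (np.arange(n_trials) % 2).astype(float),
        })
    return f.AlignedTraces(data=data, time=time, labels=labels,
                           event="reward")
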
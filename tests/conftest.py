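import numpy as np
import pytest

from popdecode import taskgen


@pytest.fixture(scope="session")
def small_trials():
    cfg = taskgen.TaskConfig(n_blocks_per_session=4, n_stimuli_per_block=32,
                             seed=7)
    return taskgen.generate_task_sequence(cfg)


@pytest.fixture(scope="session")
def default_trials():
    return taskgen.generate_task_sequence(taskgen.TaskConfig(seed=1))


def _make_epochs(seed=0, n_blocks=8, n_per_block=48, **sim_kw):
    task = taskgen.TaskConfig(n_blocks_per_session=n_blocks,
                              n_stimuli_per_block=n_per_block, seed=seed)
    trials = taskgen.generate_task_sequence(task)
    defaults = dict(n_sensors=24, tmin_ms=-250.0, tmax_ms=600.0, dt_ms=12.0,
                    stim_gain=0.6, seed=seed + 1000)
    defaults.update(sim_kw)
    sim = taskgen.SimConfig(**defaults)
    return taskgen.generate_sensor_epochs(trials, sim)


@pytest.fixture(scope="session")
def make_epochs():
    """Factory for desk-scale simulated subjects."""
    return _make_epochs


@pytest.fixture(scope="session")
def stim_epochs(make_epochs):
    """One subject with a static stimulus code only."""
    return make_epochs(seed=3)


@pytest.fixture(scope="session")
def rich_epochs(make_epochs):
    """One subject with stimulus, template and angular-distance codes."""
    return make_epochs(seed=5, template_gain=0.4, distance_gain=0.5,
                       distance_onset_ms=350.0)
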
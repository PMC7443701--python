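import numpy as np
import pandas as pd
import pytest

from lexdecode import (
    EffectSpec,
    build_stimulus_set,
    build_trial_sets,
    counterbalance,
    schedule_run,
    simulate_pattern_set,
)
from lexdecode.design import TimingConfig
from lexdecode.simulate import concat_pattern_sets


@pytest.fixture(scope="session")
def stimulus_set():
    return build_stimulus_set(seed=0)


@pytest.fixture(scope="session")
def trial_sets(stimulus_set):
    return build_trial_sets(stimulus_set)


@pytest.fixture(scope="session")
def timing():
    return TimingConfig()


@pytest.fixture(scope="session")
def make_task_patterns(trial_sets):
    """Factory: one participant's 4-run pattern set for one task."""

    def _make(effect_spec: EffectSpec, seed: int = 0, task: str = "semantic", participant: int = 0):
        chunks = []
        run_no = 0
        for run_idx, (t, set_idx) in enumerate(counterbalance(participant)):
            if t != task:
                continue
            run_no += 1
            ev = schedule_run(
                trial_sets[set_idx - 1], t, seed=seed * 1000 + run_idx
            ).assign(run=run_no)
            chunks.append(simulate_pattern_set(ev, effect_spec, seed=seed * 1000 + 500 + run_idx))
        return concat_pattern_sets(chunks)

    return _make


@pytest.fixture(scope="session")
def semantic_events(trial_sets):
    """One scheduled semantic run (set 1)."""
    return schedule_run(trial_sets[0], "semantic", seed=11).assign(run=1)
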
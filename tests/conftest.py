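import numpy as np
import pandas as pd
import pytest

from symwm import schedule as sched
from symwm import stimuli


@pytest.fixture(scope="session")
def stimulus_set():
    return stimuli.generate_stimulus_set(7)


@pytest.fixture(scope="session")
def default_schedule(stimulus_set):
    return sched.build_schedule(3, stimulus_set)


@pytest.fixture(scope="session")
def layout():
    return sched.compute_layout()


@pytest.fixture(scope="session")
def short_events():
    """A compact event stream for GLM tests: 24 events over ~260 s."""
    rng = np.random.default_rng(11)
    conds = np.resize(list(sched.CONDITIONS), 24)
    rng.shuffle(conds)
    onsets = np.cumsum(rng.uniform(8, 13, size=24)) + 5
    return pd.DataFrame({"onset_s": onsets, "duration_s": 0.25, "condition": conds})
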
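import numpy as np
import pytest

import stopvar as sv
from stopvar.task import TaskDesign


@pytest.fixture(scope="session")
def default_params() -> sv.RaceModelParams:
    return sv.RaceModelParams(400.0, 50.0, 100.0, 200.0, 30.0, 50.0, p_tf=0.0)


@pytest.fixture(scope="session")
def default_design() -> TaskDesign:
    return TaskDesign()


@pytest.fixture(scope="session")
def default_session(default_params, default_design) -> sv.ParticipantSession:
    return sv.simulate_session(default_params, default_design, rng_seed=123)


@pytest.fixture(scope="session")
def tiny_design() -> TaskDesign:
    # 32 trials/block: 8 stop + 24 go, gaps {1,2,4,5} twice each
    return TaskDesign(n_blocks=1, trials_per_block=32)


def make_session(n_stop, n_stop_failed, go_rts, ssds=None, max_rt=1500.0,
                 group="adult", subject_id="hand-0"):
    """Hand-built session with explicit stop outcomes and go RTs."""
    n_go = len(go_rts)
    n = n_go + n_stop
    design = TaskDesign(
        n_blocks=1, trials_per_block=n, stop_fraction=n_stop / n, max_rt=max_rt
    )
    trials = []
    idx = 0
    ssds = list(ssds) if ssds is not None else [250.0] * n_stop
    for rt in go_rts:
        trials.append(
            sv.TrialRecord(index=idx, block=0, kind="go", direction="left",
                           response="left" if rt is not None else "none", rt=rt,
                           onset=4.0 * idx)
        )
        idx += 1
    for k in range(n_stop):
        failed = k < n_stop_failed
        trials.append(
            sv.TrialRecord(index=idx, block=0, kind="stop", direction="right",
                           ssd=ssds[k], response="right" if failed else "none",
                           rt=500.0 + 10 * k if failed else None, onset=4.0 * idx)
        )
        idx += 1
    return sv.ParticipantSession(subject_id=subject_id, group=group,
                                 design=design, trials=trials)


@pytest.fixture
def make_hand_session():
    return make_session
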
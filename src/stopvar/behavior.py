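"""Quality control and horse-race behavioral summaries.

The canonical (integration) SSRT estimator rank-orders the correct
go-trial RTs, finds the RT at the percentile equal to the proportion of
failed inhibitions, and subtracts the mean SSD.  Go omissions are by
default assigned the response deadline (max RT) before rank ordering,
which limits the bias omissions would otherwise introduce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import DataError
from .task import ParticipantSession


@dataclass(frozen=True)
class StoppingSummary:
    """Per-subject stopping summary (counts, rates, mean SSD/RT, SSRT)."""

    subject_id: str
    group: str
    n_go: int
    n_stop: int
    pct_stop_success: float
    mean_ssd: float
    mean_go_rt: float
    ssrt_integration: Optional[float] = None


def stop_success_pct(session: ParticipantSession) -> float:
    stops = session.stop_trials
    if not stops:
        raise DataError(f"session {session.subject_id} has no stop trials")
    return 100.0 * sum(t.is_successful_stop for t in stops) / len(stops)


def qc_filter(session: ParticipantSession, min_stop_success_pct: float = 30.0) -> bool:
    """True iff the session is retained (stop-success rate >= threshold)."""
    return stop_success_pct(session) >= min_stop_success_pct


def _go_rt_pool(session: ParticipantSession, assign_max_rt_to_omissions: bool = True):
    """Correct go-trial RTs; omissions optionally enter at the deadline.

    Wrong-direction responses are excluded entirely (they are errors,
    not slow correct responses, so they get no deadline substitute).
    """
    rts = [t.rt for t in session.go_trials if t.is_correct_go]
    if assign_max_rt_to_omissions:
        n_omit = sum(1 for t in session.go_trials if not t.responded)
        rts.extend([session.design.max_rt] * n_omit)
    return np.sort(np.asarray(rts, dtype=float))


def summarize_stopping(session: ParticipantSession, ssrt: bool = True) -> StoppingSummary:
    """Counts, stop-success percentage, mean SSD and mean correct-go RT."""
    stops = session.stop_trials
    if not stops:
        raise DataError(f"session {session.subject_id} has no stop trials")
    pct = stop_success_pct(session)
    correct_rts = [t.rt for t in session.go_trials if t.is_correct_go]
    ssrt_val = None
    if ssrt:
        try:
            ssrt_val = compute_ssrt_integration(session)
        except DataError:
            ssrt_val = None
    return StoppingSummary(
        subject_id=session.subject_id,
        group=session.group,
        n_go=len(session.go_trials),
        n_stop=len(stops),
        pct_stop_success=pct,
        mean_ssd=float(np.mean([t.ssd for t in stops])),
        mean_go_rt=float(np.mean(correct_rts)) if correct_rts else float("nan"),
        ssrt_integration=ssrt_val,
    )


def compute_ssrt_integration(
    session: ParticipantSession, assign_max_rt_to_omissions: bool = True
) -> float:
    """Integration-method SSRT in ms.

    With p the proportion of failed inhibitions and N rank-ordered
    correct-go RTs, returns the RT at index ceil(p*N) (1-based, no
    interpolation) minus the mean SSD over all stop trials.
    """
    stops = session.stop_trials
    if not stops:
        raise DataError("no stop trials: SSRT undefined")
    p = sum(not t.is_successful_stop for t in stops) / len(stops)
    if p == 0.0:
        raise DataError("no failed stops: the go-RT percentile is undefined")
    rts = _go_rt_pool(session, assign_max_rt_to_omissions)
    if rts.size == 0:
        raise DataError("no usable go RTs")
    k = min(math.ceil(p * rts.size), rts.size)
    mean_ssd = float(np.mean([t.ssd for t in stops]))
    return float(rts[k - 1] - mean_ssd)
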
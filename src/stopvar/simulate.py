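"""Race-model simulation of stop-signal sessions and cohorts.

Behaviour is generated from the independent horse-race model: on every
trial a go process finishes at an ex-Gaussian latency; on stop trials a
stop process starts at the SSD and finishes after an independent
ex-Gaussian stop latency (the SSRT).  A response is emitted iff the go
process wins the race.  With probability ``p_tf`` (a trigger failure)
the stop process never launches and the trial behaves like a go trial
regardless of SSD.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ParameterError
from .exgauss import ExGaussParams, exgauss_rvs
from .task import ParticipantSession, TaskDesign, TrialRecord, as_rng, generate_trial_sequence


@dataclass(frozen=True)
class RaceModelParams:
    """Ex-Gaussian go and stop process parameters plus trigger-failure rate.

    All location/scale parameters are in milliseconds.  The mean SSRT is
    ``mu_stop + tau_stop`` and its between-trial SD ``sqrt(sigma_stop**2
    + tau_stop**2)``.
    """

    mu_go: float
    sigma_go: float
    tau_go: float
    mu_stop: float
    sigma_stop: float
    tau_stop: float
    p_tf: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sigma_go, self.tau_go, self.sigma_stop, self.tau_stop) <= 0:
            raise ParameterError("all sigma and tau parameters must be strictly positive")
        if not 0.0 <= self.p_tf <= 1.0:
            raise ParameterError(f"p_tf must lie in [0, 1], got {self.p_tf}")

    @property
    def go(self) -> ExGaussParams:
        return ExGaussParams(self.mu_go, self.sigma_go, self.tau_go)

    @property
    def stop(self) -> ExGaussParams:
        return ExGaussParams(self.mu_stop, self.sigma_stop, self.tau_stop)

    @property
    def mean_ssrt(self) -> float:
        return self.mu_stop + self.tau_stop

    @property
    def sd_ssrt(self) -> float:
        return float(np.hypot(self.sigma_stop, self.tau_stop))


def simulate_session(
    params: RaceModelParams,
    design: TaskDesign,
    group: str = "adult",
    rng_seed=None,
    subject_id: str = "sim-0",
    p_go_error: float = 0.02,
    trials: list[TrialRecord] | None = None,
) -> ParticipantSession:
    """Simulate one participant under the staircase-tracked task.

    The SSD starts at ``design.ssd_start``, increases by ``ssd_step``
    after each successful stop, decreases by ``ssd_step`` after each
    failed stop (floored at 0) and carries over across blocks.  Go
    finish times beyond ``max_rt`` are recorded as omissions.  A small
    fraction ``p_go_error`` of responses are emitted in the wrong
    direction.  Trial onsets accumulate ``max_rt`` plus the jittered
    fixation interval: because the fixation is extended by (max_rt - RT)
    after a response, every trial occupies max_rt + jitter.
    """
    rng = as_rng(rng_seed)
    if trials is None:
        trials = generate_trial_sequence(design, rng)
    else:
        trials = [replace(t) for t in trials]

    ssd = design.ssd_start
    onset = 0.0
    for trial in trials:
        trial.onset = onset
        go_finish = exgauss_rvs(params.mu_go, params.sigma_go, params.tau_go, rng=rng)
        wrong = rng.random() < p_go_error
        if trial.kind == "go":
            responded = go_finish <= design.max_rt
        else:
            trial.ssd = ssd
            if rng.random() < params.p_tf:
                # stop process never launched; behaves like a go trial
                responded = go_finish <= design.max_rt
            else:
                stop_latency = exgauss_rvs(
                    params.mu_stop, params.sigma_stop, params.tau_stop, rng=rng
                )
                responded = (go_finish < ssd + stop_latency) and (go_finish <= design.max_rt)
            if responded:
                ssd = max(ssd - design.ssd_step, 0.0)
            else:
                ssd = ssd + design.ssd_step
        if responded:
            trial.rt = float(go_finish)
            if wrong:
                trial.response = "right" if trial.direction == "left" else "left"
            else:
                trial.response = trial.direction
        else:
            trial.rt = None
            trial.response = "none"
        jitter = rng.uniform(*design.iti_jitter)
        onset += (design.max_rt + jitter) / 1000.0

    return ParticipantSession(
        subject_id=subject_id, group=group, design=design, trials=trials, truth=params
    )


# -- cohorts -----------------------------------------------------------------

_PARAM_FIELDS = [f.name for f in fields(RaceModelParams)]

# truncation bounds used when drawing per-subject true parameters
_TRUTH_BOUNDS = {
    "mu_go": (1.0, 2000.0),
    "sigma_go": (1.0, 500.0),
    "tau_go": (1.0, 500.0),
    "mu_stop": (1.0, 2000.0),
    "sigma_stop": (1.0, 500.0),
    "tau_stop": (1.0, 500.0),
    "p_tf": (0.0, 1.0),
}


@dataclass(frozen=True)
class GroupSpec:
    """Population distribution of race parameters for one group.

    Subject-level true parameters are drawn from truncated normal
    distributions with the given location and scale per parameter
    (scale 0 → every subject shares the location value).
    """

    n: int
    loc: RaceModelParams
    scale: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("each group needs n >= 1 subjects")
        bad = set(self.scale) - set(_PARAM_FIELDS)
        if bad:
            raise ConfigurationError(f"unknown scale parameters: {sorted(bad)}")
        if any(v < 0 for v in self.scale.values()):
            raise ConfigurationError("scales must be nonnegative")

    def draw_params(self, rng: np.random.Generator) -> RaceModelParams:
        values = {}
        for name in _PARAM_FIELDS:
            loc = getattr(self.loc, name)
            scale = float(self.scale.get(name, 0.0))
            lo, hi = _TRUTH_BOUNDS[name]
            if scale == 0.0:
                values[name] = loc
            else:
                a, b = (lo - loc) / scale, (hi - loc) / scale
                values[name] = float(
                    stats.truncnorm.ppf(rng.random(), a, b, loc=loc, scale=scale)
                )
        return RaceModelParams(**values)


def default_group_specs() -> dict[str, GroupSpec]:
    """Child/adult cohort defaults (n=19 children, n=26 adults).

    The two groups share the location of mu_stop but children have
    larger sigma_stop and tau_stop (wider, heavier-tailed SSRT
    distributions) and slower, more variable go processes; values are in
    the range reported by hierarchical stop-signal studies.
    """
    child_loc = RaceModelParams(
        mu_go=450.0, sigma_go=80.0, tau_go=150.0,
        mu_stop=200.0, sigma_stop=50.0, tau_stop=90.0, p_tf=0.02,
    )
    adult_loc = RaceModelParams(
        mu_go=400.0, sigma_go=60.0, tau_go=100.0,
        mu_stop=200.0, sigma_stop=20.0, tau_stop=40.0, p_tf=0.02,
    )
    child_scale = dict(
        mu_go=30.0, sigma_go=10.0, tau_go=20.0,
        mu_stop=50.0, sigma_stop=15.0, tau_stop=25.0, p_tf=0.01,
    )
    adult_scale = dict(
        mu_go=30.0, sigma_go=10.0, tau_go=20.0,
        mu_stop=50.0, sigma_stop=8.0, tau_stop=12.0, p_tf=0.01,
    )
    return {
        "child": GroupSpec(n=19, loc=child_loc, scale=child_scale),
        "adult": GroupSpec(n=26, loc=adult_loc, scale=adult_scale),
    }


def simulate_cohort(
    group_specs: Mapping[str, GroupSpec] | None = None,
    design: TaskDesign | None = None,
    rng_seed=None,
    p_go_error: float = 0.02,
) -> tuple[list[ParticipantSession], pd.DataFrame]:
    """Simulate all subjects of a multi-group cohort.

    Returns the sessions (ordered by group, then subject) and a
    ground-truth table with one row per subject holding the true race
    parameters each session was generated from.
    """
    if group_specs is None:
        group_specs = default_group_specs()
    if not group_specs:
        raise ConfigurationError("group_specs must name at least one group")
    design = design or TaskDesign()
    rng = as_rng(rng_seed)

    sessions: list[ParticipantSession] = []
    rows = []
    for group, spec in group_specs.items():
        for i in range(spec.n):
            subject_id = f"{group}-{i:03d}"
            truth = spec.draw_params(rng)
            session = simulate_session(
                truth, design, group=group, rng_seed=rng,
                subject_id=subject_id, p_go_error=p_go_error,
            )
            sessions.append(session)
            rows.append(
                {"subject_id": subject_id, "group": group}
                | {name: getattr(truth, name) for name in _PARAM_FIELDS}
            )
    return sessions, pd.DataFrame(rows)
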
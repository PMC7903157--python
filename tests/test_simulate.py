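"""Race-model session and cohort simulation."""

import numpy as np
import pytest

import stopvar as sv
from stopvar.exgauss import exgauss_rvs
from stopvar.race import successful_stop_prob
from stopvar.task import TaskDesign


def test_staircase_steps_follow_outcomes(default_session):
    stops = default_session.stop_trials
    step = default_session.design.ssd_step
    for prev, nxt in zip(stops[:-1], stops[1:]):
        if prev.is_successful_stop:
            assert nxt.ssd == prev.ssd + step
        else:
            assert nxt.ssd == max(prev.ssd - step, 0.0)
    assert stops[0].ssd == default_session.design.ssd_start


def test_trigger_failure_one_means_no_successful_stops(default_design):
    params = sv.RaceModelParams(400, 50, 100, 200, 30, 50, p_tf=1.0)
    session = sv.simulate_session(params, default_design, rng_seed=3)
    assert all(not t.is_successful_stop for t in session.stop_trials)


def test_slow_go_process_yields_omissions():
    params = sv.RaceModelParams(1450, 120, 200, 200, 30, 50, p_tf=0.0)
    session = sv.simulate_session(params, TaskDesign(), rng_seed=5)
    omissions = [t for t in session.go_trials if not t.responded]
    assert omissions, "expected go omissions with a go mean near the deadline"
    assert all(t.rt is None and t.response == "none" for t in omissions)
    responded = [t for t in session.go_trials if t.responded]
    assert all(t.rt <= session.design.max_rt for t in responded)


def test_empirical_response_rate_matches_race_probability(default_params):
    """P(respond | SSD) from the simulator vs the analytic race integral."""
    session = sv.simulate_session(default_params, TaskDesign(n_blocks=80), rng_seed=9)
    by_ssd = {}
    for t in session.stop_trials:
        by_ssd.setdefault(t.ssd, []).append(t.responded)
    for ssd, outcomes in by_ssd.items():
        n = len(outcomes)
        if n < 400:
            continue
        emp = np.mean(outcomes)
        analytic = 1.0 - successful_stop_prob(default_params, ssd)
        assert emp == pytest.approx(analytic, abs=4.0 * np.sqrt(0.25 / n))


def test_onsets_accumulate_deadline_plus_jitter(default_session):
    d = default_session.design
    diffs = np.diff([t.onset for t in default_session.trials])
    lo = (d.max_rt + d.iti_jitter[0]) / 1000.0
    hi = (d.max_rt + d.iti_jitter[1]) / 1000.0
    assert np.all(diffs >= lo - 1e-9) and np.all(diffs <= hi + 1e-9)


def test_cohort_default_sizes_and_truth_table():
    sessions, truth = sv.simulate_cohort(rng_seed=2)
    groups = [s.group for s in sessions]
    assert groups.count("child") == 19
    assert groups.count("adult") == 26
    assert len(truth) == 45
    assert set(truth["group"]) == {"child", "adult"}
    # one truth row per session, matching ids
    assert list(truth["subject_id"]) == [s.subject_id for s in sessions]


def test_children_with_doubled_stop_spread_show_wider_ssrt():
    """Doubling sigma_stop/tau_stop must widen the between-trial SSRT
    distribution (Monte-Carlo oracle on the generating ex-Gaussian)."""
    adult = sv.RaceModelParams(400, 60, 100, 200, 25, 40, p_tf=0.0)
    child = sv.RaceModelParams(400, 60, 100, 200, 50, 80, p_tf=0.0)
    specs = {
        "adult": sv.GroupSpec(n=8, loc=adult, scale={}),
        "child": sv.GroupSpec(n=8, loc=child, scale={}),
    }
    _, truth = sv.simulate_cohort(specs, TaskDesign(n_blocks=1), rng_seed=4)
    rng = np.random.default_rng(0)
    spreads = {}
    for group, params in (("adult", adult), ("child", child)):
        row = truth[truth["group"] == group].iloc[0]
        draws = exgauss_rvs(row["mu_stop"], row["sigma_stop"], row["tau_stop"],
                            size=200_000, rng=rng)
        spreads[group] = np.std(draws)
    assert spreads["child"] > 1.5 * spreads["adult"]


def test_simulation_deterministic_under_seed(default_params, default_design):
    a = sv.simulate_session(default_params, default_design, rng_seed=21)
    b = sv.simulate_session(default_params, default_design, rng_seed=21)
    assert all(
        (x.kind, x.direction, x.ssd, x.response, x.rt, x.onset)
        == (y.kind, y.direction, y.ssd, y.response, y.rt, y.onset)
        for x, y in zip(a.trials, b.trials)
    )
    ca, _ = sv.simulate_cohort(rng_seed=8)
    cb, _ = sv.simulate_cohort(rng_seed=8)
    assert all(
        x.rt == y.rt and x.ssd == y.ssd
        for sa, sb in zip(ca, cb)
        for x, y in zip(sa.trials, sb.trials)
    )


def test_empty_group_spec_rejected():
    with pytest.raises(sv.ConfigurationError):
        sv.simulate_cohort({}, rng_seed=0)
    with pytest.raises(sv.ConfigurationError):
        sv.GroupSpec(n=0, loc=sv.RaceModelParams(400, 50, 100, 200, 30, 50), scale={})
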
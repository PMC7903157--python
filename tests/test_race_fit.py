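"""Hierarchical sampler mechanics, diagnostics, summaries, predictions."""

import numpy as np
import pytest

import stopvar as sv
from stopvar.race import (
    HierarchicalPosterior,
    McmcSettings,
    PARAM_NAMES,
    fit_hierarchical,
    posterior_predictive,
    posterior_summaries,
    rhat_diagnostics,
)
from stopvar.task import TaskDesign


def test_retained_draw_count_formula():
    settings = McmcSettings()  # 3 chains, 30k samples, 10k burn-in, thin 10
    assert settings.n_retained == 2000
    assert McmcSettings(n_samples=3000, n_burn_in=1000, thinning=2).n_retained == 1000
    with pytest.raises(sv.ConfigurationError):
        McmcSettings(n_samples=1000, n_burn_in=2000)
    with pytest.raises(sv.ConfigurationError):
        McmcSettings(thinning=0)


@pytest.fixture(scope="module")
def tiny_fit():
    params = sv.RaceModelParams(400, 60, 100, 200, 30, 60, p_tf=0.0)
    spec = sv.GroupSpec(n=4, loc=params, scale=dict(mu_go=20, mu_stop=15))
    sessions, _ = sv.simulate_cohort({"adult": spec}, TaskDesign(n_blocks=1), rng_seed=3)
    settings = McmcSettings(
        n_chains=2, n_samples=400, n_burn_in=200, thinning=2,
        estimate_trigger_failure=False, rng_seed=99,
    )
    return sessions, settings, fit_hierarchical(sessions, settings)


def test_fit_shapes_and_support(tiny_fit):
    sessions, settings, post = tiny_fit
    assert post.subject_draws.shape == (2, settings.n_retained, 4, 7)
    assert post.group_loc_draws.shape == (2, settings.n_retained, 7)
    draws = post.subject_draws
    assert np.all(draws[..., 1] > 0) and np.all(draws[..., 2] > 0)  # sigma_go, tau_go
    assert np.all(draws[..., 4] > 0) and np.all(draws[..., 5] > 0)  # stop scales


def test_fit_deterministic_under_seed(tiny_fit):
    sessions, settings, post = tiny_fit
    again = fit_hierarchical(sessions, settings)
    np.testing.assert_array_equal(post.subject_draws, again.subject_draws)
    np.testing.assert_array_equal(post.group_loc_draws, again.group_loc_draws)


def test_fit_requires_two_subjects(tiny_fit):
    sessions, settings, _ = tiny_fit
    with pytest.raises(sv.ConfigurationError):
        fit_hierarchical(sessions[:1], settings)


def _fake_posterior(loc_chains, n_subj=3):
    """Posterior stub whose group-location draws are given per chain."""
    C, D = loc_chains.shape[:2]
    rng = np.random.default_rng(0)
    return HierarchicalPosterior(
        subject_ids=[f"s{i}" for i in range(n_subj)],
        param_names=PARAM_NAMES,
        subject_draws=rng.normal(200, 10, (C, D, n_subj, 7)),
        group_loc_draws=loc_chains,
        group_scale_draws=np.abs(rng.normal(20, 2, (C, D, 7))) + 1,
        acceptance={},
        settings=McmcSettings(n_samples=200, n_burn_in=100, thinning=1, rng_seed=0),
        group="g",
    )


def test_rhat_near_one_for_identical_chains():
    rng = np.random.default_rng(5)
    one = rng.normal(100, 5, (1, 400, 7))
    post = _fake_posterior(np.repeat(one, 3, axis=0))
    r = rhat_diagnostics(post)
    assert np.all(np.abs(r["rhat"] - 1.0) < 0.02)
    assert not r["flagged"].any()


def test_rhat_flags_disjoint_chains():
    rng = np.random.default_rng(6)
    chains = np.stack([rng.normal(100 + 500 * c, 1, (400, 7)) for c in range(3)])
    r = rhat_diagnostics(_fake_posterior(chains))
    assert (r.loc[r["parameter"].str.startswith("loc_"), "rhat"] > 1.1).all()


def test_rhat_matches_split_formula_oracle():
    rng = np.random.default_rng(7)
    chains = rng.normal(0, 1, (3, 400, 7)) + rng.normal(0, 0.3, (3, 1, 7))
    r = rhat_diagnostics(_fake_posterior(chains)).set_index("parameter")

    def split_rhat(x):  # classic split-R-hat
        halves = np.concatenate([x[:, : x.shape[1] // 2], x[:, x.shape[1] // 2:]])
        m, n = halves.shape
        W = halves.var(axis=1, ddof=1).mean()
        B = n * halves.mean(axis=1).var(ddof=1)
        return np.sqrt(((n - 1) / n * W + B / n) / W)

    for j, name in enumerate(PARAM_NAMES):
        assert r.loc[f"loc_{name}", "rhat"] == pytest.approx(
            split_rhat(chains[:, :, j]), rel=1e-6
        )


def test_rhat_requires_multiple_chains():
    rng = np.random.default_rng(8)
    post = _fake_posterior(rng.normal(0, 1, (1, 200, 7)))
    with pytest.raises(sv.ConfigurationError):
        rhat_diagnostics(post)


def test_posterior_summaries_match_percentile_definitions():
    rng = np.random.default_rng(9)
    loc = rng.normal(300, 10, (2, 500, 7))
    post = _fake_posterior(loc)
    subj, grp = posterior_summaries(post)
    flat = loc.reshape(-1, 7)
    row = grp[(grp["parameter"] == "loc_mu_go")].iloc[0]
    assert row["median"] == pytest.approx(np.median(flat[:, 0]))
    assert row["ci_lo"] == pytest.approx(np.percentile(flat[:, 0], 2.5))
    assert row["ci_hi"] == pytest.approx(np.percentile(flat[:, 0], 97.5))
    # subject p_tf reported on the probability scale
    assert ((subj["p_tf"] >= 0) & (subj["p_tf"] <= 1)).all()


def test_posterior_predictive_mean_and_width():
    rng = np.random.default_rng(10)
    loc = np.empty((2, 400, 7))
    loc[..., :] = [400, 60, 100, 220, 30, 60, -2.0] + rng.normal(0, 1e-3, (2, 400, 7))
    narrow = _fake_posterior(loc)
    narrow.group_scale_draws[:] = 1.0
    draws = posterior_predictive(narrow, n_predictions=400, n_per_draw=50, rng_seed=0)
    assert len(draws) == 400 * 50
    assert np.mean(draws) == pytest.approx(220 + 60, rel=0.03)

    wide_loc = loc.copy()
    wide_loc[..., 4:6] *= 2.0  # double sigma_stop and tau_stop
    wide = _fake_posterior(wide_loc)
    wide.group_scale_draws[:] = 1.0
    wider = posterior_predictive(wide, n_predictions=400, n_per_draw=50, rng_seed=0)
    iqr = lambda x: np.subtract(*np.percentile(x, [75, 25]))
    assert iqr(wider) > 1.5 * iqr(draws)


def test_default_prediction_count_from_settings():
    assert McmcSettings().n_predictions == 1000
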
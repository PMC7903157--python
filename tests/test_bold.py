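"""HRF basis, GLM designs, SSR/DoR, denoising, framewise displacement."""

import numpy as np
import pandas as pd
import pytest

import stopvar as sv
from stopvar.bold import (
    build_design,
    convolve_events,
    denoise,
    difference_of_residuals,
    dct_drift_columns,
    fit_glm_ssr,
    hrf_basis,
    mean_framewise_displacement,
)
from stopvar.boldsim import (
    GO_SUCCESS,
    STOP_SUCCESS,
    BoldSimSpec,
    default_atlas,
    simulate_bold_run,
)


# --- HRF -------------------------------------------------------------------


def test_hrf_zero_at_onset_and_peak_location():
    basis = hrf_basis(tr=2.2)
    assert basis.canonical[0] == pytest.approx(0.0, abs=1e-12)
    peak_t = np.argmax(basis.canonical) * basis.dt
    assert 4.0 <= peak_t <= 7.0
    assert basis.canonical.max() == pytest.approx(1.0)


def test_temporal_derivative_is_backward_difference():
    basis = hrf_basis(tr=2.0, deriv_delta=1.0)
    t = np.arange(len(basis.canonical)) * basis.dt
    # reconstruct independently from the double-gamma definition
    from scipy import stats as sps

    def h(tt):
        tt = np.asarray(tt, dtype=float)
        out = sps.gamma.pdf(tt, 6.0, scale=1.0) - sps.gamma.pdf(tt, 16.0, scale=1.0) / 6.0
        return np.where(tt < 0, 0.0, out)

    scale = h(t).max()
    expected = (h(t) - h(t - 1.0)) / scale
    assert np.allclose(basis.temporal_deriv, expected, atol=1e-10)


def test_hrf_invalid_shapes_raise():
    with pytest.raises(sv.ParameterError):
        hrf_basis(tr=-1.0)
    with pytest.raises(sv.ParameterError):
        hrf_basis(tr=2.2, peak_delay=0.0)


# --- designs ---------------------------------------------------------------


def _toy_events():
    rows = []
    for k, cond in enumerate(
        ["go-success"] * 6 + ["stop-success"] * 4 + ["stop-fail"] * 3 + ["error"] * 2
    ):
        rows.append({"onset": 8.0 * k + 2.0, "duration": 0.0, "trial_type": cond})
    return pd.DataFrame(rows)


def test_standard_design_task_column_count():
    events = _toy_events()
    design = build_design(
        events, "standard", STOP_SUCCESS, n_volumes=80, tr=2.2, hp_cutoff=None
    )
    task = [n for n in design.names if n != "intercept"]
    # 3 conditions x (canonical + 2 derivatives) + 1 error regressor
    assert len(task) == 10


def test_trialwise_design_adds_k_minus_one_columns():
    events = _toy_events()
    std = build_design(events, "standard", STOP_SUCCESS, 80, 2.2)
    tw = build_design(events, "trialwise", STOP_SUCCESS, 80, 2.2)
    k = (events["trial_type"] == STOP_SUCCESS).sum()
    assert tw.matrix.shape[1] == std.matrix.shape[1] + k - 1
    assert len(tw.coi_columns) == k


def test_trialwise_regressors_sum_to_condition_regressor():
    events = _toy_events()
    std = build_design(events, "standard", STOP_SUCCESS, 80, 2.2, hp_cutoff=None)
    tw = build_design(events, "trialwise", STOP_SUCCESS, 80, 2.2, hp_cutoff=None)
    summed = tw.matrix[:, tw.coi_columns].sum(axis=1)
    std_col = std.matrix[:, std.coi_columns[0]]
    assert np.allclose(summed, std_col, atol=1e-12)


def test_events_beyond_run_rejected():
    events = pd.DataFrame(
        [{"onset": 500.0, "duration": 0.0, "trial_type": STOP_SUCCESS}]
    )
    with pytest.raises(sv.DataError):
        build_design(events, "standard", STOP_SUCCESS, n_volumes=100, tr=2.0)


# --- GLM / DoR -------------------------------------------------------------


def test_ssr_zero_for_signal_in_column_space():
    events = _toy_events()
    design = build_design(events, "standard", STOP_SUCCESS, 80, 2.2)
    rng = np.random.default_rng(0)
    Y = (design.matrix @ rng.normal(size=(design.matrix.shape[1], 5))).T
    ssr = fit_glm_ssr(Y, design)
    assert np.all(ssr.values < 1e-16 * max(1.0, np.abs(Y).max()) ** 2 + 1e-12)


def test_ols_matches_normal_equations_oracle():
    events = _toy_events()
    design = build_design(events, "standard", STOP_SUCCESS, 80, 2.2)
    X = design.matrix
    rng = np.random.default_rng(1)
    Y = rng.normal(size=(5, 80))
    ssr = fit_glm_ssr(Y, design).values
    beta = np.linalg.solve(X.T @ X, X.T @ Y.T)
    expected = np.sum((Y.T - X @ beta) ** 2, axis=0)
    assert np.allclose(ssr, expected, atol=1e-8)


def test_adding_columns_never_increases_ssr():
    events = _toy_events()
    std = build_design(events, "standard", STOP_SUCCESS, 80, 2.2)
    tw = build_design(events, "trialwise", STOP_SUCCESS, 80, 2.2)
    rng = np.random.default_rng(2)
    Y = rng.normal(size=(50, 80))
    s1 = fit_glm_ssr(Y, std).values
    s2 = fit_glm_ssr(Y, tw).values
    assert np.all(s2 <= s1 + 1e-8)


def test_dor_requires_matching_modes():
    events = _toy_events()
    std = build_design(events, "standard", STOP_SUCCESS, 80, 2.2)
    rng = np.random.default_rng(3)
    Y = rng.normal(size=(4, 80))
    ssr = fit_glm_ssr(Y, std)
    with pytest.raises(sv.DataError):
        difference_of_residuals(ssr, ssr)


@pytest.fixture(scope="module")
def noiseless_runs():
    """Three deterministic-noise-free runs differing only in stop-locked
    amplitude SD (0, 0.4, 0.8)."""
    sessions, _ = sv.simulate_cohort(rng_seed=5)
    events = sv.events_from_session(sessions[0], block=0)
    runs = {}
    for sd in (0.0, 0.4, 0.8):
        spec = BoldSimSpec(
            noise_sd=0.0, drift_amplitude=0.0,
            trial_amplitude_sd={r: {STOP_SUCCESS: sd} for r in sv.INHIBITION_NETWORK},
        )
        run, amps = simulate_bold_run(events, spec, rng_seed=11)
        runs[sd] = (run, amps)
    return runs


def _dor_for_run(run):
    common = dict(
        events=run.events, condition_of_interest=STOP_SUCCESS,
        n_volumes=run.n_volumes, tr=run.tr,
        conditions=[GO_SUCCESS, STOP_SUCCESS],
    )
    ssr_std = fit_glm_ssr(run, build_design(mode="standard", **common))
    ssr_tw = fit_glm_ssr(run, build_design(mode="trialwise", **common))
    return difference_of_residuals(ssr_std, ssr_tw)


def test_dor_zero_without_trial_variability(noiseless_runs):
    run, _ = noiseless_runs[0.0]
    dor = _dor_for_run(run)
    assert np.allclose(dor.values, 0.0, atol=1e-10)


def test_dor_nonnegative_and_monotone_in_amplitude_sd(noiseless_runs):
    atlas = default_atlas()
    means = {}
    for sd, (run, _) in noiseless_runs.items():
        dor = _dor_for_run(run)
        assert np.all(dor.values >= 0.0)
        network = np.zeros(atlas.n_voxels, dtype=bool)
        for name in sv.INHIBITION_NETWORK:
            network |= atlas.masks[name]
        means[sd] = dor.values[network].mean()
    assert means[0.0] < means[0.4] < means[0.8]


def test_volume_count_is_floor_of_duration_over_tr():
    events = pd.DataFrame([{"onset": 10.0, "duration": 0.0, "trial_type": GO_SUCCESS}])
    spec = BoldSimSpec(run_duration=299.2, tr=2.2, noise_sd=0.0, drift_amplitude=0.0)
    run, _ = simulate_bold_run(events, spec, rng_seed=0)
    assert run.n_volumes == 136


def test_noise_free_run_equals_convolved_model():
    events = pd.DataFrame(
        [{"onset": 5.0 + 12.0 * k, "duration": 0.0, "trial_type": GO_SUCCESS}
         for k in range(5)]
    )
    spec = BoldSimSpec(run_duration=120.0, noise_sd=0.0, drift_amplitude=0.0)
    run, _ = simulate_bold_run(events, spec, rng_seed=0)
    basis = hrf_basis(spec.tr)
    expected = spec.baseline + convolve_events(
        events["onset"].to_numpy(), events["duration"].to_numpy(),
        np.ones(5), run.n_volumes, spec.tr, basis.canonical, basis.dt,
    )
    assert np.allclose(run.data, expected[None, :], atol=1e-10)


# --- denoising / motion ----------------------------------------------------


def test_denoise_residuals_orthogonal_to_confounds():
    rng = np.random.default_rng(4)
    Y = rng.normal(size=(6, 100))
    confounds = rng.normal(size=(100, 3))
    resid = denoise(Y, confounds)
    assert np.allclose(resid @ confounds, 0.0, atol=1e-8)
    assert np.allclose(resid.sum(axis=1), 0.0, atol=1e-8)


def test_denoise_without_confounds_removes_voxel_mean():
    rng = np.random.default_rng(5)
    Y = rng.normal(loc=7.0, size=(3, 40))
    resid = denoise(Y)
    assert np.allclose(resid, Y - Y.mean(axis=1, keepdims=True), atol=1e-10)


def test_denoise_matches_brute_force_ols():
    rng = np.random.default_rng(6)
    Y = rng.normal(size=(2, 30))
    confounds = rng.normal(size=(30, 2))
    flags = np.zeros(30, dtype=bool)
    flags[[4, 17]] = True
    resid = denoise(Y, confounds, flags)
    X = np.column_stack([np.ones(30), confounds,
                         np.eye(30)[:, 4], np.eye(30)[:, 17]])
    expected = (Y.T - X @ np.linalg.lstsq(X, Y.T, rcond=None)[0]).T
    assert np.allclose(resid, expected, atol=1e-10)
    assert np.allclose(resid[:, [4, 17]], 0.0, atol=1e-8)


def test_denoise_rejects_fully_flagged_run():
    with pytest.raises(sv.DataError):
        denoise(np.ones((2, 10)), outlier_flags=np.ones(10, dtype=bool))


def test_framewise_displacement_cases():
    assert mean_framewise_displacement(np.zeros((10, 6))) == 0.0
    motion = np.zeros((8, 6))
    motion[4:, 0] = 0.1  # one 0.1-mm x step
    assert mean_framewise_displacement(motion) == pytest.approx(0.1 / 7)
    # hand-computed 5-volume series with rotations (50-mm sphere)
    m = np.zeros((5, 6))
    m[1] = [0.1, 0.0, 0.0, 0.002, 0.0, 0.0]
    m[2] = [0.1, -0.2, 0.0, 0.002, 0.0, -0.001]
    # frame diffs: 1->2: 0.1+50*0.002; 2->3: 0.2+50*0.001;
    # 3->4 (back to zero): 0.1+0.2+50*(0.002+0.001); 4->5: 0
    fd = (0.1 + 0.1) + (0.2 + 0.05) + (0.3 + 0.15) + 0.0
    assert mean_framewise_displacement(m) == pytest.approx(fd / 4)
    with pytest.raises(sv.DataError):
        mean_framewise_displacement(np.zeros((5, 4)))


def test_drift_columns_span_slow_frequencies():
    drift = dct_drift_columns(100, 2.2, cutoff=128.0)
    assert drift.shape[0] == 100 and drift.shape[1] >= 1
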
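"""ROI extraction, ANOVA, cluster maps, correlations, power."""

import numpy as np
import pytest
from scipy import stats as sps

import stopvar as sv
from stopvar.stats import (
    correlations,
    extract_roi_values,
    fisher_z_compare,
    one_way_anova,
    power_sample_size,
    voxelwise_group_map,
)


# --- ROI means -------------------------------------------------------------


def test_roi_means_constant_and_toy():
    masks = {"a": np.array([1, 1, 1, 0, 0], bool), "b": np.array([0, 0, 0, 1, 1], bool)}
    const = extract_roi_values(np.full(5, 3.5), masks)
    assert const == {"a": 3.5, "b": 3.5}
    toy = extract_roi_values(np.array([1.0, 2.0, 3.0, 10.0, 20.0]), masks)
    assert toy["a"] == pytest.approx(2.0)


def test_network_mean_pools_equal_sized_rois():
    masks = {"a": np.array([1, 1, 0, 0], bool), "b": np.array([0, 0, 1, 1], bool)}
    vals = extract_roi_values(np.array([1.0, 3.0, 5.0, 7.0]), masks, network=("a", "b"))
    assert vals["network"] == pytest.approx((vals["a"] + vals["b"]) / 2)


def test_empty_mask_rejected():
    with pytest.raises(sv.DataError):
        extract_roi_values(np.ones(4), {"a": np.zeros(4, bool)})


# --- ANOVA -----------------------------------------------------------------


def test_anova_zero_f_for_identical_means():
    res = one_way_anova({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    assert res.F == pytest.approx(0.0)
    assert res.eta_squared == pytest.approx(0.0)


def test_anova_two_groups_equals_squared_t():
    rng = np.random.default_rng(0)
    a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
    res = one_way_anova({"a": a, "b": b})
    t, p = sps.ttest_ind(a, b)
    assert res.F == pytest.approx(t**2, rel=1e-10)
    assert res.p == pytest.approx(p, rel=1e-10)
    assert (res.df_between, res.df_within) == (1, 25)


def test_anova_hand_computed_eta_squared():
    res = one_way_anova({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
    assert res.eta_squared == pytest.approx(13.5 / 17.5)
    assert res.F == pytest.approx(13.5)


def test_anova_cross_checked_against_pingouin():
    import pandas as pd
    import pingouin as pg

    rng = np.random.default_rng(1)
    groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(0.5, 1.2, 14),
              "c": rng.normal(1.0, 0.8, 9)}
    res = one_way_anova(groups)
    df = pd.DataFrame(
        [{"g": g, "y": v} for g, vals in groups.items() for v in vals]
    )
    ref = pg.anova(data=df, dv="y", between="g", detailed=True)
    assert res.F == pytest.approx(float(ref["F"][0]), rel=1e-9)
    assert res.eta_squared == pytest.approx(float(ref["np2"][0]), rel=1e-9)


def test_anova_degenerate_inputs():
    with pytest.raises(sv.DataError):
        one_way_anova({"a": [1.0, 2.0]})
    with pytest.raises(sv.DataError):
        one_way_anova({"a": [], "b": [1.0]})


# --- voxel-wise map --------------------------------------------------------


def test_identical_groups_give_empty_cluster_table():
    rng = np.random.default_rng(2)
    a = rng.normal(size=(8, 1000))
    t_map, table = voxelwise_group_map({"x": a, "y": a.copy()}, (10, 10, 10))
    assert len(table) == 0
    assert np.nansum(np.abs(t_map)) == 0.0


def test_planted_cluster_recovered():
    shape = (10, 10, 10)
    atlas = sv.default_atlas(shape)
    mask = atlas.masks["r_thalamus"]
    rng = np.random.default_rng(3)
    a = rng.normal(0, 0.1, (10, 1000))
    b = rng.normal(0, 0.1, (12, 1000))
    b[:, mask] += 5.0  # strong group difference in a 27-voxel cube
    t_map, table = voxelwise_group_map({"child": a, "adult": b}, shape,
                                       min_cluster_voxels=10)
    assert len(table) == 1
    row = table.iloc[0]
    assert row["size"] == 27
    assert row["direction"] == "adult>child"
    flat_peak = np.ravel_multi_index(row["peak_ijk"], shape)
    assert mask[flat_peak]


def test_small_clusters_filtered_by_extent():
    shape = (10, 10, 10)
    rng = np.random.default_rng(4)
    a = rng.normal(0, 0.1, (10, 1000))
    b = rng.normal(0, 0.1, (10, 1000))
    b[:, :5] += 5.0  # a 5-voxel line: below the 10-voxel extent threshold
    _, table = voxelwise_group_map({"x": a, "y": b}, shape, min_cluster_voxels=10)
    assert len(table) == 0


# --- correlations ----------------------------------------------------------


def test_perfect_linear_correlation():
    x = np.arange(10.0)
    res = correlations(x, 3.0 * x + 1.0)
    assert res.r == pytest.approx(1.0)


def test_four_point_hand_computed_r():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([2.0, 1.0, 4.0, 3.0])
    # hand computation: cov = 1.0 (ddof=1); sx = sy = 1.29099...
    res = correlations(x, y)
    assert res.r == pytest.approx(0.6, abs=1e-12)
    assert res.n == 4


def test_partial_correlation_with_irrelevant_covariate_matches_raw():
    rng = np.random.default_rng(5)
    n = 2000
    x = rng.normal(size=n)
    y = 0.5 * x + rng.normal(size=n)
    z = rng.normal(size=n)  # independent of both
    raw = correlations(x, y)
    part = correlations(x, y, covariates=z[:, None])
    assert part.r == pytest.approx(raw.r, abs=0.02)


def test_partial_correlation_cross_checked_against_pingouin():
    import pandas as pd
    import pingouin as pg

    rng = np.random.default_rng(6)
    n = 60
    z = rng.normal(size=n)
    x = 0.7 * z + rng.normal(size=n)
    y = -0.5 * z + rng.normal(size=n)
    res = correlations(x, y, covariates=z[:, None])
    ref = pg.partial_corr(
        data=pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
    )
    assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
    assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)


def test_zero_variance_correlation_rejected():
    with pytest.raises(sv.DataError):
        correlations(np.ones(5), np.arange(5.0))


# --- Fisher z --------------------------------------------------------------


def test_fisher_z_zero_for_equal_correlations():
    z, p = fisher_z_compare(0.4, 30, 0.4, 25)
    assert z == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_fisher_z_formula_oracle_and_antisymmetry():
    z, p = fisher_z_compare(0.5, 30, 0.0, 30)
    expected = (np.arctanh(0.5) - 0.0) / np.sqrt(1 / 27 + 1 / 27)
    assert z == pytest.approx(expected, rel=1e-12)
    assert p == pytest.approx(2 * sps.norm.sf(abs(expected)), rel=1e-12)
    z2, _ = fisher_z_compare(0.0, 30, 0.5, 30)
    assert z2 == pytest.approx(-z)


def test_fisher_z_domain_errors():
    with pytest.raises(sv.DataError):
        fisher_z_compare(1.0, 30, 0.5, 30)
    with pytest.raises(sv.DataError):
        fisher_z_compare(0.2, 3, 0.5, 30)


# --- power -----------------------------------------------------------------


def test_power_very_large_effect_floors_at_two():
    n, total = power_sample_size(10.0, 0.05, 0.80)
    assert (n, total) == (2, 4)


def test_power_invalid_inputs():
    with pytest.raises(sv.ConfigurationError):
        power_sample_size(-1.0)
    with pytest.raises(sv.ConfigurationError):
        power_sample_size(0.5, alpha=1.5)


@pytest.mark.parametrize("d", [0.5, 0.8, 1.2])
def test_power_matches_monte_carlo_oracle(d):
    """Smallest-n search agrees with simulated two-sample t power to
    within one subject per group."""
    n_analytic, _ = power_sample_size(d, 0.05, 0.80)
    rng = np.random.default_rng(1234)

    def mc_power(n, reps=6000):
        a = rng.normal(0.0, 1.0, (reps, n))
        b = rng.normal(d, 1.0, (reps, n))
        t, p = sps.ttest_ind(a, b, axis=1)
        return np.mean(p < 0.05)

    n_mc = 2
    while mc_power(n_mc) < 0.80 and n_mc < 200:
        n_mc += 1
    assert abs(n_mc - n_analytic) <= 1
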
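"""End-to-end pipeline: simulate -> behavior -> race fit -> DoR -> statistics.

A single :class:`PipelineConfig` (YAML-serialisable) drives every
stage; the master seed deterministically derives per-stage sub-seeds,
so identical configs and seeds produce identical artifacts.  Each stage
is an importable function; :func:`run_pipeline` orchestrates them,
persists every intermediate table/map and writes a markdown report with
behavioral, BOLD-variability and correlation sections.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import io as svio
from .behavior import qc_filter, summarize_stopping
from .bold import (
    build_design,
    difference_of_residuals,
    fit_glm_ssr,
    mean_framewise_displacement,
)
from .boldsim import (
    CONTROL_REGION,
    GO_SUCCESS,
    INHIBITION_NETWORK,
    STOP_SUCCESS,
    BoldSimSpec,
    default_atlas,
    events_from_session,
    simulate_bold_run,
)
from .exceptions import ConfigurationError, StopvarError
from .race import (
    HierarchicalPosterior,
    McmcSettings,
    fit_groups,
    posterior_summaries,
    rhat_diagnostics,
)
from .simulate import GroupSpec, RaceModelParams, default_group_specs, simulate_cohort
from .stats import (
    correlations,
    extract_roi_values,
    fisher_z_compare,
    one_way_anova,
    power_sample_size,
    voxelwise_group_map,
)
from .task import TaskDesign

log = logging.getLogger("stopvar")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one full analysis run needs."""

    design: TaskDesign = field(default_factory=TaskDesign)
    groups: Mapping[str, GroupSpec] = field(default_factory=default_group_specs)
    bold: BoldSimSpec = field(default_factory=BoldSimSpec)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    qc_min_stop_success: float = 30.0
    alpha: float = 0.05
    cluster_extent: int = 10
    p_go_error: float = 0.02
    # group-level base SD of the stop-locked trial amplitude in the
    # inhibition network (a.u.); adults more variable than children
    stop_amplitude_sd_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"child": 0.3, "adult": 0.8}
    )
    go_amplitude_sd: float = 0.2
    couple_bold_to_behavior: bool = True
    seed: int = 0

    def stage_seed(self, offset: int) -> int:
        state = np.random.SeedSequence([self.seed, offset]).generate_state(1)[0]
        return int(state % (2**31 - 1))


# ---------------------------------------------------------------------------
# YAML round trip
# ---------------------------------------------------------------------------


def config_to_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["design"]["gap_pattern"] = list(config.design.gap_pattern)
    d["design"]["iti_jitter"] = list(config.design.iti_jitter)
    d["bold"]["shape"] = list(config.bold.shape)
    d["groups"] = {
        g: {"n": s.n, "loc": dataclasses.asdict(s.loc), "scale": dict(s.scale)}
        for g, s in config.groups.items()
    }
    d["stop_amplitude_sd_by_group"] = dict(config.stop_amplitude_sd_by_group)
    d["bold"]["amplitude_mean"] = dict(config.bold.amplitude_mean)
    d["bold"]["trial_amplitude_sd"] = {
        k: dict(v) for k, v in config.bold.trial_amplitude_sd.items()
    }
    return d


def config_from_dict(d: dict) -> PipelineConfig:
    design = TaskDesign(
        **{
            **d.get("design", {}),
            "gap_pattern": tuple(d.get("design", {}).get("gap_pattern", (1, 2, 4, 5))),
            "iti_jitter": tuple(d.get("design", {}).get("iti_jitter", (2000.0, 4000.0))),
        }
    )
    groups = {
        g: GroupSpec(n=s["n"], loc=RaceModelParams(**s["loc"]), scale=dict(s["scale"]))
        for g, s in d.get("groups", {}).items()
    } or default_group_specs()
    bold_d = dict(d.get("bold", {}))
    if "shape" in bold_d:
        bold_d["shape"] = tuple(bold_d["shape"])
    bold = BoldSimSpec(**bold_d)
    mcmc = McmcSettings(**d.get("mcmc", {}))
    extra = {
        k: d[k]
        for k in (
            "qc_min_stop_success", "alpha", "cluster_extent", "p_go_error",
            "stop_amplitude_sd_by_group", "go_amplitude_sd",
            "couple_bold_to_behavior", "seed",
        )
        if k in d
    }
    return PipelineConfig(design=design, groups=groups, bold=bold, mcmc=mcmc, **extra)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path) -> PipelineConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig):
    """Simulate the cohort's behavioral sessions."""
    sessions, truth = simulate_cohort(
        config.groups, config.design, rng_seed=config.stage_seed(1),
        p_go_error=config.p_go_error,
    )
    return sessions, truth


def stage_behavior(config: PipelineConfig, sessions):
    """QC filtering and horse-race summaries per subject."""
    rows, retained = [], []
    for s in sessions:
        keep = qc_filter(s, config.qc_min_stop_success)
        summary = summarize_stopping(s)
        rows.append(dataclasses.asdict(summary) | {"retained": keep})
        if keep:
            retained.append(s)
    return pd.DataFrame(rows), retained


def stage_fit_race(config: PipelineConfig, sessions):
    """Hierarchical Bayesian fit per group; subject and group summaries."""
    settings = replace(config.mcmc, rng_seed=config.stage_seed(2))
    posteriors = fit_groups(sessions, settings)
    subject_frames, group_frames, rhat_frames = [], [], []
    for group, post in posteriors.items():
        subj, grp = posterior_summaries(post)
        subject_frames.append(subj)
        group_frames.append(grp)
        if post.n_chains >= 2:
            r = rhat_diagnostics(post)
            r.insert(0, "group", group)
            rhat_frames.append(r)
    estimates = pd.concat(subject_frames, ignore_index=True)
    group_summary = pd.concat(group_frames, ignore_index=True)
    rhat = pd.concat(rhat_frames, ignore_index=True) if rhat_frames else pd.DataFrame()
    return posteriors, estimates, group_summary, rhat


def _subject_bold_spec(config: PipelineConfig, session) -> BoldSimSpec:
    """Region/condition amplitude SDs for one subject.

    Inhibition-network regions carry the group's stop-locked amplitude
    SD; when coupling is on it is scaled by (group-typical SSRT SD /
    subject's true SSRT SD), so behaviorally consistent stoppers have
    more variable stop-locked BOLD amplitudes.  The calcarine control
    region has go-locked variability only.
    """
    base = config.stop_amplitude_sd_by_group.get(session.group, 0.5)
    if config.couple_bold_to_behavior and session.truth is not None:
        ref = config.groups[session.group].loc.sd_ssrt
        base = base * ref / session.truth.sd_ssrt
    sd_map: dict[str, dict[str, float]] = {}
    for region in INHIBITION_NETWORK:
        sd_map[region] = {STOP_SUCCESS: base, GO_SUCCESS: config.go_amplitude_sd}
    sd_map[CONTROL_REGION] = {GO_SUCCESS: config.go_amplitude_sd}
    return replace(config.bold, trial_amplitude_sd=sd_map)


def stage_bold(config: PipelineConfig, sessions):
    """Simulate each subject's runs and compute DoR for successful stops.

    One run per task block.  Per run: standard and trialwise GLMs
    (motion as nuisance, DCT high-pass), raw SSRs, DoR; runs are summed
    per subject.  Returns the ROI/network table, the per-subject DoR
    matrix (subjects x voxels), and the atlas.
    """
    atlas = default_atlas(config.bold.shape)
    seq = np.random.SeedSequence([config.stage_seed(3)])
    subject_seeds = seq.spawn(len(sessions))
    roi_rows, dor_values = [], []
    for session, sseed in zip(sessions, subject_seeds):
        rng = np.random.default_rng(sseed)
        spec = _subject_bold_spec(config, session)
        dor_total = np.zeros(atlas.n_voxels)
        fds = []
        for block in range(config.design.n_blocks):
            events = events_from_session(session, block)
            run, _ = simulate_bold_run(events, spec, rng_seed=rng, atlas=atlas)
            present = set(run.events["trial_type"])
            conds = [c for c in (GO_SUCCESS, STOP_SUCCESS) if c in present]
            if STOP_SUCCESS not in conds:
                continue
            common = dict(
                events=run.events,
                condition_of_interest=STOP_SUCCESS,
                n_volumes=run.n_volumes,
                tr=run.tr,
                nuisance=run.motion,
                conditions=conds,
            )
            ssr_std = fit_glm_ssr(run, build_design(mode="standard", **common))
            ssr_tw = fit_glm_ssr(run, build_design(mode="trialwise", **common))
            dor_total += difference_of_residuals(ssr_std, ssr_tw).values
            fds.append(mean_framewise_displacement(run.motion))
        values = extract_roi_values(dor_total, atlas.masks, network=INHIBITION_NETWORK)
        roi_rows.append(
            {"subject_id": session.subject_id, "group": session.group}
            | values
            | {"mean_fd": float(np.mean(fds)) if fds else np.nan}
        )
        dor_values.append(dor_total)
    return pd.DataFrame(roi_rows), np.asarray(dor_values), atlas


def stage_group_stats(
    config: PipelineConfig,
    behavior: pd.DataFrame,
    estimates: pd.DataFrame,
    roi: pd.DataFrame,
    dor_matrix: np.ndarray,
    atlas,
):
    """ANOVAs, voxel-wise group map, correlations, Fisher-z, power."""
    if "retained" in behavior.columns:
        behavior = behavior[behavior["retained"]]
    groups = sorted(roi["group"].unique())

    def _by_group(df: pd.DataFrame, col: str) -> dict[str, np.ndarray]:
        return {g: df.loc[df["group"] == g, col].to_numpy(float) for g in groups}

    anova_rows = []
    behavioral_measures = [
        ("ssrt_integration", behavior), ("pct_stop_success", behavior),
        ("mu_stop", estimates), ("sigma_stop", estimates), ("tau_stop", estimates),
    ]
    for measure, table in behavioral_measures:
        res = one_way_anova(_by_group(table.dropna(subset=[measure]), measure))
        anova_rows.append({"measure": measure, "domain": "behavior"} | dataclasses.asdict(res))
    for roi_name in list(INHIBITION_NETWORK) + [CONTROL_REGION, "network"]:
        res = one_way_anova(_by_group(roi, roi_name))
        anova_rows.append({"measure": f"dor_{roi_name}", "domain": "bold"} | dataclasses.asdict(res))
    anova = pd.DataFrame(anova_rows)

    # voxel-wise two-sample map with cluster-extent filter
    maps_by_group = {
        g: dor_matrix[(roi["group"] == g).to_numpy()] for g in groups
    }
    t_map, clusters = voxelwise_group_map(
        maps_by_group, atlas.shape, alpha=config.alpha,
        min_cluster_voxels=config.cluster_extent,
    )

    # correlations per group: network / control DoR vs stop parameters,
    # plus partial correlations controlling the go parameters
    merged = roi.merge(estimates, on=["subject_id", "group"])
    corr_rows = []
    go_cols = ["mu_go", "sigma_go", "tau_go"]
    def _try_corr(g, region, measure, kind, x, y, covariates=None):
        try:
            res = correlations(x, y, covariates=covariates,
                               covariate_names=tuple(go_cols) if covariates is not None else ())
        except StopvarError:
            return  # undefined at this sample size; skipped, not silently faked
        corr_rows.append({"group": g, "region": region, "measure": measure,
                          "kind": kind, "r": res.r, "n": res.n, "p": res.p})

    for g in groups:
        sub = merged[merged["group"] == g]
        for region in ("network", CONTROL_REGION):
            for param in ("tau_stop", "sigma_stop", "mu_stop"):
                x, y = sub[param].to_numpy(float), sub[region].to_numpy(float)
                _try_corr(g, region, param, "pearson", x, y)
                _try_corr(g, region, param, "partial(go)", x, y,
                          covariates=sub[go_cols].to_numpy(float))
        _try_corr(g, "network", "mean_fd", "pearson",
                  sub["mean_fd"].to_numpy(float), sub["network"].to_numpy(float))
    fd_all = correlations(merged["mean_fd"].to_numpy(float), merged["network"].to_numpy(float))
    corr_rows.append(
        {"group": "all", "region": "network", "measure": "mean_fd",
         "kind": "pearson", "r": fd_all.r, "n": fd_all.n, "p": fd_all.p}
    )
    corr = pd.DataFrame(corr_rows)

    # Fisher r-to-z group comparison of the main stop-parameter correlations
    z_rows = []
    if len(groups) == 2:
        g1, g2 = groups
        for param in ("tau_stop", "sigma_stop", "mu_stop"):
            sel = corr[(corr["kind"] == "pearson") & (corr["region"] == "network")
                       & (corr["measure"] == param)]
            if set(sel["group"]) != {g1, g2}:
                continue
            r1 = float(sel.loc[sel["group"] == g1, "r"].iloc[0])
            n1 = int(sel.loc[sel["group"] == g1, "n"].iloc[0])
            r2 = float(sel.loc[sel["group"] == g2, "r"].iloc[0])
            n2 = int(sel.loc[sel["group"] == g2, "n"].iloc[0])
            z, p = fisher_z_compare(r1, n1, r2, n2)
            z_rows.append({"measure": param, "z": z, "p": p,
                           "r_" + g1: r1, "r_" + g2: r2})
    fisher = pd.DataFrame(z_rows)

    # motion check: two-sample t on mean framewise displacement
    fd_by_group = _by_group(roi, "mean_fd")
    if len(groups) == 2:
        tt = sps.ttest_ind(*fd_by_group.values())
        motion = pd.DataFrame(
            [{"t": float(tt.statistic), "p": float(tt.pvalue)}
             | {f"mean_fd_{g}": float(np.mean(v)) for g, v in fd_by_group.items()}]
        )
    else:
        motion = pd.DataFrame()

    n_per, n_total = power_sample_size(1.2, config.alpha, 0.80)
    power = pd.DataFrame(
        [{"effect_size_d": 1.2, "alpha": config.alpha, "power": 0.80,
          "n_per_group": n_per, "n_total": n_total}]
    )
    return {
        "anova": anova, "t_map": t_map, "clusters": clusters,
        "correlations": corr, "fisher_z": fisher, "motion": motion, "power": power,
    }


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _write_report(out: Path, results: dict, behavior: pd.DataFrame, rhat: pd.DataFrame) -> None:
    anova = results["anova"]
    corr = results["correlations"]

    def fmt_anova(measure: str) -> str:
        row = anova[anova["measure"] == measure].iloc[0]
        return (
            f"F({row['df_between']}, {row['df_within']}) = {row['F']:.3f}, "
            f"p = {row['p']:.4f}, eta2 = {row['eta_squared']:.3f}"
        )

    lines = ["# Stop-signal variability report", ""]
    lines += ["## Behavior", ""]
    for g, sub in behavior.groupby("group"):
        lines.append(
            f"- {g}: n = {len(sub)}, stop success = {sub['pct_stop_success'].mean():.1f}%, "
            f"integration SSRT = {sub['ssrt_integration'].mean():.1f} ms"
        )
    for m in ("ssrt_integration", "pct_stop_success", "mu_stop", "sigma_stop", "tau_stop"):
        lines.append(f"- ANOVA {m}: {fmt_anova(m)}")
    if len(rhat):
        worst = rhat.loc[rhat["rhat"].idxmax()]
        lines.append(f"- MCMC convergence: max group-level R-hat = {worst['rhat']:.3f} "
                     f"({worst['parameter']}, {worst['group']})")
    lines += ["", "## BOLD variability", ""]
    for name in list(INHIBITION_NETWORK) + [CONTROL_REGION, "network"]:
        lines.append(f"- ANOVA DoR {name}: {fmt_anova(f'dor_{name}')}")
    clusters = results["clusters"]
    lines.append(f"- whole-grid two-sample map: {len(clusters)} suprathreshold cluster(s)")
    for _, c in clusters.iterrows():
        lines.append(f"  - {c['direction']}: {c['size']} voxels, peak t = {c['peak_t']:.2f} "
                     f"at {c['peak_ijk']}")
    if len(results["motion"]):
        m = results["motion"].iloc[0]
        lines.append(f"- mean FD group difference: t = {m['t']:.2f}, p = {m['p']:.3f}")
    lines += ["", "## Correlations between neural and behavioral variability", ""]
    for _, row in corr[corr["kind"] == "pearson"].iterrows():
        lines.append(
            f"- {row['group']}: {row['region']} DoR vs {row['measure']}: "
            f"r = {row['r']:.3f}, p = {row['p']:.4f} (n = {row['n']})"
        )
    for _, row in results["fisher_z"].iterrows():
        lines.append(f"- Fisher z ({row['measure']}): z = {row['z']:.2f}, p = {row['p']:.3f}")
    p = results["power"].iloc[0]
    lines.append(
        f"- power: d = {p['effect_size_d']}, alpha = {p['alpha']}, power = {p['power']} "
        f"-> n = {int(p['n_per_group'])}/group ({int(p['n_total'])} total)"
    )
    (out / "report.md").write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage, persisting all intermediates under ``out_dir``."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        save_config(config, out / "config.yaml")
    except OSError as e:
        raise StopvarError(f"[stage: setup] cannot write to {out}: {e}") from e

    def _stage(name, fn, *args):
        log.info("stage %s ...", name)
        try:
            return fn(config, *args)
        except StopvarError:
            raise
        except Exception as e:  # stage-tagged failure, partial outputs retained
            raise StopvarError(f"[stage: {name}] {e}") from e

    sessions, truth = _stage("simulate", stage_simulate)
    svio.write_sessions_tsv(sessions, out / "sessions.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    behavior, retained = _stage("behavior", stage_behavior, sessions)
    behavior.to_csv(out / "behavior_summaries.tsv", sep="\t", index=False)

    posteriors, estimates, group_summary, rhat = _stage("fit-race", stage_fit_race, retained)
    estimates.to_csv(out / "subject_estimates.tsv", sep="\t", index=False)
    group_summary.to_csv(out / "group_posterior.tsv", sep="\t", index=False)
    if len(rhat):
        rhat.to_csv(out / "rhat.tsv", sep="\t", index=False)
    for group, post in posteriors.items():
        post.to_frame().to_csv(out / f"posterior_draws_{group}.tsv", sep="\t", index=False)

    roi, dor_matrix, atlas = _stage("bold-dor", stage_bold, retained)
    roi.to_csv(out / "dor_roi_values.tsv", sep="\t", index=False)
    svio.save_map_nifti(dor_matrix.T, atlas.shape, out / "dor_maps.nii.gz")
    (out / "dor_subjects.txt").write_text("\n".join(roi["subject_id"]) + "\n")

    results = _stage("analyze", stage_group_stats, behavior, estimates, roi, dor_matrix, atlas)
    for key in ("anova", "clusters", "correlations", "fisher_z", "motion", "power"):
        results[key].to_csv(out / f"{key}.tsv", sep="\t", index=False)
    svio.save_map_nifti(results["t_map"], atlas.shape, out / "group_t_map.nii.gz")
    _write_report(out, results, behavior, rhat)
    log.info("pipeline complete: %s", out)
    return {
        "sessions": sessions, "truth": truth, "behavior": behavior,
        "estimates": estimates, "group_posterior": group_summary, "rhat": rhat,
        "roi": roi, "dor_matrix": dor_matrix, "atlas": atlas,
    } | results
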
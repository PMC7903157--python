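"""Hierarchical Bayesian estimation of the SSRT distribution.

The model is the Bayesian parametric approach to stop-signal data: go
finish times and stop-signal reaction times (SSRTs) each follow an
ex-Gaussian distribution, racing independently on stop trials, with a
per-subject probability ``p_tf`` that the stop process is never
triggered.  Trial likelihoods:

* go trial with RT t              ->  f_go(t)
* go omission                     ->  S_go(max_rt)            (right-censored)
* failed stop, RT t at SSD d      ->  f_go(t) * [p_tf + (1 - p_tf) * S_stop(t - d)]
* successful stop at SSD d        ->  (1 - p_tf) * Int f_stop(s) * S_go(d + s) ds

Subject-level parameters follow truncated-normal population
distributions whose locations and scales are estimated per group
(groups are always fitted separately); ``p_tf`` is modelled on the
probit scale with a normal population distribution.  Sampling is
adaptive Metropolis-within-Gibbs: per-subject parameter blocks (go
triplet, stop triplet, probit trigger-failure rate) and group-level
location/scale moves, with proposal scales tuned to 20-50% acceptance
during burn-in and frozen afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .behavior import compute_ssrt_integration
from .exceptions import ConfigurationError, DataError, ParameterError
from .exgauss import exgauss_logpdf, exgauss_logsf
from .simulate import RaceModelParams
from .task import ParticipantSession

PARAM_NAMES = ("mu_go", "sigma_go", "tau_go", "mu_stop", "sigma_stop", "tau_stop", "z_tf")
_GO, _STOP, _Z = slice(0, 3), slice(3, 6), 6

# fixed probit value representing p_tf = 0 when trigger failures are not estimated
_Z_OFF = -8.0


# --------------------------------------------------------------------------
# settings and priors
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class McmcSettings:
    """MCMC configuration (defaults: 3 chains, 30,000 samples of which
    10,000 burn-in, thinning 10, 1000 posterior predictions, trigger
    failures estimated)."""

    n_chains: int = 3
    n_samples: int = 30_000
    n_burn_in: int = 10_000
    thinning: int = 10
    n_predictions: int = 1000
    estimate_trigger_failure: bool = True
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ConfigurationError("need at least one chain")
        if self.n_samples <= self.n_burn_in:
            raise ConfigurationError("n_samples must exceed n_burn_in")
        if self.thinning < 1:
            raise ConfigurationError("thinning must be >= 1")

    @property
    def n_retained(self) -> int:
        """Retained draws per chain: (n_samples - n_burn_in) / thinning."""
        return (self.n_samples - self.n_burn_in) // self.thinning


@dataclass(frozen=True)
class PriorSpec:
    """Supports for subject parameters and uniform group-level priors.

    Subject parameters are truncated normal on ``bounds``; group
    locations are uniform on the same supports and group scales uniform
    on ``scale_bounds``.
    """

    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "mu_go": (0.0, 2000.0),
            "sigma_go": (1.0, 500.0),
            "tau_go": (1.0, 500.0),
            "mu_stop": (0.0, 2000.0),
            "sigma_stop": (1.0, 500.0),
            "tau_stop": (1.0, 500.0),
            "z_tf": (-6.0, 6.0),
        }
    )
    scale_bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "mu_go": (0.01, 500.0),
            "sigma_go": (0.01, 500.0),
            "tau_go": (0.01, 500.0),
            "mu_stop": (0.01, 500.0),
            "sigma_stop": (0.01, 500.0),
            "tau_stop": (0.01, 500.0),
            "z_tf": (0.01, 3.0),
        }
    )

    def lower(self) -> np.ndarray:
        return np.array([self.bounds[p][0] for p in PARAM_NAMES])

    def upper(self) -> np.ndarray:
        return np.array([self.bounds[p][1] for p in PARAM_NAMES])

    def scale_lower(self) -> np.ndarray:
        return np.array([self.scale_bounds[p][0] for p in PARAM_NAMES])

    def scale_upper(self) -> np.ndarray:
        return np.array([self.scale_bounds[p][1] for p in PARAM_NAMES])


# --------------------------------------------------------------------------
# likelihood internals (vectorised across subjects)
# --------------------------------------------------------------------------

_K_BODY = 48  # Gauss-Legendre nodes over the Gaussian body of the stop density
_K_TAIL = 48  # nodes over its exponential tail
_XI_BODY, _W_BODY = np.polynomial.legendre.leggauss(_K_BODY)
_XI_TAIL, _W_TAIL = np.polynomial.legendre.leggauss(_K_TAIL)


class _StackedData:
    """Trial data of one or more sessions flattened for vectorised use.

    Successful-stop trials are collapsed to unique (subject, SSD) pairs
    with counts, since the staircase revisits the same delays.
    """

    def __init__(self, sessions: Sequence[ParticipantSession]):
        self.n_subjects = len(sessions)
        self.subject_ids = [s.subject_id for s in sessions]
        self.max_rt = sessions[0].design.max_rt
        go_rt, go_idx = [], []
        n_omit = np.zeros(self.n_subjects)
        sr_rt, sr_d, sr_idx = [], [], []
        ss_pairs: dict[tuple[int, float], int] = {}
        for i, session in enumerate(sessions):
            for t in session.trials:
                if t.kind == "go":
                    if t.responded:
                        go_rt.append(t.rt)
                        go_idx.append(i)
                    else:
                        n_omit[i] += 1
                else:
                    if t.ssd is None:
                        raise DataError("stop trial without an SSD")
                    if t.responded:
                        if t.rt is None:
                            raise DataError("responded trial without an RT")
                        sr_rt.append(t.rt)
                        sr_d.append(t.ssd)
                        sr_idx.append(i)
                    else:
                        key = (i, float(t.ssd))
                        ss_pairs[key] = ss_pairs.get(key, 0) + 1
        self.go_rt = np.asarray(go_rt, dtype=float)
        self.go_idx = np.asarray(go_idx, dtype=np.intp)
        self.n_omit = n_omit
        self.sr_rt = np.asarray(sr_rt, dtype=float)
        self.sr_d = np.asarray(sr_d, dtype=float)
        self.sr_idx = np.asarray(sr_idx, dtype=np.intp)
        keys = sorted(ss_pairs)
        self.ss_idx = np.asarray([k[0] for k in keys], dtype=np.intp)
        self.ss_d = np.asarray([k[1] for k in keys], dtype=float)
        self.ss_cnt = np.asarray([ss_pairs[k] for k in keys], dtype=float)


def _quad_grid(stop: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes/log-weights for Int f_stop(s) * g(s) ds, per subject.

    Two Gauss-Legendre panels: [mu-8s, mu+8s] for the Gaussian body and
    [mu+8s, mu+8s+30t] for the exponential tail; omitted mass < 1e-12.
    Returns x and log(w) of shape (S, K_BODY + K_TAIL).
    """
    mu, sigma, tau = stop[:, 0:1], stop[:, 1:2], stop[:, 2:3]
    lo, mid = mu - 8.0 * sigma, mu + 8.0 * sigma
    hi = mid + 30.0 * tau
    x_body = 0.5 * (mid - lo) * _XI_BODY + 0.5 * (mid + lo)
    x_tail = 0.5 * (hi - mid) * _XI_TAIL + 0.5 * (hi + mid)
    logw_body = np.log(_W_BODY * 0.5) + np.log(mid - lo)
    logw_tail = np.log(_W_TAIL * 0.5) + np.log(hi - mid)
    x = np.concatenate([x_body, x_tail], axis=1)
    logw = np.concatenate(
        [np.broadcast_to(logw_body, x_body.shape), logw_tail], axis=1
    )
    return x, logw


def _stop_density_grid(stop: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nodes x and log(f_stop(x) * w) per subject, shape (S, K)."""
    x, logw = _quad_grid(stop)
    logf = exgauss_logpdf(x, stop[:, 0:1], stop[:, 1:2], stop[:, 2:3])
    return x, logf + logw


def _ll_go(data: _StackedData, go: np.ndarray) -> np.ndarray:
    """Go-trial log-likelihood per subject (responded + censored omissions)."""
    mu, sigma, tau = go[data.go_idx, 0], go[data.go_idx, 1], go[data.go_idx, 2]
    lp = exgauss_logpdf(data.go_rt, mu, sigma, tau)
    out = np.bincount(data.go_idx, weights=lp, minlength=data.n_subjects)
    out += data.n_omit * exgauss_logsf(data.max_rt, go[:, 0], go[:, 1], go[:, 2])
    return out


def _stop_pieces(
    data: _StackedData, go: np.ndarray, x: np.ndarray, log_fw: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """p_tf-independent pieces of the stop-trial likelihood.

    Returns ``sr_lp_go`` (log f_go at each signal-respond RT) is computed
    separately; here: the log success integrals per unique (subject, SSD)
    pair and nothing else.
    """
    gi = go[data.ss_idx]
    arg = data.ss_d[:, None] + x[data.ss_idx]
    log_sf_go = exgauss_logsf(arg, gi[:, 0:1], gi[:, 1:2], gi[:, 2:3])
    return special.logsumexp(log_fw[data.ss_idx] + log_sf_go, axis=1)


def _sr_terms(data: _StackedData, go: np.ndarray, stop: np.ndarray):
    gi = go[data.sr_idx]
    lp_go = exgauss_logpdf(data.sr_rt, gi[:, 0], gi[:, 1], gi[:, 2])
    si = stop[data.sr_idx]
    log_sf_st = exgauss_logsf(data.sr_rt - data.sr_d, si[:, 0], si[:, 1], si[:, 2])
    return lp_go, log_sf_st


def _combine_stop(
    data: _StackedData,
    sr_lp_go: np.ndarray,
    sr_log_sf_st: np.ndarray,
    ss_li: np.ndarray,
    z: np.ndarray,
) -> np.ndarray:
    """Stop-trial log-likelihood per subject, given cached pieces and z_tf."""
    p = special.ndtr(z)
    out = np.zeros(data.n_subjects)
    if data.sr_rt.size:
        pi = p[data.sr_idx]
        mix = sr_lp_go + np.log(pi + (1.0 - pi) * np.exp(sr_log_sf_st))
        out += np.bincount(data.sr_idx, weights=mix, minlength=data.n_subjects)
    if data.ss_d.size:
        with np.errstate(divide="ignore"):
            term = data.ss_cnt * (np.log1p(-p[data.ss_idx]) + ss_li)
        out += np.bincount(data.ss_idx, weights=term, minlength=data.n_subjects)
    return out


# --------------------------------------------------------------------------
# public likelihood API
# --------------------------------------------------------------------------


def _params_vector(params: RaceModelParams) -> np.ndarray:
    z = special.ndtri(params.p_tf) if 0.0 < params.p_tf < 1.0 else (
        -np.inf if params.p_tf == 0.0 else np.inf
    )
    return np.array(
        [params.mu_go, params.sigma_go, params.tau_go,
         params.mu_stop, params.sigma_stop, params.tau_stop, z]
    )


def successful_stop_prob(params: RaceModelParams, ssd) -> np.ndarray | float:
    """P(successful inhibition | SSD) = (1-p_tf) * Int f_stop * S_go.

    Nonincreasing in SSD; zero when p_tf = 1.
    """
    ssd = np.atleast_1d(np.asarray(ssd, dtype=float))
    stop = np.array([[params.mu_stop, params.sigma_stop, params.tau_stop]])
    x, log_fw = _stop_density_grid(stop)
    log_sf_go = exgauss_logsf(
        ssd[:, None] + x[0], params.mu_go, params.sigma_go, params.tau_go
    )
    integral = np.exp(special.logsumexp(log_fw[0] + log_sf_go, axis=1))
    out = (1.0 - params.p_tf) * integral
    return out if out.size > 1 else float(out[0])


def signal_respond_logpdf(t, ssd, params: RaceModelParams):
    """Log density of responding at time t on a stop trial with the given SSD."""
    lp_go = exgauss_logpdf(t, params.mu_go, params.sigma_go, params.tau_go)
    sf_st = np.exp(
        exgauss_logsf(
            np.asarray(t, dtype=float) - ssd,
            params.mu_stop, params.sigma_stop, params.tau_stop,
        )
    )
    with np.errstate(divide="ignore"):
        return lp_go + np.log(params.p_tf + (1.0 - params.p_tf) * sf_st)


def trial_loglik(trial, params: RaceModelParams, max_rt: float = 1500.0) -> float:
    """Log-likelihood of a single trial under the race model."""
    if trial.kind == "go":
        if trial.responded:
            if trial.rt is None:
                raise DataError("responded go trial without an RT")
            return float(exgauss_logpdf(trial.rt, params.mu_go, params.sigma_go, params.tau_go))
        return float(exgauss_logsf(max_rt, params.mu_go, params.sigma_go, params.tau_go))
    if trial.ssd is None:
        raise DataError("stop trial without an SSD")
    if trial.responded:
        if trial.rt is None:
            raise DataError("responded stop trial without an RT")
        return float(signal_respond_logpdf(trial.rt, trial.ssd, params))
    with np.errstate(divide="ignore"):
        return float(np.log(successful_stop_prob(params, trial.ssd)))


def session_loglik(session: ParticipantSession, params: RaceModelParams) -> float:
    """Sum of trial log-likelihoods for one session (vectorised)."""
    data = _StackedData([session])
    theta = _params_vector(params)[None, :]
    ll = _ll_go(data, theta[:, _GO])
    x, log_fw = _stop_density_grid(theta[:, _STOP])
    ss_li = _stop_pieces(data, theta[:, _GO], x, log_fw)
    sr_lp_go, sr_log_sf = _sr_terms(data, theta[:, _GO], theta[:, _STOP])
    ll = ll + _combine_stop(data, sr_lp_go, sr_log_sf, ss_li, theta[:, _Z])
    return float(ll[0])


# --------------------------------------------------------------------------
# hierarchical sampler
# --------------------------------------------------------------------------


def _truncnorm_logpdf(x, loc, scale, lo, hi):
    """Vectorised truncated-normal log density; -inf outside [lo, hi]."""
    z = (x - loc) / scale
    log_mass = np.log(
        np.maximum(special.ndtr((hi - loc) / scale) - special.ndtr((lo - loc) / scale), 1e-300)
    )
    out = -0.5 * z * z - np.log(scale) - 0.5 * np.log(2.0 * np.pi) - log_mass
    return np.where((x < lo) | (x > hi), -np.inf, out)


@dataclass
class HierarchicalPosterior:
    """Retained MCMC draws for one group's hierarchical fit.

    ``subject_draws`` has shape (chains, draws, subjects, 7) in
    PARAM_NAMES order (z_tf on the probit scale); group locations and
    scales have shape (chains, draws, 7).
    """

    subject_ids: list[str]
    param_names: tuple[str, ...]
    subject_draws: np.ndarray
    group_loc_draws: np.ndarray
    group_scale_draws: np.ndarray
    acceptance: dict[str, float]
    settings: McmcSettings
    group: str = ""

    @property
    def n_chains(self) -> int:
        return self.subject_draws.shape[0]

    @property
    def n_retained(self) -> int:
        return self.subject_draws.shape[1]

    def to_inference_data(self):
        """Group-level draws as an ``arviz.InferenceData``."""
        import arviz as az

        data = {}
        for j, name in enumerate(self.param_names):
            data[f"loc_{name}"] = self.group_loc_draws[:, :, j]
            data[f"scale_{name}"] = self.group_scale_draws[:, :, j]
        return az.from_dict(posterior=data)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (chain, iteration, parameter, value) of all draws."""
        rows = []
        C, D, S, P = self.subject_draws.shape
        for c in range(C):
            for j, name in enumerate(self.param_names):
                for what, arr in (
                    ("loc", self.group_loc_draws),
                    ("scale", self.group_scale_draws),
                ):
                    rows.append(
                        pd.DataFrame(
                            {
                                "chain": c,
                                "iteration": np.arange(D),
                                "parameter": f"{what}_{name}",
                                "value": arr[c, :, j],
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)


def _initial_state(
    sessions: Sequence[ParticipantSession],
    priors: PriorSpec,
    rng: np.random.Generator,
    estimate_tf: bool,
) -> np.ndarray:
    """Data-driven per-subject starting values, jittered per chain."""
    lower, upper = priors.lower(), priors.upper()
    S = len(sessions)
    P = np.empty((S, 7))
    for i, session in enumerate(sessions):
        rts = np.array([t.rt for t in session.go_trials if t.responded], dtype=float)
        m = float(np.mean(rts)) if rts.size else 500.0
        s = float(np.std(rts)) if rts.size > 1 else 100.0
        tau0 = np.clip(0.8 * s, 10.0, 400.0)
        sigma0 = np.clip(np.sqrt(max(s * s - tau0 * tau0, 100.0)), 5.0, 400.0)
        mu0 = np.clip(m - tau0, 50.0, 1500.0)
        try:
            ssrt0 = compute_ssrt_integration(session)
            ssrt0 = float(np.clip(ssrt0, 80.0, 800.0))
        except DataError:
            ssrt0 = 250.0
        P[i] = [mu0, sigma0, tau0, 0.75 * ssrt0, 30.0, 0.25 * ssrt0,
                special.ndtri(0.03) if estimate_tf else _Z_OFF]
    jitter = np.array([20.0, 8.0, 15.0, 20.0, 8.0, 10.0, 0.3 if estimate_tf else 0.0])
    P = P + rng.normal(0.0, 1.0, P.shape) * jitter
    return np.clip(P, lower + 1e-3, upper - 1e-3)


def fit_hierarchical(
    sessions: Sequence[ParticipantSession],
    settings: McmcSettings | None = None,
    priors: PriorSpec | None = None,
    group: str = "",
) -> HierarchicalPosterior:
    """Fit the hierarchical race model to one group's sessions.

    Runs ``settings.n_chains`` independent adaptive
    Metropolis-within-Gibbs chains; identical seeds give identical
    draws.  Convergence is *reported*, not assumed: run
    :func:`rhat_diagnostics` on the result.
    """
    if len(sessions) < 2:
        raise ConfigurationError("hierarchical fit needs at least 2 subjects")
    settings = settings or McmcSettings()
    priors = priors or PriorSpec()
    data = _StackedData(sessions)
    S = data.n_subjects
    estimate_tf = settings.estimate_trigger_failure

    lower, upper = priors.lower(), priors.upper()
    slower, supper = priors.scale_lower(), priors.scale_upper()
    n_ret = settings.n_retained

    subject_draws = np.empty((settings.n_chains, n_ret, S, 7))
    loc_draws = np.empty((settings.n_chains, n_ret, 7))
    scale_draws = np.empty((settings.n_chains, n_ret, 7))
    acc_totals: dict[str, list[float]] = {
        "go": [], "stop": [], "z": [], "group": [], "joint": []
    }

    seed_seq = np.random.SeedSequence(settings.rng_seed)
    chain_seeds = seed_seq.spawn(settings.n_chains)

    base_step = {
        "go": np.array([10.0, 5.0, 10.0]),
        "stop": np.array([12.0, 6.0, 12.0]),
        "z": 0.3,
        # joint moves: translate a family with its group location, or
        # stretch its deviations together with the group scale
        "tr_go": 4.0, "tr_stop": 5.0, "tr_z": 0.15,
        "st_go": 0.08, "st_stop": 0.1, "st_z": 0.1,
        # mean-preserving mu/tau trade: the flattest posterior direction
        "rg_go": 6.0, "rg_stop": 8.0,
    }
    _RIDGE = np.array([1.0, 0.0, -1.0])
    _ZS = slice(6, 7)

    for chain in range(settings.n_chains):
        rng = np.random.default_rng(chain_seeds[chain])
        P = _initial_state(sessions, priors, rng, estimate_tf)
        loc = np.clip(P.mean(axis=0), lower + 1e-3, upper - 1e-3)
        scale = np.clip(P.std(axis=0), np.maximum(slower * 2, 1.0), supper - 1e-3)
        scale[_Z] = np.clip(scale[_Z], 0.1, supper[_Z] - 1e-3) if estimate_tf else 0.1

        # caches
        ll_go = _ll_go(data, P[:, _GO])
        x, log_fw = _stop_density_grid(P[:, _STOP])
        ss_li = _stop_pieces(data, P[:, _GO], x, log_fw)
        sr_lp_go, sr_log_sf = _sr_terms(data, P[:, _GO], P[:, _STOP])
        ll_stop = _combine_stop(data, sr_lp_go, sr_log_sf, ss_li, P[:, _Z])

        log_step = {
            "go": np.zeros(S),
            "stop": np.zeros(S),
            "z": np.zeros(S),
            "loc": np.zeros(7),
            "scale": np.zeros(7),
            "tr_go": 0.0, "tr_stop": 0.0, "tr_z": 0.0,
            "st_go": 0.0, "st_stop": 0.0, "st_z": 0.0,
            "rg_go": 0.0, "rg_stop": 0.0,
        }
        acc_count = {k: np.zeros_like(v) for k, v in log_step.items()}
        window = 25
        ret = 0

        for it in range(settings.n_samples):
            in_burn = it < settings.n_burn_in

            def _prior_block(mat, cols):
                return _truncnorm_logpdf(
                    mat, loc[cols], scale[cols], lower[cols], upper[cols]
                ).sum(axis=1)

            # --- go block ------------------------------------------------
            step = np.exp(log_step["go"])[:, None] * base_step["go"]
            prop = P[:, _GO] + rng.normal(size=(S, 3)) * step
            ok = np.all((prop > lower[_GO]) & (prop < upper[_GO]), axis=1)
            prop_safe = np.where(ok[:, None], prop, P[:, _GO])
            ll_go_p = _ll_go(data, prop_safe)
            ss_li_p = _stop_pieces(data, prop_safe, x, log_fw)
            sr_lp_go_p, _ = _sr_terms(data, prop_safe, P[:, _STOP])
            ll_stop_p = _combine_stop(data, sr_lp_go_p, sr_log_sf, ss_li_p, P[:, _Z])
            delta = (
                ll_go_p + ll_stop_p - ll_go - ll_stop
                + _prior_block(prop_safe, _GO) - _prior_block(P[:, _GO], _GO)
            )
            accept = ok & (np.log(rng.random(S)) < delta)
            P[accept, _GO] = prop[accept]
            ll_go[accept] = ll_go_p[accept]
            ll_stop[accept] = ll_stop_p[accept]
            if data.sr_rt.size:
                m = accept[data.sr_idx]
                sr_lp_go[m] = sr_lp_go_p[m]
            if data.ss_d.size:
                m = accept[data.ss_idx]
                ss_li[m] = ss_li_p[m]
            acc_count["go"] += accept

            # --- stop block ----------------------------------------------
            step = np.exp(log_step["stop"])[:, None] * base_step["stop"]
            prop = P[:, _STOP] + rng.normal(size=(S, 3)) * step
            ok = np.all((prop > lower[_STOP]) & (prop < upper[_STOP]), axis=1)
            prop_safe = np.where(ok[:, None], prop, P[:, _STOP])
            x_p, log_fw_p = _stop_density_grid(prop_safe)
            ss_li_p = _stop_pieces(data, P[:, _GO], x_p, log_fw_p)
            _, sr_log_sf_p = _sr_terms(data, P[:, _GO], prop_safe)
            ll_stop_p = _combine_stop(data, sr_lp_go, sr_log_sf_p, ss_li_p, P[:, _Z])
            delta = (
                ll_stop_p - ll_stop
                + _prior_block(prop_safe, _STOP) - _prior_block(P[:, _STOP], _STOP)
            )
            accept = ok & (np.log(rng.random(S)) < delta)
            P[accept, _STOP] = prop[accept]
            ll_stop[accept] = ll_stop_p[accept]
            x[accept] = x_p[accept]
            log_fw[accept] = log_fw_p[accept]
            if data.sr_rt.size:
                m = accept[data.sr_idx]
                sr_log_sf[m] = sr_log_sf_p[m]
            if data.ss_d.size:
                m = accept[data.ss_idx]
                ss_li[m] = ss_li_p[m]
            acc_count["stop"] += accept

            # --- trigger-failure block -----------------------------------
            if estimate_tf:
                step = np.exp(log_step["z"]) * base_step["z"]
                prop_z = P[:, _Z] + rng.normal(size=S) * step
                ok = (prop_z > lower[_Z]) & (prop_z < upper[_Z])
                prop_safe_z = np.where(ok, prop_z, P[:, _Z])
                ll_stop_p = _combine_stop(data, sr_lp_go, sr_log_sf, ss_li, prop_safe_z)
                delta = (
                    ll_stop_p - ll_stop
                    + _truncnorm_logpdf(prop_safe_z, loc[_Z], scale[_Z], lower[_Z], upper[_Z])
                    - _truncnorm_logpdf(P[:, _Z], loc[_Z], scale[_Z], lower[_Z], upper[_Z])
                )
                accept = ok & (np.log(rng.random(S)) < delta)
                P[accept, _Z] = prop_z[accept]
                ll_stop[accept] = ll_stop_p[accept]
                acc_count["z"] += accept

            # --- group level ---------------------------------------------
            for what in ("loc", "scale"):
                step = np.exp(log_step[what]) * np.where(
                    np.arange(7) == _Z, 0.1, 5.0
                )
                if what == "loc":
                    prop_g = loc + rng.normal(size=7) * step
                    ok = (prop_g > lower) & (prop_g < upper)
                    cur_lp = _truncnorm_logpdf(P, loc, scale, lower, upper).sum(axis=0)
                    prop_safe_g = np.where(ok, prop_g, loc)
                    new_lp = _truncnorm_logpdf(P, prop_safe_g, scale, lower, upper).sum(axis=0)
                else:
                    prop_g = scale + rng.normal(size=7) * step
                    ok = (prop_g > slower) & (prop_g < supper)
                    cur_lp = _truncnorm_logpdf(P, loc, scale, lower, upper).sum(axis=0)
                    prop_safe_g = np.where(ok, prop_g, scale)
                    new_lp = _truncnorm_logpdf(P, loc, prop_safe_g, lower, upper).sum(axis=0)
                accept = ok & (np.log(rng.random(7)) < new_lp - cur_lp)
                if not estimate_tf:
                    accept[_Z] = False
                if what == "loc":
                    loc = np.where(accept, prop_g, loc)
                else:
                    scale = np.where(accept, prop_g, scale)
                acc_count[what] += accept

            # --- joint translation / stretch moves ------------------------
            # The conditional of a group location given subject values is
            # far narrower than its marginal; translating the whole family
            # (or stretching its deviations with the group scale) moves
            # along the marginal direction and restores mixing.
            fams = [("go", _GO), ("stop", _STOP)] + ([("z", _ZS)] if estimate_tf else [])
            for fam, cols in fams:
                moves = ("tr", "st", "rg") if fam in ("go", "stop") else ("tr", "st")
                for move in moves:
                    key = f"{move}_{fam}"
                    step = np.exp(log_step[key]) * base_step[key]
                    nc = P[:, cols].shape[1]
                    if move == "tr":
                        shift = rng.normal(size=nc) * step
                        loc_p, scale_p = loc[cols] + shift, scale[cols]
                        subj_p = P[:, cols] + shift
                        jac = 0.0
                    elif move == "rg":
                        shift = rng.normal() * step * _RIDGE
                        loc_p, scale_p = loc[cols] + shift, scale[cols]
                        subj_p = P[:, cols] + shift
                        jac = 0.0
                    else:
                        gamma = np.exp(rng.normal(size=nc) * step)
                        loc_p, scale_p = loc[cols], scale[cols] * gamma
                        subj_p = loc_p + (P[:, cols] - loc_p) * gamma
                        jac = (S + 1) * float(np.sum(np.log(gamma)))
                    ok = (
                        np.all((loc_p > lower[cols]) & (loc_p < upper[cols]))
                        and np.all((scale_p > slower[cols]) & (scale_p < supper[cols]))
                        and np.all((subj_p > lower[cols]) & (subj_p < upper[cols]))
                    )
                    if not ok:
                        rng.random()  # keep the draw stream aligned
                        continue
                    prior_cur = _truncnorm_logpdf(
                        P[:, cols], loc[cols], scale[cols], lower[cols], upper[cols]
                    ).sum()
                    prior_new = _truncnorm_logpdf(
                        subj_p, loc_p, scale_p, lower[cols], upper[cols]
                    ).sum()
                    if fam == "go":
                        ll_go_p = _ll_go(data, subj_p)
                        ss_li_p = _stop_pieces(data, subj_p, x, log_fw)
                        sr_lp_go_p, _ = _sr_terms(data, subj_p, P[:, _STOP])
                        ll_stop_p = _combine_stop(data, sr_lp_go_p, sr_log_sf, ss_li_p, P[:, _Z])
                        dll = (ll_go_p.sum() + ll_stop_p.sum()) - (ll_go.sum() + ll_stop.sum())
                    elif fam == "stop":
                        x_p, log_fw_p = _stop_density_grid(subj_p)
                        ss_li_p = _stop_pieces(data, P[:, _GO], x_p, log_fw_p)
                        _, sr_log_sf_p = _sr_terms(data, P[:, _GO], subj_p)
                        ll_stop_p = _combine_stop(data, sr_lp_go, sr_log_sf_p, ss_li_p, P[:, _Z])
                        dll = ll_stop_p.sum() - ll_stop.sum()
                    else:
                        ll_stop_p = _combine_stop(data, sr_lp_go, sr_log_sf, ss_li, subj_p[:, 0])
                        dll = ll_stop_p.sum() - ll_stop.sum()
                    if np.log(rng.random()) < dll + prior_new - prior_cur + jac:
                        P[:, cols] = subj_p
                        if move in ("tr", "rg"):
                            loc[cols] = loc_p
                        else:
                            scale[cols] = scale_p
                        if fam == "go":
                            ll_go, ll_stop = ll_go_p, ll_stop_p
                            sr_lp_go, ss_li = sr_lp_go_p, ss_li_p
                        elif fam == "stop":
                            ll_stop = ll_stop_p
                            x, log_fw = x_p, log_fw_p
                            sr_log_sf, ss_li = sr_log_sf_p, ss_li_p
                        else:
                            ll_stop = ll_stop_p
                        acc_count[key] = acc_count[key] + 1.0

            # --- adaptation (burn-in only) --------------------------------
            if in_burn and (it + 1) % window == 0:
                for key in log_step:
                    rate = acc_count[key] / window
                    log_step[key] = np.clip(
                        log_step[key] + 0.5 * (rate - 0.3), -6.0, 4.0
                    )
                    acc_count[key] = acc_count[key] * 0.0
            # --- retain ---------------------------------------------------
            if not in_burn and (it - settings.n_burn_in) % settings.thinning == 0:
                subject_draws[chain, ret] = P
                loc_draws[chain, ret] = loc
                scale_draws[chain, ret] = scale
                ret += 1

        assert ret == n_ret
        denom = settings.n_samples - settings.n_burn_in
        acc_totals["go"].append(float(np.mean(acc_count["go"])) / denom)
        acc_totals["stop"].append(float(np.mean(acc_count["stop"])) / denom)
        acc_totals["z"].append(float(np.mean(acc_count["z"])) / denom)
        acc_totals["group"].append(
            float(np.mean(acc_count["loc"] + acc_count["scale"])) / (2 * denom)
        )
        joint_keys = ["tr_go", "tr_stop", "st_go", "st_stop", "rg_go", "rg_stop"] + (
            ["tr_z", "st_z"] if estimate_tf else []
        )
        acc_totals["joint"].append(
            float(np.mean([acc_count[k] for k in joint_keys])) / denom
        )

    return HierarchicalPosterior(
        subject_ids=data.subject_ids,
        param_names=PARAM_NAMES,
        subject_draws=subject_draws,
        group_loc_draws=loc_draws,
        group_scale_draws=scale_draws,
        acceptance={k: float(np.mean(v)) for k, v in acc_totals.items()},
        settings=settings,
        group=group or (sessions[0].group if sessions else ""),
    )


def fit_groups(
    sessions: Sequence[ParticipantSession],
    settings: McmcSettings | None = None,
    priors: PriorSpec | None = None,
) -> dict[str, HierarchicalPosterior]:
    """Fit each group separately (never pooled), keyed by group label."""
    settings = settings or McmcSettings()
    groups: dict[str, list[ParticipantSession]] = {}
    for s in sessions:
        groups.setdefault(s.group, []).append(s)
    out = {}
    seq = np.random.SeedSequence(settings.rng_seed)
    for (name, group_sessions), child_seed in zip(sorted(groups.items()), seq.spawn(len(groups))):
        sub_settings = McmcSettings(
            n_chains=settings.n_chains,
            n_samples=settings.n_samples,
            n_burn_in=settings.n_burn_in,
            thinning=settings.thinning,
            n_predictions=settings.n_predictions,
            estimate_trigger_failure=settings.estimate_trigger_failure,
            rng_seed=int(child_seed.generate_state(1)[0] % (2**31 - 1)),
        )
        out[name] = fit_hierarchical(group_sessions, sub_settings, priors, group=name)
    return out


# --------------------------------------------------------------------------
# diagnostics, summaries, predictions
# --------------------------------------------------------------------------


def rhat_diagnostics(posterior: HierarchicalPosterior, threshold: float = 1.1) -> pd.DataFrame:
    """Split-R̂ per group-level parameter; flags values above threshold."""
    if posterior.n_chains < 2:
        raise ConfigurationError("R-hat needs at least 2 chains")
    import arviz as az

    active = posterior.param_names if posterior.settings.estimate_trigger_failure else [
        p for p in posterior.param_names if p != "z_tf"
    ]
    data = {}
    for j, name in enumerate(posterior.param_names):
        if name not in active:
            continue
        data[f"loc_{name}"] = posterior.group_loc_draws[:, :, j]
        data[f"scale_{name}"] = posterior.group_scale_draws[:, :, j]
    rhat = az.rhat(az.from_dict(posterior=data), method="split")
    rows = []
    for name in active:
        for what in ("loc", "scale"):
            value = float(rhat[f"{what}_{name}"].values)
            rows.append(
                {"parameter": f"{what}_{name}", "rhat": value, "flagged": value > threshold}
            )
    return pd.DataFrame(rows)


def posterior_summaries(
    posterior: HierarchicalPosterior,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Posterior medians and central 95% intervals.

    Returns (subject_table, group_table).  Subject rows report the
    ex-Gaussian parameters in ms and ``p_tf`` on the probability scale;
    the stop-parameter columns are the per-subject behavioral
    variability measures used downstream.
    """
    draws = posterior.subject_draws.reshape(-1, *posterior.subject_draws.shape[2:])
    rows = []
    for i, sid in enumerate(posterior.subject_ids):
        row = {"subject_id": sid, "group": posterior.group}
        for j, name in enumerate(posterior.param_names):
            values = draws[:, i, j]
            if name == "z_tf":
                values = special.ndtr(values)
                name = "p_tf"
            row[name] = float(np.median(values))
            row[f"{name}_lo"] = float(np.percentile(values, 2.5))
            row[f"{name}_hi"] = float(np.percentile(values, 97.5))
        rows.append(row)
    subject_df = pd.DataFrame(rows)

    grows = []
    for what, arr in (("loc", posterior.group_loc_draws), ("scale", posterior.group_scale_draws)):
        flat = arr.reshape(-1, arr.shape[-1])
        for j, name in enumerate(posterior.param_names):
            grows.append(
                {
                    "group": posterior.group,
                    "parameter": f"{what}_{name}",
                    "median": float(np.median(flat[:, j])),
                    "ci_lo": float(np.percentile(flat[:, j], 2.5)),
                    "ci_hi": float(np.percentile(flat[:, j], 97.5)),
                }
            )
    return subject_df, pd.DataFrame(grows)


def posterior_predictive(
    posterior: HierarchicalPosterior,
    n_predictions: Optional[int] = None,
    n_per_draw: int = 100,
    rng_seed=None,
) -> np.ndarray:
    """Predicted SSRT samples for the fitted group.

    Draws ``n_predictions`` retained posterior states; for each, samples
    a new subject's stop parameters from the population distribution and
    ``n_per_draw`` SSRTs from the implied ex-Gaussian.  The pooled array
    is the estimated group SSRT distribution.
    """
    from scipy import stats as sps

    n_predictions = n_predictions or posterior.settings.n_predictions
    rng = np.random.default_rng(rng_seed)
    C, D = posterior.group_loc_draws.shape[:2]
    chains = rng.integers(0, C, n_predictions)
    iters = rng.integers(0, D, n_predictions)
    priors = PriorSpec()
    out = np.empty((n_predictions, n_per_draw))
    stop_names = ("mu_stop", "sigma_stop", "tau_stop")
    idx = [posterior.param_names.index(n) for n in stop_names]
    for k in range(n_predictions):
        loc = posterior.group_loc_draws[chains[k], iters[k], idx]
        scale = posterior.group_scale_draws[chains[k], iters[k], idx]
        subj = np.empty(3)
        for j, name in enumerate(stop_names):
            lo, hi = priors.bounds[name]
            a, b = (lo - loc[j]) / scale[j], (hi - loc[j]) / scale[j]
            subj[j] = sps.truncnorm.ppf(rng.random(), a, b, loc=loc[j], scale=scale[j])
        out[k] = rng.normal(subj[0], subj[1], n_per_draw) + rng.exponential(subj[2], n_per_draw)
    return out.ravel()
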
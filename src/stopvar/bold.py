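"""Trial-by-trial BOLD variability via the difference of residuals (DoR).

Two GLMs are fitted per run: a *standard* model with one regressor per
condition (canonical HRF plus temporal and dispersion derivatives) and
one regressor for error trials, and a *trialwise* model identical
except that the condition of interest's canonical regressor is replaced
by one canonical regressor per trial of that condition.  The trialwise
design nests the standard one, so its residual sum of squares (SSR) is
voxel-wise no larger; the difference

    DoR = SSR_standard - SSR_trialwise

is the variance uniquely captured by letting each trial have its own
amplitude, i.e. the trial-by-trial variability of the condition of
interest.  Neither SSR is divided by degrees of freedom: the trialwise
model's df depends on the subject's number of trials of that condition,
and dividing would bias subjects with different success/failure ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DataError, ParameterError

DEFAULT_HP_CUTOFF = 128.0  # s, discrete-cosine high-pass


# --------------------------------------------------------------------------
# HRF basis
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HrfBasis:
    """Canonical double-gamma HRF with temporal/dispersion derivatives.

    Kernels are sampled on a microtime grid of step ``dt`` seconds; the
    canonical kernel is peak-normalised to 1.
    """

    canonical: np.ndarray
    temporal_deriv: np.ndarray
    dispersion_deriv: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        if not (len(self.canonical) == len(self.temporal_deriv) == len(self.dispersion_deriv)):
            raise ParameterError("basis kernels must share length")


def _double_gamma(t, peak_delay, peak_disp, under_delay, under_disp, ratio):
    peak = sps.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = sps.gamma.pdf(t, under_delay / under_disp, scale=under_disp)
    return peak - under / ratio


def hrf_basis(
    tr: float,
    microtime_resolution: int = 16,
    peak_delay: float = 6.0,
    peak_disp: float = 1.0,
    under_delay: float = 16.0,
    under_disp: float = 1.0,
    ratio: float = 6.0,
    length: float = 32.0,
    deriv_delta: float = 1.0,
    disp_delta: float = 0.01,
) -> HrfBasis:
    """Double-gamma HRF basis sampled at dt = tr / microtime_resolution.

    The temporal derivative is the backward finite difference
    ``(h(t) - h(t - deriv_delta)) / deriv_delta`` and the dispersion
    derivative the finite difference in the peak dispersion parameter.
    """
    if tr <= 0:
        raise ParameterError("tr must be positive")
    if min(peak_delay, peak_disp, under_delay, under_disp, ratio) <= 0:
        raise ParameterError("HRF shape parameters must be positive")
    dt = tr / microtime_resolution
    t = np.arange(0.0, length, dt)

    h = _double_gamma(t, peak_delay, peak_disp, under_delay, under_disp, ratio)
    scale = h.max()
    h = h / scale
    h_shift = _double_gamma(t - deriv_delta, peak_delay, peak_disp, under_delay, under_disp, ratio)
    h_shift = np.where(t - deriv_delta < 0, 0.0, h_shift) / scale
    td = (h - h_shift) / deriv_delta
    h_disp = _double_gamma(t, peak_delay, peak_disp + disp_delta, under_delay, under_disp, ratio)
    dd = (h - h_disp / scale) / disp_delta
    return HrfBasis(canonical=h, temporal_deriv=td, dispersion_deriv=dd, dt=dt)


def convolve_events(
    onsets: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    n_volumes: int,
    tr: float,
    kernel: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Convolve an event train with a kernel and sample at volume times.

    Zero-duration events are modelled as unit impulses on the microtime
    grid; longer durations as boxcars.
    """
    n_bins = int(np.ceil(n_volumes * tr / dt)) + len(kernel)
    stim = np.zeros(n_bins)
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        start = int(round(onset / dt))
        stop = max(start + 1, int(round((onset + dur) / dt)))
        stim[start:stop] += amp
    full = np.convolve(stim, kernel)[:n_bins]
    vol_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return full[vol_idx]


# --------------------------------------------------------------------------
# design matrices
# --------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Time x regressor matrix with names and bookkeeping."""

    matrix: np.ndarray
    names: list[str]
    mode: str  # "standard" | "trialwise"
    condition_of_interest: str
    coi_columns: list[int]
    rank: int = 0

    def __post_init__(self) -> None:
        self.rank = int(np.linalg.matrix_rank(self.matrix))

    @property
    def full_rank(self) -> bool:
        return self.rank == self.matrix.shape[1]


def dct_drift_columns(n_volumes: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine high-pass set for periods longer than ``cutoff`` s."""
    order = int(np.floor(2.0 * n_volumes * tr / cutoff))
    n = np.arange(n_volumes)
    cols = [np.cos(np.pi * r * (n + 0.5) / n_volumes) for r in range(1, order + 1)]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


def build_design(
    events: pd.DataFrame,
    mode: str,
    condition_of_interest: str,
    n_volumes: int,
    tr: float,
    nuisance: Optional[np.ndarray] = None,
    conditions: Optional[Sequence[str]] = None,
    error_label: str = "error",
    basis: Optional[HrfBasis] = None,
    hp_cutoff: Optional[float] = DEFAULT_HP_CUTOFF,
    derivatives: bool = True,
) -> DesignMatrix:
    """Build a standard or trialwise GLM design.

    Standard mode: per condition, the canonical regressor plus (if
    ``derivatives``) temporal and dispersion derivatives; error trials
    get a single canonical regressor; then drift columns, nuisance
    series, and an intercept.  Trialwise mode is identical except the
    condition of interest's single canonical regressor is replaced by
    one canonical regressor per trial of that condition (its
    derivatives remain at condition level, preserving nesting).
    """
    if mode not in ("standard", "trialwise"):
        raise DataError(f"unknown design mode {mode!r}")
    if np.any(events["onset"].to_numpy() > n_volumes * tr):
        raise DataError("events extend beyond the end of the run")
    basis = basis or hrf_basis(tr)
    if conditions is None:
        conditions = sorted(c for c in events["trial_type"].unique() if c != error_label)
    if condition_of_interest not in conditions:
        raise DataError(f"condition of interest {condition_of_interest!r} not in {conditions}")

    def _conv(sel: pd.DataFrame, kernel: np.ndarray) -> np.ndarray:
        return convolve_events(
            sel["onset"].to_numpy(float),
            sel["duration"].to_numpy(float),
            np.ones(len(sel)),
            n_volumes, tr, kernel, basis.dt,
        )

    cols, names, coi_cols = [], [], []
    for cond in conditions:
        sel = events[events["trial_type"] == cond]
        if mode == "trialwise" and cond == condition_of_interest:
            for k in range(len(sel)):
                cols.append(_conv(sel.iloc[[k]], basis.canonical))
                names.append(f"{cond}#trial{k:03d}")
                coi_cols.append(len(cols) - 1)
        else:
            cols.append(_conv(sel, basis.canonical))
            names.append(cond)
            if cond == condition_of_interest:
                coi_cols.append(len(cols) - 1)
        if derivatives:
            cols.append(_conv(sel, basis.temporal_deriv))
            names.append(f"{cond}:td")
            cols.append(_conv(sel, basis.dispersion_deriv))
            names.append(f"{cond}:dd")
    errors = events[events["trial_type"] == error_label]
    if len(errors):
        cols.append(_conv(errors, basis.canonical))
        names.append(error_label)
    if hp_cutoff:
        drift = dct_drift_columns(n_volumes, tr, hp_cutoff)
        for r in range(drift.shape[1]):
            cols.append(drift[:, r])
            names.append(f"drift{r + 1:02d}")
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_volumes:
            nuisance = nuisance.T
        if nuisance.shape[0] != n_volumes:
            raise DataError("nuisance series length does not match run volumes")
        for r in range(nuisance.shape[1]):
            cols.append(nuisance[:, r])
            names.append(f"nuisance{r + 1:02d}")
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    return DesignMatrix(
        matrix=np.column_stack(cols),
        names=names,
        mode=mode,
        condition_of_interest=condition_of_interest,
        coi_columns=coi_cols,
    )


# --------------------------------------------------------------------------
# GLM fitting, DoR, denoising, motion
# --------------------------------------------------------------------------


@dataclass
class SsrMap:
    """Voxel-wise raw residual sum of squares (never divided by df)."""

    values: np.ndarray
    mode: str
    subject_id: str = ""
    run: int = 0


@dataclass
class DoRMap:
    """Voxel-wise difference of residuals for one condition of interest."""

    values: np.ndarray
    condition: str
    subject_id: str = ""


def fit_glm_ssr(bold, design: DesignMatrix) -> SsrMap:
    """Ordinary least squares per voxel; returns raw SSR.

    ``bold`` is a (voxels x time) array or any object with a ``data``
    attribute of that shape.
    """
    Y = np.asarray(getattr(bold, "data", bold), dtype=float)
    X = design.matrix
    if Y.shape[1] != X.shape[0]:
        raise DataError(
            f"run has {Y.shape[1]} volumes but the design {X.shape[0]} rows"
        )
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    return SsrMap(values=np.sum(resid**2, axis=0), mode=design.mode)


def difference_of_residuals(
    ssr_standard: SsrMap, ssr_trialwise: SsrMap, condition: str = "stop-success",
    tol: float = 1e-8,
) -> DoRMap:
    """DoR = SSR_standard - SSR_trialwise, per voxel.

    Nonnegative up to numerical tolerance because the trialwise design
    nests the standard one; values within ``tol`` of zero are clipped
    to zero at reporting.
    """
    if ssr_standard.mode != "standard" or ssr_trialwise.mode != "trialwise":
        raise DataError(
            f"expected (standard, trialwise) SSR maps, got "
            f"({ssr_standard.mode}, {ssr_trialwise.mode})"
        )
    if ssr_standard.values.shape != ssr_trialwise.values.shape:
        raise DataError("SSR maps are on different voxel grids")
    dor = ssr_standard.values - ssr_trialwise.values
    dor = np.where(np.abs(dor) < tol, 0.0, dor)
    dor = np.where((dor < 0) & (dor > -tol), 0.0, dor)
    return DoRMap(values=dor, condition=condition, subject_id=ssr_standard.subject_id)


def denoise(bold, confounds: Optional[np.ndarray] = None,
            outlier_flags: Optional[np.ndarray] = None) -> np.ndarray:
    """Regress confounds and flagged volumes out of every voxel.

    Confounds are (volumes x k); each flagged volume gets its own
    indicator column.  Returns the (voxels x time) residuals (the
    intercept removes each voxel's mean).
    """
    Y = np.asarray(getattr(bold, "data", bold), dtype=float)
    n_vols = Y.shape[1]
    cols = [np.ones(n_vols)]
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != n_vols:
            confounds = confounds.T
        if confounds.shape[0] != n_vols:
            raise DataError("confound rows must equal run volumes")
        cols.extend(confounds.T)
    if outlier_flags is not None:
        flags = np.asarray(outlier_flags, dtype=bool)
        if flags.shape[0] != n_vols:
            raise DataError("outlier flags must have one entry per volume")
        if flags.all():
            raise DataError("all volumes flagged as outliers")
        for idx in np.flatnonzero(flags):
            col = np.zeros(n_vols)
            col[idx] = 1.0
            cols.append(col)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return (Y.T - X @ beta).T


def mean_framewise_displacement(motion: np.ndarray, rotation_radius_mm: float = 50.0) -> float:
    """Mean FD in mm: sum of absolute backward differences of the six
    realignment parameters, rotations (radians) converted to arc length
    on a 50-mm sphere."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise DataError("motion series must be (volumes x 6): 3 translations mm, 3 rotations rad")
    if motion.shape[0] < 2:
        raise DataError("need at least two volumes for framewise displacement")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + rotation_radius_mm * d[:, 3:].sum(axis=1)
    return float(fd.mean())
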
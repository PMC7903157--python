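"""Synthetic event-related BOLD runs with known trial-by-trial variability.

The synthetic "brain" is a small labelled voxel grid with disjoint
cubic regions named for the inhibition network (right IFG pars
triangularis, caudate, putamen, thalamus, STN) plus a right calcarine
control region; there is no anatomical realism.  Every voxel's signal
is

    baseline + sum_trials amplitude * HRF(t - onset) + AR(1) noise + drift

where the per-trial amplitude is drawn Normal(condition mean,
trial_amplitude_sd of the voxel's region and condition) and shared by
all voxels of a region, so that a region's ground-truth trial
variability is exactly the configured SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import signal as spsignal

from .bold import HrfBasis, convolve_events, hrf_basis
from .exceptions import ConfigurationError, ParameterError
from .task import ParticipantSession, as_rng

INHIBITION_NETWORK = ("r_ifg", "r_caudate", "r_putamen", "r_thalamus", "r_stn")
CONTROL_REGION = "r_calcarine"

GO_SUCCESS, STOP_SUCCESS, ERROR = "go-success", "stop-success", "error"


@dataclass(frozen=True)
class RegionAtlas:
    """Named, disjoint voxel masks over a flat voxel grid."""

    shape: tuple[int, int, int]
    masks: Mapping[str, np.ndarray]  # name -> flat boolean mask

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def labels(self) -> np.ndarray:
        """Flat array of region indices (0 = background)."""
        out = np.zeros(self.n_voxels, dtype=int)
        for i, name in enumerate(self.masks, start=1):
            out[self.masks[name]] = i
        return out


def default_atlas(shape: tuple[int, int, int] = (10, 10, 10), cube: int = 3) -> RegionAtlas:
    """Six disjoint cubic regions (inhibition network + calcarine control)."""
    corners = {
        "r_ifg": (0, 0, 0),
        "r_caudate": (0, 0, 6),
        "r_putamen": (0, 6, 0),
        "r_thalamus": (6, 0, 0),
        "r_stn": (6, 6, 0),
        "r_calcarine": (6, 0, 6),
    }
    masks = {}
    for name, (i, j, k) in corners.items():
        m = np.zeros(shape, dtype=bool)
        m[i : i + cube, j : j + cube, k : k + cube] = True
        masks[name] = m.ravel()
    return RegionAtlas(shape=shape, masks=masks)


@dataclass(frozen=True)
class BoldSimSpec:
    """Generator settings for one synthetic BOLD run.

    ``trial_amplitude_sd`` maps region -> condition -> SD of the
    per-trial response amplitude (arbitrary units); unlisted pairs get
    SD 0.  ``run_duration`` of None derives the duration from the last
    event onset plus 24 s of washout.
    """

    tr: float = 2.2
    shape: tuple[int, int, int] = (10, 10, 10)
    baseline: float = 100.0
    amplitude_mean: Mapping[str, float] = field(
        default_factory=lambda: {GO_SUCCESS: 1.0, STOP_SUCCESS: 1.0, ERROR: 1.0}
    )
    trial_amplitude_sd: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.5
    ar1: float = 0.3
    drift_amplitude: float = 2.0
    motion_step_trans: float = 0.05  # mm per volume (random walk)
    motion_step_rot: float = 0.0005  # rad per volume
    run_duration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ParameterError("tr must be positive")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ParameterError("noise and drift SDs must be nonnegative")
        if not abs(self.ar1) < 1:
            raise ParameterError("|ar1| must be < 1")
        for region, conds in self.trial_amplitude_sd.items():
            if any(sd < 0 for sd in conds.values()):
                raise ParameterError(f"negative trial amplitude SD for region {region}")

    def sd_for(self, region: str, condition: str) -> float:
        return float(self.trial_amplitude_sd.get(region, {}).get(condition, 0.0))


@dataclass
class BoldRun:
    """One synthetic 4D run flattened to (voxels x volumes)."""

    data: np.ndarray
    tr: float
    events: pd.DataFrame
    motion: np.ndarray
    atlas: RegionAtlas
    subject_id: str = ""
    run: int = 0

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


def events_from_session(session: ParticipantSession, block: int) -> pd.DataFrame:
    """BIDS-style events (onset, duration, trial_type) for one block.

    Trial types: correct go responses -> "go-success", successful stops
    -> "stop-success"; failed stops, wrong-direction responses and go
    omissions are pooled as "error".  Onsets are re-zeroed to the
    block's first trial.
    """
    trials = [t for t in session.trials if t.block == block]
    if not trials:
        raise ConfigurationError(f"session has no trials in block {block}")
    t0 = trials[0].onset
    rows = []
    for t in trials:
        if t.is_correct_go:
            kind = GO_SUCCESS
        elif t.is_successful_stop:
            kind = STOP_SUCCESS
        else:
            kind = ERROR
        rows.append({"onset": t.onset - t0, "duration": 0.0, "trial_type": kind})
    return pd.DataFrame(rows)


def simulate_bold_run(
    events: pd.DataFrame,
    spec: BoldSimSpec | None = None,
    rng_seed=None,
    atlas: RegionAtlas | None = None,
    basis: HrfBasis | None = None,
) -> tuple[BoldRun, pd.DataFrame]:
    """Simulate one run; returns the run and its ground-truth amplitudes.

    The amplitude table has one row per (trial, region) with the drawn
    response amplitude; background voxels respond at the condition mean.
    """
    spec = spec or BoldSimSpec()
    atlas = atlas or default_atlas(spec.shape)
    if atlas.shape != spec.shape:
        raise ConfigurationError("atlas and spec voxel grids differ")
    rng = as_rng(rng_seed)
    basis = basis or hrf_basis(spec.tr)

    duration = spec.run_duration
    if duration is None:
        duration = float(events["onset"].max()) + 24.0
    if len(events) and float(events["onset"].max()) > duration:
        raise ConfigurationError("run duration does not cover all events")
    # tolerance guards against 299.2/2.2 -> 135.999... style float error
    n_vols = int(np.floor(duration / spec.tr + 1e-9))

    onsets = events["onset"].to_numpy(float)
    durs = events["duration"].to_numpy(float)
    conds = events["trial_type"].to_numpy()
    mean_amp = np.array([spec.amplitude_mean.get(c, 1.0) for c in conds])

    # per-region trial amplitudes (shared by all voxels of the region)
    region_names = ["background"] + list(atlas.masks)
    amp_rows = []
    region_signal = {}
    for region in region_names:
        if region == "background":
            amps = mean_amp.copy()
        else:
            sds = np.array([spec.sd_for(region, c) for c in conds])
            amps = mean_amp + rng.normal(0.0, 1.0, len(conds)) * sds
        region_signal[region] = convolve_events(
            onsets, durs, amps, n_vols, spec.tr, basis.canonical, basis.dt
        )
        for i, (onset, cond, amp) in enumerate(zip(onsets, conds, amps)):
            amp_rows.append(
                {"trial": i, "onset": onset, "trial_type": cond, "region": region,
                 "amplitude": float(amp)}
            )

    labels = atlas.labels()
    V = atlas.n_voxels
    data = np.empty((V, n_vols))
    data[:] = spec.baseline
    data[labels == 0] += region_signal["background"]
    for i, name in enumerate(atlas.masks, start=1):
        data[labels == i] += region_signal[name]

    if spec.drift_amplitude > 0:
        t = np.arange(n_vols) * spec.tr
        slope = rng.normal(0.0, spec.drift_amplitude / max(t[-1], 1.0), V)
        phase = rng.uniform(0.0, 2.0 * np.pi, V)
        period = rng.uniform(60.0, 200.0, V)
        data += slope[:, None] * t[None, :]
        data += spec.drift_amplitude * 0.5 * np.sin(
            2.0 * np.pi * t[None, :] / period[:, None] + phase[:, None]
        )

    if spec.noise_sd > 0:
        w = rng.normal(0.0, spec.noise_sd * np.sqrt(1.0 - spec.ar1**2), (V, n_vols))
        data += spsignal.lfilter([1.0], [1.0, -spec.ar1], w, axis=1)

    steps = np.column_stack(
        [rng.normal(0.0, spec.motion_step_trans, (n_vols, 3)),
         rng.normal(0.0, spec.motion_step_rot, (n_vols, 3))]
    )
    motion = np.cumsum(steps, axis=0)
    motion[0] = 0.0

    run = BoldRun(data=data, tr=spec.tr, events=events.reset_index(drop=True),
                  motion=motion, atlas=atlas)
    return run, pd.DataFrame(amp_rows)
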
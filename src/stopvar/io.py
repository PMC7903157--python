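"""Reading and writing of the package's tabular and imaging formats.

Sessions and ground truth are TSV (one row per trial / per subject);
events follow the BIDS events convention (onset, duration, trial_type);
motion is a header-less 6-column TSV (3 translations in mm, 3 rotations
in rad); volumetric maps are NIfTI-1 via nibabel.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import DataError
from .task import ParticipantSession, TaskDesign, TrialRecord

SESSION_COLUMNS = [
    "subject_id", "group", "index", "block", "kind", "direction",
    "ssd", "response", "rt", "onset",
]


def sessions_to_frame(sessions: Sequence[ParticipantSession]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "index": t.index,
                    "block": t.block,
                    "kind": t.kind,
                    "direction": t.direction,
                    "ssd": t.ssd if t.ssd is not None else np.nan,
                    "response": t.response,
                    "rt": t.rt if t.rt is not None else np.nan,
                    "onset": t.onset,
                }
            )
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def write_sessions_tsv(sessions: Sequence[ParticipantSession], path) -> None:
    sessions_to_frame(sessions).to_csv(path, sep="\t", index=False)


def read_sessions_tsv(path, design: TaskDesign | None = None) -> list[ParticipantSession]:
    df = pd.read_csv(path, sep="\t")
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"session table lacks columns {sorted(missing)}")
    design = design or TaskDesign()
    sessions = []
    for (sid, group), sub in df.groupby(["subject_id", "group"], sort=False):
        trials = []
        for _, row in sub.sort_values("index").iterrows():
            trials.append(
                TrialRecord(
                    index=int(row["index"]),
                    block=int(row["block"]),
                    kind=row["kind"],
                    direction=row["direction"],
                    ssd=None if pd.isna(row["ssd"]) else float(row["ssd"]),
                    response=row["response"],
                    rt=None if pd.isna(row["rt"]) else float(row["rt"]),
                    onset=None if pd.isna(row["onset"]) else float(row["onset"]),
                )
            )
        sessions.append(
            ParticipantSession(subject_id=str(sid), group=str(group), design=design, trials=trials)
        )
    return sessions


def write_events_tsv(events: pd.DataFrame, path) -> None:
    events[["onset", "duration", "trial_type"]].to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"onset", "duration", "trial_type"} <= set(df.columns):
        raise DataError("events TSV needs onset, duration, trial_type columns")
    return df


def write_motion_tsv(motion: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(motion, dtype=float), delimiter="\t", fmt="%.8g")


def read_motion_tsv(path) -> np.ndarray:
    motion = np.loadtxt(path, delimiter="\t", ndmin=2)
    if motion.shape[1] != 6:
        raise DataError(f"motion TSV must have 6 columns, found {motion.shape[1]}")
    return motion


def default_affine(voxel_size_mm: float = 3.0) -> np.ndarray:
    aff = np.eye(4) * voxel_size_mm
    aff[3, 3] = 1.0
    return aff


def save_map_nifti(values: np.ndarray, shape, path, affine: np.ndarray | None = None) -> None:
    """Save a flat voxel map (or voxels x k stack) as a NIfTI-1 image."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim == 1:
        img_data = values.reshape(shape)
    else:
        img_data = values.reshape(*shape, values.shape[1])
    nib.save(nib.Nifti1Image(img_data, affine if affine is not None else default_affine()), str(path))


def load_map_nifti(path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        return data.ravel()
    return data.reshape(-1, data.shape[-1])


def save_bold_nifti(data: np.ndarray, shape, tr: float, path) -> None:
    """Save a (voxels x volumes) run as 4D NIfTI with the TR in the header."""
    data = np.asarray(data, dtype=np.float32)
    img = nib.Nifti1Image(data.reshape(*shape, data.shape[1]), default_affine())
    img.header.set_zooms((3.0, 3.0, 3.0, float(tr)))
    nib.save(img, str(path))


def load_bold_nifti(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DataError("expected a 4D BOLD image")
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    return data.reshape(-1, data.shape[-1]), tr
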
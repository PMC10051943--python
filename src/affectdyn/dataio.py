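"""CSV/JSON interchange for trajectories, ratings and fitted descriptors.

Trajectory CSV dialect: columns ``subject_id, rater_id, t, valence,
arousal``, one row per sample; the fused consensus trajectory uses
``rater_id = "EWE"``.  Ratings CSV: ``subject_id, rater_id, trait, rating``
with integer ratings 1-7.  Note the CSV column order is (valence, arousal)
while in-memory arrays are (arousal, valence).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .ou import Trajectory

__all__ = [
    "trajectory_to_frame",
    "trajectories_from_frame",
    "read_trajectories",
    "write_trajectories",
    "read_ratings",
    "write_ratings",
    "write_descriptors",
    "read_descriptors",
]

_TRAJ_COLS = ["subject_id", "rater_id", "t", "valence", "arousal"]


def trajectory_to_frame(traj, subject_id, rater_id) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "rater_id": rater_id,
            "t": traj.t,
            "valence": traj.valence,
            "arousal": traj.arousal,
        }
    )


def trajectories_from_frame(df) -> dict:
    """Nested dict subject_id -> rater_id -> Trajectory from a long frame."""
    out = {}
    for (sid, rid), grp in df.groupby(["subject_id", "rater_id"], sort=True):
        grp = grp.sort_values("t")
        out.setdefault(sid, {})[rid] = Trajectory(
            t=grp["t"].to_numpy(),
            y=np.column_stack([grp["arousal"].to_numpy(), grp["valence"].to_numpy()]),
        )
    return out


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _TRAJ_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {missing}")
    return df


def write_trajectories(df, path):
    df.to_csv(path, index=False, columns=_TRAJ_COLS)


def read_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ["subject_id", "rater_id", "trait", "rating"] if c not in df.columns]
    if missing:
        raise ValueError(f"ratings CSV missing columns: {missing}")
    bad = ~df["rating"].between(1, 7)
    if bad.any():
        raise ValueError("ratings outside the 1-7 scale")
    return df


def write_ratings(df, path):
    df.to_csv(path, index=False, columns=["subject_id", "rater_id", "trait", "rating"])


def write_descriptors(results_by_subject, path):
    """Posterior summaries and descriptors, JSON keyed by subject id."""
    out = {}
    for sid, res in results_by_subject.items():
        summ = res.summary()
        out[sid] = {
            "descriptor": res.descriptor().tolist(),
            "summary": {
                name: {k: float(v) for k, v in row.items()}
                for name, row in summ.iterrows()
            },
            "diagnostics": {
                k: v for k, v in res.diagnostics.items() if np.isscalar(v) or isinstance(v, (bool, str))
            },
        }
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)


def read_descriptors(path) -> dict:
    """subject_id -> 8-vector descriptor from a descriptors JSON."""
    with open(path) as fh:
        data = json.load(fh)
    return {sid: np.asarray(rec["descriptor"], float) for sid, rec in data.items()}
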
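"""CSV interchange for marker coordinates, trial metadata, morphometrics
and kinematics tables.

Marker-coordinate files are flat CSV with header
``frame,t_s,m01_x,m01_y,m01_z,...,m10_z`` (units cm, frame 0-based),
matching the column-per-coordinate layout that 3-D point digitizers export.
Missing values are written as empty fields and parsed back as NaN ("" is
the explicit missing token); floats round-trip bit-exactly via shortest
repr.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kinextract import TrialKinematics
from .smoothing import MarkerTrackSet, TrialMeta

__all__ = [
    "write_marker_tracks",
    "read_marker_tracks",
    "read_trial_metadata",
    "write_kinematics_table",
    "read_kinematics_table",
    "read_morphometrics",
]

METADATA_COLUMNS = [
    "trial_id", "individual_id", "sex", "age_class", "temperature_C",
    "handedness", "frame_rate_hz", "representative", "coord_file",
]


def _marker_columns(n_markers: int) -> list[str]:
    return [f"m{m:02d}_{ax}" for m in range(1, n_markers + 1)
            for ax in "xyz"]


def write_marker_tracks(tracks: MarkerTrackSet, path: str | Path) -> None:
    n_frames, n_markers, _ = tracks.positions.shape
    cols = _marker_columns(n_markers)
    flat = tracks.positions.reshape(n_frames, n_markers * 3)
    df = pd.DataFrame(flat, columns=cols)
    df.insert(0, "t_s", np.arange(n_frames) / tracks.frame_rate_hz)
    df.insert(0, "frame", np.arange(n_frames))
    # %.17g guarantees bit-exact float64 round-trips
    df.to_csv(path, index=False, float_format="%.17g")


def read_marker_tracks(path: str | Path,
                       meta: TrialMeta | None = None) -> MarkerTrackSet:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "frame" not in df.columns or "t_s" not in df.columns:
        raise ValueError(
            f"{path}: malformed header, missing 'frame'/'t_s' columns")
    mcols = [c for c in df.columns if c.startswith("m") and "_" in c]
    n_markers = len(mcols) // 3
    expected = _marker_columns(n_markers)
    missing = [c for c in expected if c not in df.columns]
    if missing or len(mcols) != 3 * n_markers:
        raise ValueError(f"{path}: missing marker columns {missing}")
    t = df["t_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 frames")
    frame_rate = 1.0 / float(np.median(np.diff(t)))
    pos = df[expected].to_numpy(float).reshape(len(df), n_markers, 3)
    if meta is None:
        meta = TrialMeta(trial_id=path.stem)
    return MarkerTrackSet(positions=pos, frame_rate_hz=frame_rate, meta=meta)


def read_trial_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    return df


def read_morphometrics(path: str | Path) -> pd.DataFrame:
    from .synthgen import MORPHO_COLUMNS

    df = pd.read_csv(path)
    missing = [c for c in MORPHO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: morphometrics missing columns {missing}")
    return df


def write_kinematics_table(rows: dict[str, TrialKinematics],
                           path: str | Path) -> None:
    """One row per trial; missing values are written as empty fields."""
    recs = []
    for trial_id, kin in rows.items():
        rec = {"trial_id": trial_id}
        for f in TrialKinematics.FIELDS:
            v = getattr(kin, f)
            if isinstance(v, float) and not np.isfinite(v):
                v = np.nan
            rec[f] = v
        recs.append(rec)
    pd.DataFrame(recs, columns=["trial_id", *TrialKinematics.FIELDS]).to_csv(
        path, index=False)


def read_kinematics_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("trial_id", *TrialKinematics.FIELDS)
               if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: kinematics table missing columns {missing}")
    return df
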
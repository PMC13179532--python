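"""Per-trial feature extraction from OpenFace-dialect frame tables.

The analysis uses a single frame per trial, 2 s after stimulus onset (the
group-level head-turn timecourse peaks 2-3 s post onset), reduced to one of
four 2-D feature sets:

* ``head_rot``   — head yaw and pitch (rad);
* ``gaze_left``  — left-eye gaze direction, world x (left/right) and y (up/down);
* ``gaze_angle`` — gaze angles averaged over both eyes, horizontal and vertical;
* ``pca2``       — the first two principal components of all 55 features,
  z-scored and fitted on the training split only.

A trial with no frame within the matching tolerance of onset + 2 s is marked
invalid and excluded (``valid=False`` is a value, not an error).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import (
    FEATURE_COLUMNS,
    FRAME_COLUMNS,
    STIMULUS_LOG_COLUMNS,
    TrialRecord,
)

FEATURE_SETS = ("head_rot", "gaze_left", "gaze_angle", "pca2")

_IDX = {c: i for i, c in enumerate(FEATURE_COLUMNS)}
#: (axis1, axis2) feature indices for the three direct projections; axis 1 is
#: the left/right-encoding coordinate in each case.
FEATURE_SET_INDICES = {
    "head_rot": (_IDX["pose_Ry"], _IDX["pose_Rx"]),
    "gaze_left": (_IDX["gaze_0_x"], _IDX["gaze_0_y"]),
    "gaze_angle": (_IDX["gaze_angle_x"], _IDX["gaze_angle_y"]),
}


class FormatError(ValueError):
    """A feature or stimulus-log CSV does not match the expected dialect."""


@dataclass
class TrialFeatureVector:
    """The 55 features of one trial's analysis frame (or invalid)."""

    trial: TrialRecord
    values: np.ndarray | None   # shape (55,), ordered as FEATURE_COLUMNS
    valid: bool


@dataclass
class PcaProjection:
    """Standardising 2-component PCA fitted on training trials."""

    center: np.ndarray    # (55,)
    scale: np.ndarray     # (55,)
    loadings: np.ndarray  # (2, 55), orthonormal rows

    def transform(self, values: np.ndarray) -> np.ndarray:
        z = (np.asarray(values, float) - self.center) / self.scale
        return z @ self.loadings.T


def read_stimulus_log(path) -> list[TrialRecord]:
    df = pd.read_csv(path)
    missing = [c for c in STIMULUS_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"stimulus log {path} missing column(s): "
                          f"{', '.join(missing)}")
    return [TrialRecord(str(r.participant_id), str(r.group), int(r.trial_index),
                        str(r.stimulus), str(r.side), float(r.onset_time_s))
            for r in df.itertuples(index=False)]


def read_feature_table(path, flip_yaw: bool = False) -> pd.DataFrame:
    """Read one participant's OpenFace-dialect frame table.

    Malformed (non-numeric / missing-value) rows are dropped with a warning
    naming their line numbers.  ``flip_yaw`` negates ``pose_Ry`` and the
    horizontal gaze coordinates for mirrored camera conventions.
    """
    df = pd.read_csv(path, skipinitialspace=True)
    missing = [c for c in FRAME_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"feature table {path} missing column(s): "
                          f"{', '.join(missing)}")
    df = df[list(FRAME_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = df.isna().any(axis=1)
    if bad.any():
        lines = [str(i + 2) for i in df.index[bad]]  # +2: header + 1-based
        warnings.warn(f"{path}: dropped {bad.sum()} malformed row(s) at "
                      f"line(s) {', '.join(lines[:10])}"
                      + ("..." if len(lines) > 10 else ""))
        df = df[~bad]
    if flip_yaw:
        for c in ("pose_Ry", "gaze_angle_x", "gaze_0_x", "gaze_1_x"):
            df[c] = -df[c]
    return df.sort_values("timestamp", kind="stable").reset_index(drop=True)


def read_session(features, stimulus_csv, flip_yaw: bool = False
                 ) -> tuple[dict[str, pd.DataFrame], list[TrialRecord]]:
    """Read a session: feature tables plus the stimulus log.

    ``features`` may be a directory containing ``<pid>_features.csv`` files,
    a mapping ``{pid: path}``, or a single path (participant id taken from
    the file name stem).
    """
    schedule = read_stimulus_log(stimulus_csv)
    if isinstance(features, (str, Path)) and Path(features).is_dir():
        paths = {p.name[:-len("_features.csv")]: p
                 for p in sorted(Path(features).glob("*_features.csv"))}
    elif isinstance(features, dict):
        paths = features
    else:
        p = Path(features)
        paths = {p.stem.replace("_features", ""): p}
    frames = {pid: read_feature_table(p, flip_yaw=flip_yaw)
              for pid, p in paths.items()}
    return frames, schedule


def extract_trial_vector(frames: pd.DataFrame, trial: TrialRecord,
                         offset_s: float = 2.0,
                         tol_s: float | None = None) -> TrialFeatureVector:
    """Pick the frame nearest ``onset + offset_s``.

    ``tol_s`` defaults to half the median frame interval; if no frame lies
    within it the trial is invalid.  Equidistant frames resolve to the
    earlier one.
    """
    ts = frames["timestamp"].to_numpy(float)
    if len(ts) == 0:
        return TrialFeatureVector(trial, None, False)
    if tol_s is None:
        tol_s = (float(np.median(np.diff(ts))) / 2.0) if len(ts) > 1 else 0.5
    target = trial.onset_time_s + offset_s
    d = np.abs(ts - target)
    i = int(np.argmin(d))  # first minimum -> earlier frame on ties
    if d[i] > tol_s + 1e-12:
        return TrialFeatureVector(trial, None, False)
    vals = frames.iloc[i][list(FEATURE_COLUMNS)].to_numpy(float)
    return TrialFeatureVector(trial, vals, True)


def extract_all(frames_by_pid: dict[str, pd.DataFrame],
                schedule: list[TrialRecord], offset_s: float = 2.0,
                tol_s: float | None = None) -> list[TrialFeatureVector]:
    out = []
    for trial in schedule:
        fr = frames_by_pid.get(trial.participant_id)
        if fr is None:
            out.append(TrialFeatureVector(trial, None, False))
        else:
            out.append(extract_trial_vector(fr, trial, offset_s, tol_s))
    return out


def vectors_to_frame(vectors: list[TrialFeatureVector]) -> pd.DataFrame:
    """Per-trial feature CSV layout: ids, side, valid flag, f1..f55."""
    rows = []
    for v in vectors:
        t = v.trial
        vals = ([np.nan] * 55) if not v.valid else list(v.values)
        rows.append([t.participant_id, t.group, t.trial_index, t.stimulus,
                     t.side, t.onset_time_s, v.valid] + vals)
    cols = ["participant_id", "group", "trial_index", "stimulus", "side",
            "onset_time_s", "valid"] + [f"f{i + 1}" for i in range(55)]
    return pd.DataFrame(rows, columns=cols)


def select_features(vector: TrialFeatureVector | np.ndarray, feature_set: str,
                    pca: PcaProjection | None = None) -> np.ndarray:
    """Project a valid 55-feature vector to the requested 2-D feature set."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    if isinstance(vector, TrialFeatureVector):
        if not vector.valid:
            raise ValueError("cannot project an invalid trial vector")
        values = vector.values
    else:
        values = np.asarray(vector, float)
    if feature_set == "pca2":
        if pca is None:
            raise ValueError("pca2 requires a fitted PcaProjection")
        return pca.transform(values)
    i, j = FEATURE_SET_INDICES[feature_set]
    return np.array([values[i], values[j]], float)


def select_features_matrix(vectors, feature_set: str,
                           pca: PcaProjection | None = None) -> np.ndarray:
    rows = [v.values if isinstance(v, TrialFeatureVector) else v for v in vectors]
    X = np.asarray(rows, float)
    if feature_set == "pca2":
        if pca is None:
            raise ValueError("pca2 requires a fitted PcaProjection")
        return pca.transform(X)
    i, j = FEATURE_SET_INDICES[feature_set]
    return X[:, [i, j]]


def fit_pca(training_vectors, standardize: bool = True) -> PcaProjection:
    """Fit the top-2 principal axes of the (z-scored) training matrix.

    The 55 features mix radians, millimetres and AU units, so features are
    z-scored by default before the decomposition.  A constant feature gets
    scale 1 with a warning.  Component signs are fixed so each loading row's
    largest-magnitude entry is positive.
    """
    X = np.asarray([v.values if isinstance(v, TrialFeatureVector) else v
                    for v in training_vectors], float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("fit_pca needs at least 3 valid training vectors")
    center = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0, ddof=0)
        const = scale <= 1e-12
        if const.any():
            warnings.warn(f"{int(const.sum())} constant feature(s); scale set to 1")
            scale = np.where(const, 1.0, scale)
    else:
        scale = np.ones(X.shape[1])
    Z = (X - center) / scale
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt[:2].copy()
    for r in range(2):
        if loadings[r, np.argmax(np.abs(loadings[r]))] < 0:
            loadings[r] = -loadings[r]
    return PcaProjection(center=center, scale=scale, loadings=loadings)


def mean_abs_yaw_timecourse(frames_by_pid: dict[str, pd.DataFrame],
                            schedule: list[TrialRecord],
                            window: tuple[float, float] = (-1.0, 5.0),
                            bin_s: float = 0.1) -> pd.DataFrame:
    """Group-mean absolute head yaw versus time from stimulus onset.

    For each trial, frames within ``window`` of its onset are binned by
    time-from-onset; the curve is the per-bin mean of |yaw| across all the
    group's trials.  Returns columns ``group, t, mean_abs_yaw, n_frames``
    (empty bins are absent, i.e. marked missing).
    """
    if not schedule:
        raise ValueError("need at least one trial")
    recs = []
    for trial in schedule:
        fr = frames_by_pid.get(trial.participant_id)
        if fr is None:
            continue
        t_rel = fr["timestamp"].to_numpy(float) - trial.onset_time_s
        m = (t_rel >= window[0] - 1e-9) & (t_rel <= window[1] + 1e-9)
        if not m.any():
            continue
        b = np.floor((t_rel[m] - window[0]) / bin_s).astype(int)
        recs.append(pd.DataFrame({
            "group": trial.group,
            "t": window[0] + (b + 0.5) * bin_s,
            "abs_yaw": np.abs(fr["pose_Ry"].to_numpy(float)[m]),
        }))
    if not recs:
        raise ValueError("no frames fall inside the analysis window")
    df = pd.concat(recs, ignore_index=True)
    out = (df.groupby(["group", "t"], as_index=False)
             .agg(mean_abs_yaw=("abs_yaw", "mean"), n_frames=("abs_yaw", "size")))
    return out.sort_values(["group", "t"]).reset_index(drop=True)
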
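"""Synthetic behavioural test sessions in the OpenFace per-frame feature dialect.

Emulates a sound-field lateralization session: a seated infant or toddler is
presented warble tones (0.5/1/2 kHz carriers) and single-syllable utterances
("ba", "da") from a speaker 45 degrees to the left or right, while a camera
facing the child records head pose, eye gaze and facial action-unit (AU)
activations.  The generator produces per-frame feature tables (55 scalar
features per frame: 35 AUs, 8 gaze, 6 head pose, 6 head-shape parameters)
plus a stimulus log, with the statistical structure the downstream clustering
analysis assumes:

* each participant receives 10 trials — the five stimulus types twice each in
  randomised order, side drawn per trial, inter-stimulus interval >= 6 s;
* a minority of trials carry an overt response: a smooth unimodal head-yaw
  excursion toward (usually) the presentation side, peaking 2-3 s after
  stimulus onset, with horizontal gaze correlated with the head turn;
* resting head yaw sits ~10 degrees off-centre on average (random side);
* occasionally the frame nearest 2 s post onset is missing.

Sign convention: positive yaw means the head is turned toward the RIGHT
speaker from the child's perspective.  Readers accept a ``flip_yaw`` switch
for mirrored camera-frame data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STIMULI = ("warble500", "warble1000", "warble2000", "ba", "da")
GROUPS = ("infant", "toddler")
SIDES = ("left", "right")

# AU activation columns: 35 channels (numbers 1-34 plus 45, "_r" = regression
# output, dimensionless activation >= 0).
AU_NUMBERS = tuple(range(1, 35)) + (45,)
AU_COLUMNS = tuple(f"AU{n:02d}_r" for n in AU_NUMBERS)

GAZE_COLUMNS = (
    "gaze_0_x", "gaze_0_y", "gaze_0_z",
    "gaze_1_x", "gaze_1_y", "gaze_1_z",
    "gaze_angle_x", "gaze_angle_y",
)
POSE_COLUMNS = ("pose_Tx", "pose_Ty", "pose_Tz", "pose_Rx", "pose_Ry", "pose_Rz")
SHAPE_COLUMNS = ("p_scale", "p_rx", "p_ry", "p_rz", "p_tx", "p_ty")

#: Canonical ordering of the 55 scalar features used everywhere downstream.
FEATURE_COLUMNS = GAZE_COLUMNS + POSE_COLUMNS + SHAPE_COLUMNS + AU_COLUMNS
assert len(FEATURE_COLUMNS) == 55

#: Full per-frame CSV header (bookkeeping columns + the 55 features).
FRAME_COLUMNS = ("frame", "timestamp", "success") + FEATURE_COLUMNS

STIMULUS_LOG_COLUMNS = (
    "participant_id", "group", "trial_index", "stimulus", "side", "onset_time_s"
)

# Fixed resting-state AU activation profile (dimensionless, arbitrary but
# deterministic; no stimulus coupling unless facial_reaction is enabled).
_AU_BASE = 0.2 + 0.8 * (1.0 + np.sin(0.7 * np.arange(len(AU_COLUMNS)))) / 2.0
# AUs receiving a stimulus-locked bump in facial-reaction mode (brow raiser,
# upper-lid raiser, jaw drop, blink — indices into AU_COLUMNS).
_REACTIVE_AU_IDX = (1, 3, 25, 34)


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus presentation."""

    participant_id: str
    group: str                  # "infant" | "toddler"
    trial_index: int            # 0-based within participant
    stimulus: str               # one of STIMULI
    side: str                   # "left" | "right" (speaker used)
    onset_time_s: float         # seconds from session start


@dataclass
class ResponseModelParams:
    """Parameters of the per-trial behavioural response model.

    ``peak_yaw_rad`` is the mean peak absolute yaw of a *responding* trial
    (radians): the head turns from its resting angle to ~that angle toward
    the responded side.  ``baseline_yaw_rad`` is the mean absolute resting
    off-centre yaw.  Group defaults follow the observed timecourses: toddler
    responses peak at ~17 deg (0.30 rad), infant at ~12 deg (0.21 rad), both
    around 2-3 s post onset, from a ~10 deg off-centre baseline.
    """

    responder_prob: float = 0.25
    correct_side_prob: float = 0.8
    peak_yaw_rad: float = 0.30
    latency_peak_s: float = 2.5
    latency_jitter_sd: float = 0.3      # s, per-trial peak-time spread (clipped 1.5-4.0 s)
    baseline_yaw_rad: float = math.radians(10.0)
    gaze_head_corr: float = 0.8
    noise_sd: float = 0.02
    missing_frame_prob: float = 20.0 / 580.0
    frame_rate_hz: float = 30.0
    # secondary kinematic knobs
    amp_jitter_frac: float = 0.2        # per-trial amplitude CV (clipped x0.4-1.6)
    response_support_s: float = 2.7     # total turn duration (turn+hold+return)
    response_edge_s: float = 0.3        # rise/fall time of the turn
    gaze_angle_y_sd: float = 0.10       # rad
    facial_reaction: bool = False       # stimulus-locked AU bumps for responders

    @classmethod
    def for_group(cls, group: str, **overrides) -> "ResponseModelParams":
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        base = cls() if group == "toddler" else cls(
            peak_yaw_rad=0.21, correct_side_prob=0.65)
        return replace(base, **overrides)

    def validate(self) -> None:
        for name in ("responder_prob", "correct_side_prob", "gaze_head_corr",
                     "missing_frame_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.peak_yaw_rad < 0:
            raise ValueError("peak_yaw_rad must be >= 0")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def schedule_stimuli(participant_id: str, group: str, seed) -> list[TrialRecord]:
    """Build one participant's 10-trial schedule.

    Each of the five stimulus types appears exactly twice, in randomised
    order; the speaker side is drawn independently per trial; successive
    onsets are separated by at least 6 s (6 s + exponential slack, emulating
    the assistant re-centring the child between presentations).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rng = _rng(seed)
    stims = list(STIMULI) * 2
    order = rng.permutation(len(stims))
    onset = float(rng.uniform(2.0, 4.0))
    trials = []
    for i, j in enumerate(order):
        side = SIDES[int(rng.integers(2))]
        trials.append(TrialRecord(
            participant_id=participant_id, group=group, trial_index=i,
            stimulus=stims[j], side=side, onset_time_s=round(onset, 6)))
        onset += 6.0 + float(rng.exponential(4.0))
    return trials


def response_envelope(t_rel: np.ndarray, centre_s: float,
                      support_s: float = 2.7, edge_s: float = 0.3) -> np.ndarray:
    """Turn-and-hold response envelope in [0, 1] (Tukey window).

    An individual overt response is a quick head turn toward the speaker, a
    hold on the target, and a return to rest: the envelope rises from 0 to 1
    over ``edge_s``, holds at 1, and falls back, with total support
    ``support_s`` centred on ``centre_s``.  Averaged over the per-trial
    latency spread this produces the smooth unimodal group timecourse peaking
    2-3 s after onset.
    """
    half = support_s / 2.0
    d = np.abs(np.asarray(t_rel, float) - centre_s)
    w = np.zeros_like(d)
    w[d <= half - edge_s] = 1.0
    e = (d > half - edge_s) & (d < half)
    w[e] = 0.5 * (1.0 + np.cos(np.pi * (d[e] - (half - edge_s)) / edge_s))
    return w


def _unit_gaze(ax: np.ndarray, ay: np.ndarray) -> np.ndarray:
    """World-coordinate unit gaze vectors from horizontal/vertical angles."""
    x = np.sin(ax)
    y = np.sin(ay)
    z = -np.sqrt(np.clip(1.0 - x * x - y * y, 1e-12, None))
    v = np.stack([x, y, z], axis=1)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def simulate_trial_frames(trial: TrialRecord, params: ResponseModelParams,
                          seed) -> pd.DataFrame:
    """Simulate the per-frame feature table for one trial.

    Returns a DataFrame with ``FRAME_COLUMNS`` covering
    [onset - 1 s, onset + 5 s] at ``frame_rate_hz``.  With probability
    ``responder_prob`` the trial carries a response: yaw is blended from the
    resting angle toward ``sign x amplitude`` under a raised-cosine envelope
    (sign toward the responded side, which matches the speaker side with
    probability ``correct_side_prob``).  With probability
    ``missing_frame_prob`` the frame nearest onset + 2 s is dropped.
    """
    params.validate()
    rng = _rng(seed)
    dt = 1.0 / params.frame_rate_hz
    n = int(round(6.0 * params.frame_rate_hz)) + 1
    t_rel = -1.0 + dt * np.arange(n)
    ts = trial.onset_time_s + t_rel

    responder = rng.random() < params.responder_prob
    correct = rng.random() < params.correct_side_prob
    resp_side = trial.side if correct else ("left" if trial.side == "right" else "right")
    sign = 1.0 if resp_side == "right" else -1.0

    # resting yaw: zero-mean (child centred on the screen) with mean
    # absolute value baseline_yaw_rad
    baseline = rng.normal(0.0, params.baseline_yaw_rad * math.sqrt(math.pi / 2.0))
    amp = 0.0
    w = np.zeros(n)
    if responder:
        amp = params.peak_yaw_rad * float(
            np.clip(rng.normal(1.0, params.amp_jitter_frac), 0.4, 1.6))
        latency = float(np.clip(
            rng.normal(params.latency_peak_s, params.latency_jitter_sd), 1.5, 4.0))
        w = response_envelope(t_rel, latency, params.response_support_s,
                              params.response_edge_s)

    yaw = baseline * (1.0 - w) + sign * amp * w + rng.normal(0, params.noise_sd, n)
    pitch = rng.normal(0.0, 0.05) + rng.normal(0, params.noise_sd, n)
    roll = rng.normal(0.0, 0.03) + rng.normal(0, params.noise_sd, n)

    rho = params.gaze_head_corr
    gaze_x = rho * yaw + math.sqrt(1.0 - rho * rho) * rng.normal(
        0, params.baseline_yaw_rad, n)
    gaze_y = rng.normal(0.0, params.gaze_angle_y_sd) + rng.normal(
        0, params.gaze_angle_y_sd / 2.0, n)

    df = pd.DataFrame(index=np.arange(n), columns=list(FRAME_COLUMNS), dtype=float)
    df["frame"] = np.arange(1, n + 1)
    df["timestamp"] = ts
    df["success"] = 1.0
    for eye in (0, 1):
        jx = rng.normal(0, 0.01, n)
        jy = rng.normal(0, 0.01, n)
        v = _unit_gaze(gaze_x + jx, gaze_y + jy)
        df[f"gaze_{eye}_x"], df[f"gaze_{eye}_y"], df[f"gaze_{eye}_z"] = v.T
    df["gaze_angle_x"] = gaze_x
    df["gaze_angle_y"] = gaze_y
    df["pose_Tx"] = rng.normal(0.0, 5.0, n)
    df["pose_Ty"] = rng.normal(0.0, 5.0, n)
    df["pose_Tz"] = rng.normal(600.0, 10.0, n)
    df["pose_Rx"] = pitch
    df["pose_Ry"] = yaw
    df["pose_Rz"] = roll
    df["p_scale"] = rng.normal(1.0, 0.01, n)
    for c in SHAPE_COLUMNS[1:]:
        df[c] = rng.normal(0.0, 0.05, n)
    au = np.clip(_AU_BASE[None, :] + rng.normal(0, 0.15, (n, len(AU_COLUMNS))), 0, None)
    if params.facial_reaction and responder:
        au[:, list(_REACTIVE_AU_IDX)] += 0.5 * w[:, None]
    df[list(AU_COLUMNS)] = au

    if rng.random() < params.missing_frame_prob:
        drop = int(np.argmin(np.abs(t_rel - 2.0)))
        df = df.drop(index=drop).reset_index(drop=True)
    return df


def simulate_participant(participant_id: str, group: str,
                         params: ResponseModelParams | None, seed
                         ) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Schedule and simulate all 10 trials of one participant.

    Returns the schedule and a single frame table (all trials concatenated,
    sorted by timestamp, frames renumbered from 1).
    """
    rng = _rng(seed)
    if params is None:
        params = ResponseModelParams.for_group(group)
    schedule = schedule_stimuli(participant_id, group, rng)
    parts = [simulate_trial_frames(t, params, rng) for t in schedule]
    frames = pd.concat(parts, ignore_index=True)
    frames = frames.sort_values("timestamp", kind="stable").reset_index(drop=True)
    frames["frame"] = np.arange(1, len(frames) + 1, dtype=float)
    return schedule, frames


def simulate_cohort(n_infants: int, n_toddlers: int, seed,
                    params_by_group: dict[str, ResponseModelParams] | None = None,
                    ) -> tuple[list[TrialRecord], dict[str, pd.DataFrame]]:
    """Simulate a full cohort; returns (all trials, frames per participant)."""
    ss = np.random.SeedSequence(seed)
    kids = ([("infant", f"I{i + 1:02d}") for i in range(n_infants)]
            + [("toddler", f"T{i + 1:02d}") for i in range(n_toddlers)])
    schedule: list[TrialRecord] = []
    frames: dict[str, pd.DataFrame] = {}
    for child_ss, (group, pid) in zip(ss.spawn(len(kids)), kids):
        p = None if params_by_group is None else params_by_group.get(group)
        sched, fr = simulate_participant(pid, group, p, np.random.default_rng(child_ss))
        schedule.extend(sched)
        frames[pid] = fr
    return schedule, frames


def schedule_to_frame(schedule: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.participant_id, t.group, t.trial_index, t.stimulus, t.side,
          t.onset_time_s) for t in schedule],
        columns=list(STIMULUS_LOG_COLUMNS))


def write_session(schedule: list[TrialRecord], frames: dict[str, pd.DataFrame],
                  out_dir) -> dict:
    """Write one feature CSV per participant plus the stimulus log.

    Feature files are named ``<participant_id>_features.csv`` and round-trip
    losslessly through :func:`soundturn.features.read_session`.
    Returns ``{"stimulus_log": path, "features": {pid: path}}``.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "stimulus_log.csv"
    schedule_to_frame(schedule).to_csv(log_path, index=False)
    paths = {}
    for pid, df in frames.items():
        p = out / f"{pid}_features.csv"
        df.to_csv(p, index=False)
        paths[pid] = p
    return {"stimulus_log": log_path, "features": paths}
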
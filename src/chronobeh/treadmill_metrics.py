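"""Segmentation and scoring of the 7 s front-back-front treadmill sequence.

Each trial's position trace (cm from the front wall, 100 samples/s) is
aligned to the goal-zone entrance, segmented into transport / hold /
acceleration phases, and scored for duration, peak speed, rear-most reach
and compensation strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import TREADMILL_FS, GOAL_ZONE_CM, GOAL_TIME_S
from .sessions import pixels_to_cm  # re-exported convenience

#: |ground velocity| below this is "holding position" (cm/s)
HOLD_TOLERANCE_CM_S = 3.0
#: positions beyond this count as the rear zone (cm)
REAR_ZONE_CM = 60.0
#: velocity smoothing window (s): centered difference + box smoothing
VELOCITY_SMOOTH_S = 0.05


@dataclass
class TreadmillTrial:
    """One segmented and scored treadmill trial."""

    belt_speed: float
    duration: float
    correct: bool
    entrance_time: float
    phases: dict
    peak_speed: float
    min_rear_position: float
    hold_duration: float
    strategy: Optional[str] = None
    quality_ok: bool = True
    aligned_times: Optional[np.ndarray] = None
    aligned_position: Optional[np.ndarray] = None


def velocity(times, position, smooth_s: float = VELOCITY_SMOOTH_S):
    """Ground-frame velocity (cm/s) by centered differences with box
    smoothing of the stated width."""
    times = np.asarray(times, float)
    position = np.asarray(position, float)
    v = np.gradient(position, times)
    w = max(int(round(smooth_s * TREADMILL_FS)), 1)
    if w > 1:
        kernel = np.ones(w) / w
        v = np.convolve(v, kernel, mode="same")
    return v


def find_entrance(times, position, goal_zone_cm: float = GOAL_ZONE_CM) -> float:
    """First time the animal re-enters the goal zone (position <= 10 cm)
    after having clearly left it."""
    times = np.asarray(times, float)
    position = np.asarray(position, float)
    left_zone = position > goal_zone_cm + 1.0
    if not left_zone.any():
        raise ValueError("trial never leaves the goal zone")
    i0 = int(np.argmax(left_zone))
    below = position[i0:] <= goal_zone_cm
    if not below.any():
        raise ValueError("no goal-zone entrance in trial")
    i = i0 + int(np.argmax(below))
    if i == 0:
        return float(times[0])
    # linear interpolation of the crossing
    t0, t1 = times[i - 1], times[i]
    y0, y1 = position[i - 1], position[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (y0 - goal_zone_cm) * (t1 - t0) / (y0 - y1))


def align_and_duration(trial, goal_time_s: float = GOAL_TIME_S):
    """Re-reference a raw trial to its goal entrance.

    Returns ``(aligned_times, duration_s, correct)`` with t = 0 at the
    entrance; ``correct`` iff duration >= the 7 s goal time.
    """
    entrance = find_entrance(trial.sample_times, trial.position)
    duration = entrance - trial.trial_start
    aligned = trial.sample_times - entrance
    return aligned, float(duration), bool(duration >= goal_time_s)


def segment_phases(times, position, belt_speed: float) -> dict:
    """Split [start, entrance] into transport / hold / acceleration spans.

    The rear plateau (rear-most reach) anchors the boundaries: transport
    ends at the first arrival within a noise-scaled band of the plateau,
    the final acceleration starts at the last departure from that band,
    and the hold phase is the span between.  Ground velocity (centered
    difference, 50 ms box smoothing) is used for quality control: traces
    whose hold phase is not near-stationary (|v| < 3 cm/s tolerance) or
    whose final run is not monotone toward the goal are flagged
    ``quality_ok = False`` (best-effort spans are still returned).
    """
    times = np.asarray(times, float)
    position = np.asarray(position, float)
    entrance = find_entrance(times, position)
    v = velocity(times, position)
    in_trial = times <= entrance
    idx = np.flatnonzero(in_trial)
    pos_t = position[idx]
    quality = True

    rear_peak = float(pos_t.max())
    # noise-scaled plateau band: estimate jitter from the interior of the
    # coarse plateau (ends excluded — they carry approach/departure
    # curvature), then take a 4-sigma band (>= 0.01 cm)
    rough = np.flatnonzero(pos_t >= rear_peak - 0.5)
    sigma = 0.0
    if rough.size > 10:
        k = max(rough.size // 10, 1)
        interior = pos_t[rough[k:-k]]
        if interior.size > 3:
            sigma = float(np.std(interior))
    eps = max(4.0 * sigma, 0.01)
    near = pos_t >= rear_peak - eps
    i_arrive = int(np.argmax(near))
    i_leave = int(len(near) - 1 - np.argmax(near[::-1]))
    t_transport = (float(times[idx[0]]), float(times[idx[i_arrive]]))
    t_hold = (float(times[idx[i_arrive]]), float(times[idx[i_leave]]))
    t_accel = (float(times[idx[i_leave]]), float(entrance))

    hold_mask = (times >= t_hold[0]) & (times <= t_hold[1])
    if hold_mask.sum() > 5 and np.mean(np.abs(v[hold_mask]) < 2 * HOLD_TOLERANCE_CM_S) < 0.8:
        quality = False
    accel_mask = (times > t_accel[0] + 0.1) & (times < entrance)
    if accel_mask.sum() > 5 and np.mean(v[accel_mask] < HOLD_TOLERANCE_CM_S) < 0.95:
        quality = False
    return {
        "transport": t_transport,
        "hold": t_hold,
        "acceleration": t_accel,
        "entrance": float(entrance),
        "quality_ok": quality,
    }


def peak_speed(times, position, phases) -> float:
    """Maximum |velocity| (cm/s, ground frame) within the acceleration
    phase of the final run."""
    t0, t1 = phases["acceleration"]
    if t1 <= t0:
        raise ValueError("empty acceleration phase")
    times = np.asarray(times, float)
    v = velocity(times, position)
    m = (times >= t0) & (times <= t1)
    if not m.any():
        raise ValueError("acceleration phase contains no samples")
    return float(np.max(np.abs(v[m])))


def score_trial(raw, goal_time_s: float = GOAL_TIME_S) -> TreadmillTrial:
    """Full per-trial scoring: alignment, phases, peak speed, rear reach."""
    aligned, duration, correct = align_and_duration(raw, goal_time_s)
    phases = segment_phases(raw.sample_times, raw.position, raw.belt_speed)
    pk = peak_speed(raw.sample_times, raw.position, phases)
    t0, t1 = phases["transport"][0], phases["acceleration"][1]
    m = (raw.sample_times >= t0) & (raw.sample_times <= t1)
    min_rear = float(np.max(raw.position[m]))  # rear-most reach (largest cm)
    hold_dur = phases["hold"][1] - phases["hold"][0]
    return TreadmillTrial(
        belt_speed=float(raw.belt_speed),
        duration=duration,
        correct=correct,
        entrance_time=phases["entrance"],
        phases=phases,
        peak_speed=pk,
        min_rear_position=min_rear,
        hold_duration=float(hold_dur),
        quality_ok=phases["quality_ok"],
        aligned_times=aligned,
        aligned_position=np.asarray(raw.position, float),
    )


# ---------------------------------------------------------------------------
# session-level summaries
# ---------------------------------------------------------------------------

def trial_table(trials, dose: Optional[float] = None) -> pd.DataFrame:
    rows = [
        {
            "belt_speed": t.belt_speed,
            "duration_s": t.duration,
            "correct": t.correct,
            "peak_speed_cm_s": t.peak_speed,
            "rearmost_cm": t.min_rear_position,
            "hold_duration_s": t.hold_duration,
            "strategy": t.strategy,
            "quality_ok": t.quality_ok,
        }
        for t in trials
    ]
    df = pd.DataFrame(rows)
    if dose is not None:
        df["dose"] = dose
    return df


def trajectory_difference(
    trials,
    reference_belt_speed: float = 30.0,
    include_incorrect: bool = False,
    grid_pre_s: float = 7.0,
):
    """Median aligned trajectory per belt speed minus the median trajectory
    at the reference speed, on a common time grid ending at the entrance.

    Returns ``(grid, {belt_speed: difference_curve}, {belt_speed: mad})``
    where ``mad`` is the mean absolute difference summary.
    """
    use = [t for t in trials if (t.correct or include_incorrect)]
    grid = np.arange(-grid_pre_s, 0.0, 1.0 / TREADMILL_FS)

    def median_curve(sub):
        rows = [np.interp(grid, t.aligned_times, t.aligned_position) for t in sub]
        return np.median(np.asarray(rows), axis=0)

    ref = [t for t in use if t.belt_speed == reference_belt_speed]
    if len(ref) < 3:
        raise ValueError("need >= 3 trials at the reference belt speed")
    ref_curve = median_curve(ref)
    diffs, mad = {}, {}
    for v in sorted({t.belt_speed for t in use}):
        sub = [t for t in use if t.belt_speed == v]
        if len(sub) < 3:
            continue
        d = median_curve(sub) - ref_curve
        diffs[v] = d
        mad[v] = float(np.mean(np.abs(d)))
    return grid, diffs, mad


@dataclass
class ControlReference:
    """Control-condition distributions used for strategy classification."""

    hold_p5: float
    hold_mean: float
    hold_sd: float
    rear_p5: float
    rear_mean: float
    rear_sd: float

    @classmethod
    def from_trials(cls, control_trials) -> "ControlReference":
        holds = np.asarray([t.hold_duration for t in control_trials], float)
        rears = np.asarray([t.min_rear_position for t in control_trials], float)
        if holds.size < 5:
            raise ValueError("control reference needs >= 5 trials")
        return cls(
            hold_p5=float(np.percentile(holds, 5)),
            hold_mean=float(holds.mean()),
            hold_sd=float(max(holds.std(ddof=1), 1e-6)),
            rear_p5=float(np.percentile(rears, 5)),
            rear_mean=float(rears.mean()),
            rear_sd=float(max(rears.std(ddof=1), 1e-6)),
        )


def classify_strategy(trial: TreadmillTrial, control: ControlReference) -> str:
    """Label a trial's compensation strategy against control percentiles.

    ``shortened_hold`` if the hold phase is below the control 5th
    percentile; ``partial_transport`` if the rear-most reach is below the
    control 5th percentile; when both hold, the larger deviation in
    control-referenced z-units wins; otherwise ``normal``.
    """
    if control is None:
        raise ValueError("control reference is required")
    short_hold = trial.hold_duration < control.hold_p5
    partial = trial.min_rear_position < control.rear_p5
    if short_hold and partial:
        z_hold = (control.hold_mean - trial.hold_duration) / control.hold_sd
        z_rear = (control.rear_mean - trial.min_rear_position) / control.rear_sd
        return "shortened_hold" if z_hold >= z_rear else "partial_transport"
    if short_hold:
        return "shortened_hold"
    if partial:
        return "partial_transport"
    return "normal"


def score_session(raw_session, control: Optional[ControlReference] = None):
    """Score every trial of a raw session; attach strategy labels when a
    control reference is provided."""
    trials = [score_trial(tr) for tr in raw_session.trials]
    if control is not None:
        for t in trials:
            t.strategy = classify_strategy(t, control)
    return trials
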
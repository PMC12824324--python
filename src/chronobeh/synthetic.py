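"""Seeded generative simulator for the lever and treadmill tasks.

The generator encodes two separable distortions:

* a **clock** distortion (``clock_gain``): subjective time accumulates at
  rate ``1/clock_gain``, so for ``clock_gain < 1`` the internal clock runs
  fast, elapsed time is overestimated, and fixed-interval press bouts begin
  and peak before the objective 30 s target (at ``30 x clock_gain`` s).
  Timing imprecision additionally puts a fraction of intervals into an
  untimed "lapse" state with a flat press rate, spreading presses over the
  whole interval.
* a **motor** distortion (``motor_scale``): every limb and locomotion speed
  is multiplied by ``motor_scale``; in ``motor_slowing`` mode slowed
  movements add a fixed latency to every hold regardless of the required
  interval, whereas ``timing_scaling`` mode stretches holds proportionally
  to the required interval.

All randomness flows from one ``numpy`` Generator per session, seeded by a
documented counter scheme (:func:`chronobeh.config.derive_seed`), so the
same (config, seed) is bit-identical.
"""

from __future__ import annotations

import numpy as np

from .config import (
    GenConfig,
    FIXED_INTERVAL_S,
    FIXED_HOLD_MS,
    BLOCK_LEN,
    BLOCK_THRESHOLDS_MS,
    LEVER_FS,
    TREADMILL_FS,
    SPATIAL_THRESHOLD_CM,
)
from .sessions import LeverSession, TreadmillSessionRaw, TreadmillTrialRaw


class InfeasibleKinematics(ValueError):
    """The goal cannot be reached under any allowed compensation strategy."""


# ---------------------------------------------------------------------------
# press-rate model (fixed-interval task)
# ---------------------------------------------------------------------------

def press_rate(t, config: GenConfig, dose: float):
    """Instantaneous press-bout rate (presses/s) at objective time ``t``
    since the last reward, for a *timed* interval.

    Scalar-timing ramp: a Gaussian rise of subjective width
    ``weber_fraction x 30 s`` toward the point where subjective time
    reaches the 30 s target; past the target the rate relaxes to a
    sustained level (half the peak, subjective time constant 3 s) and the
    animal keeps pressing until the reward arrives.  With
    ``clock_gain < 1`` the rate peaks at ``30 x clock_gain`` objective
    seconds, i.e. early.
    """
    config.require_dose(dose)
    cg = config.clock_gain[dose]
    t = np.asarray(t, float)
    t_subj = t / cg
    sigma = config.weber_fraction * FIXED_INTERVAL_S
    sustain = 0.5
    ramp = np.where(
        t_subj < FIXED_INTERVAL_S,
        np.exp(-0.5 * ((t_subj - FIXED_INTERVAL_S) / sigma) ** 2),
        sustain + (1.0 - sustain) * np.exp(-(t_subj - FIXED_INTERVAL_S) / 3.0),
    )
    return config.press_rate_baseline + config.press_rate_peak * ramp


def lapse_probability(config: GenConfig, dose: float) -> float:
    """Probability that a fixed-interval trial is untimed (flat pressing)."""
    cg = config.clock_gain[dose]
    return float(np.clip(config.lapse_coefficient * (1.0 - cg), 0.0, 0.9))


def sample_interval_press_times(
    rng: np.random.Generator,
    config: GenConfig,
    dose: float,
    t_max: float,
    refractory_s: float,
) -> np.ndarray:
    """Sample press-bout onset times in one interval by Poisson thinning,
    then enforce a refractory gap (a press occupies the paws)."""
    lapse = rng.random() < lapse_probability(config, dose)
    if lapse:
        lam_max = config.lapse_press_rate
    else:
        lam_max = config.press_rate_baseline + config.press_rate_peak
    n_cand = rng.poisson(lam_max * t_max)
    cand = np.sort(rng.uniform(0.0, t_max, size=n_cand))
    if lapse:
        keep = np.ones(cand.size, bool)
    else:
        keep = rng.random(cand.size) * lam_max < press_rate(cand, config, dose)
    times = cand[keep]
    out = []
    last = -np.inf
    for t in times:
        if t - last >= refractory_s:
            out.append(t)
            last = t
    return np.asarray(out)


# ---------------------------------------------------------------------------
# single-press machinery (shared by both lever tasks)
# ---------------------------------------------------------------------------

def _hold_distortion_ms(config: GenConfig, dose: float, required_ms: float) -> float:
    """Dose-induced lengthening of the planned hold, per production_mode."""
    if config.production_mode == "motor_slowing":
        ms = config.motor_scale[dose]
        return config.motor_time_const_ms * (1.0 / ms - 1.0)
    cg = config.clock_gain[dose]
    return (required_ms + config.planned_margin_ms) * (1.0 / cg - 1.0)


def _draw_hold_s(rng, config: GenConfig, dose: float, required_ms: float) -> float:
    """Draw one above-threshold hold duration (s) for a press attempt.

    Planned holds follow scalar timing (multiplicative Weber noise); a
    ``reactive_release_fraction`` of trials instead release as a reaction to
    reward delivery (~300 ms after it).
    """
    if rng.random() < config.reactive_release_fraction:
        # release is a reaction to the reward stimulus: required interval
        # plus a (motor-scaled) reaction time, independent of the plan
        rt = config.reaction_time_ms * (1.0 + 0.15 * rng.standard_normal())
        hold_ms = required_ms + max(rt, 50.0) / config.motor_scale[dose]
    else:
        distortion = _hold_distortion_ms(config, dose, required_ms)
        planned = required_ms + config.planned_margin_ms + distortion
        hold_ms = planned * (1.0 + config.weber_fraction * rng.standard_normal())
    return max(hold_ms, 50.0) / 1000.0


class _Press:
    """Analytic description of one bilateral trapezoidal press."""

    __slots__ = ("t_on_l", "t_on_r", "t_release", "rise_speed", "amp", "hold_s")

    def __init__(self, t_bout, lag, hold_s, rise_speed, amp):
        self.t_on_l = t_bout
        self.t_on_r = t_bout + lag
        self.rise_speed = rise_speed
        self.amp = amp
        self.hold_s = hold_s
        # joint above-spatial-threshold span has length hold_s
        t_fall_below = self.joint_onset + hold_s
        self.t_release = t_fall_below - (amp - SPATIAL_THRESHOLD_CM) / rise_speed

    @property
    def joint_onset(self) -> float:
        """First instant both levers are above the 2.6 cm spatial threshold."""
        return max(self.t_on_l, self.t_on_r) + SPATIAL_THRESHOLD_CM / self.rise_speed

    @property
    def joint_end(self) -> float:
        return self.t_release + (self.amp - SPATIAL_THRESHOLD_CM) / self.rise_speed

    @property
    def t_end(self) -> float:
        """Time the levers are fully back at rest."""
        return self.t_release + self.amp / self.rise_speed

    def breakpoints(self, lever: str):
        t_on = self.t_on_l if lever == "left" else self.t_on_r
        rise = self.amp / self.rise_speed
        return (
            [t_on, t_on + rise, self.t_release, self.t_release + rise],
            [0.0, self.amp, self.amp, 0.0],
        )


def _make_press(rng, config: GenConfig, dose: float, t_bout: float, hold_s: float) -> _Press:
    lag = rng.normal(0.0, config.coordination_noise) if config.coordination_noise > 0 else 0.0
    speed = config.lever_rise_speed * config.motor_scale[dose]
    return _Press(t_bout, lag, hold_s, speed, config.press_amplitude_cm)


class _Tap:
    """A short exploratory lever touch that stays below the 2.6 cm
    spatial threshold (it registers as a press but never as an attempt)."""

    __slots__ = ("t_on_l", "t_on_r", "rise_speed", "amp", "dwell", "hold_s")

    def __init__(self, t_bout, lag, amp, dwell, rise_speed):
        self.t_on_l = t_bout
        self.t_on_r = t_bout + lag
        self.amp = amp
        self.dwell = dwell
        self.rise_speed = rise_speed
        self.hold_s = 0.0

    @property
    def joint_onset(self) -> float:
        return max(self.t_on_l, self.t_on_r)

    @property
    def t_end(self) -> float:
        return max(self.t_on_l, self.t_on_r) + 2 * self.amp / self.rise_speed + self.dwell

    def breakpoints(self, lever: str):
        t_on = self.t_on_l if lever == "left" else self.t_on_r
        rise = self.amp / self.rise_speed
        return (
            [t_on, t_on + rise, t_on + rise + self.dwell, t_on + 2 * rise + self.dwell],
            [0.0, self.amp, self.amp, 0.0],
        )


def _make_tap(rng, config: GenConfig, dose: float, t_bout: float) -> _Tap:
    lag = rng.normal(0.0, config.coordination_noise) if config.coordination_noise > 0 else 0.0
    speed = config.lever_rise_speed * config.motor_scale[dose]
    amp = rng.uniform(0.8, 2.2)
    dwell = rng.uniform(0.05, 0.2)
    return _Tap(t_bout, lag, amp, dwell, speed)


def _render(presses, t_end: float, rng, config: GenConfig):
    """Render analytic presses onto the 250 samples/s grid."""
    n = int(np.ceil(t_end * LEVER_FS)) + 1
    times = np.arange(n) / LEVER_FS
    left = np.zeros(n)
    right = np.zeros(n)
    for p in presses:
        for lever, arr in (("left", left), ("right", right)):
            bp_t, bp_y = p.breakpoints(lever)
            i0 = max(int(np.floor(bp_t[0] * LEVER_FS)), 0)
            i1 = min(int(np.ceil(bp_t[-1] * LEVER_FS)) + 1, n)
            seg = np.interp(times[i0:i1], bp_t, bp_y)
            np.maximum(arr[i0:i1], seg, out=arr[i0:i1])
    if config.position_jitter_cm > 0:
        for arr in (left, right):
            arr += rng.normal(0.0, config.position_jitter_cm, size=n) * (arr > 0)
    np.clip(left, 0.0, config.press_amplitude_cm + 0.4, out=left)
    np.clip(right, 0.0, config.press_amplitude_cm + 0.4, out=right)
    return times, left, right


# ---------------------------------------------------------------------------
# fixed-interval sessions
# ---------------------------------------------------------------------------

def simulate_fixed_interval_session(config: GenConfig, dose: float, seed: int) -> LeverSession:
    """Simulate one fixed-interval (30 s) session.

    Press bouts follow the scalar-timing ramp; the first bilateral press
    whose joint onset falls at least 30 s after the previous reward and
    whose joint hold reaches 750 ms is rewarded (at joint onset + 750 ms),
    which resets the interval.
    """
    config.require_dose(dose)
    if config.n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = np.random.default_rng(seed)
    required_ms = FIXED_HOLD_MS
    cg = config.clock_gain[dose]
    rise = config.press_amplitude_cm / (config.lever_rise_speed * config.motor_scale[dose])
    refractory = 0.4  # minimum gap between press-bout onsets (short touches)

    presses = []
    reward_times = []
    trial_truth = []
    t0 = 0.0  # time of last reward (interval origin)
    t_max = max(FIXED_INTERVAL_S * cg + 5 * config.weber_fraction * FIXED_INTERVAL_S, 38.0)
    for trial_idx in range(config.n_trials):
        # the schedule gate opens interval_s after the previous reward;
        # at session start it is already open
        gate_rel = 0.0 if trial_idx == 0 else FIXED_INTERVAL_S
        rel = list(sample_interval_press_times(rng, config, dose, t_max, refractory))
        reward = None
        n_attempts = 0
        # presses must clear the previous interval's rewarded press tail
        last_end_rel = (presses[-1].t_end - t0 + 0.2) if presses else 0.0
        i = 0
        while reward is None:
            if i < len(rel):
                tb = rel[i]
                i += 1
            else:
                # ensure the interval terminates: keep pressing past the gate
                tb = max(last_end_rel + 0.5, gate_rel + 0.2) + rng.exponential(0.8)
            if tb < last_end_rel + 0.1:
                continue
            # commit to a full coordinated hold with probability following
            # the timing bump; otherwise make a short sub-threshold touch
            t_subj = tb / cg
            sigma = config.weber_fraction * FIXED_INTERVAL_S
            if t_subj < FIXED_INTERVAL_S:
                # squared bump: full holds concentrate near the target
                p_commit = float(np.exp(-(((t_subj - FIXED_INTERVAL_S) / sigma) ** 2)))
            else:
                p_commit = 1.0
            p_commit = max(p_commit, 0.1)
            if rng.random() < p_commit:
                hold = _draw_hold_s(rng, config, dose, required_ms)
                p = _make_press(rng, config, dose, t0 + tb, hold)
                n_attempts += 1
            else:
                hold = 0.0
                p = _make_tap(rng, config, dose, t0 + tb)
            presses.append(p)
            last_end_rel = p.t_end - t0
            if p.joint_onset - t0 >= gate_rel and hold >= required_ms / 1000.0:
                reward = p.joint_onset + required_ms / 1000.0
        reward_times.append(reward)
        trial_truth.append(
            {
                "n_attempts": n_attempts,
                "hold_s": float(presses[-1].hold_s),
                "overshoot_ms": float(presses[-1].hold_s * 1000.0 - required_ms),
                "onset_lag_s": float(presses[-1].t_on_r - presses[-1].t_on_l),
            }
        )
        t0 = reward
    t_end = presses[-1].t_end + 1.0
    times, left, right = _render(presses, t_end, rng, config)
    truth = {
        "clock_gain": cg,
        "motor_scale": config.motor_scale[dose],
        "planned_margin_ms": config.planned_margin_ms,
        "weber_fraction": config.weber_fraction,
        "bump_center_s": FIXED_INTERVAL_S * cg,
        "reward_times": [float(r) for r in reward_times],
        "trials": trial_truth,
    }
    return LeverSession(
        sample_times=times,
        left_pos=left,
        right_pos=right,
        reward_times=np.asarray(reward_times),
        schedule="fixed_interval",
        dose=dose,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# two-interval production sessions
# ---------------------------------------------------------------------------

def block_threshold_ms(trial_index: int) -> float:
    """Required hold for a 0-based rewarded-trial index (20-trial blocks,
    sessions always start with the 1250 ms block)."""
    return BLOCK_THRESHOLDS_MS[(trial_index // BLOCK_LEN) % 2]


def simulate_two_interval_session(config: GenConfig, dose: float, seed: int) -> LeverSession:
    """Simulate one two-interval production session (alternating 20-trial
    blocks of 1250 ms and 750 ms required holds, 1.5 s inter-trial
    interval)."""
    config.require_dose(dose)
    if config.n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = np.random.default_rng(seed)
    presses = []
    reward_times = []
    block_labels = []
    trial_truth = []
    cursor = 0.5
    for k in range(config.n_trials):
        required_ms = block_threshold_ms(k)
        block_labels.append(required_ms)
        iti = 1.5
        approach = 0.4 + (0.2 * rng.random() if config.coordination_noise > 0 else 0.0)
        t_bout = cursor + iti + approach
        n_attempts = 0
        while True:
            n_attempts += 1
            failed = (
                config.attempt_failure_rate > 0
                and rng.random() < config.attempt_failure_rate
            )
            if failed:
                hold = rng.uniform(0.3, 0.9) * required_ms / 1000.0
            else:
                hold = _draw_hold_s(rng, config, dose, required_ms)
            p = _make_press(rng, config, dose, t_bout, hold)
            presses.append(p)
            if hold >= required_ms / 1000.0:
                reward = p.joint_onset + required_ms / 1000.0
                break
            t_bout = p.t_end + 0.3 + (0.3 * rng.random() if config.coordination_noise > 0 else 0.1)
        reward_times.append(reward)
        trial_truth.append(
            {
                "required_ms": required_ms,
                "n_attempts": n_attempts,
                "hold_s": float(p.hold_s),
                "overshoot_ms": float(p.hold_s * 1000.0 - required_ms),
                "onset_lag_s": float(p.t_on_r - p.t_on_l),
            }
        )
        cursor = p.t_end
    t_end = presses[-1].t_end + 1.0
    times, left, right = _render(presses, t_end, rng, config)
    truth = {
        "clock_gain": config.clock_gain[dose],
        "motor_scale": config.motor_scale[dose],
        "planned_margin_ms": config.planned_margin_ms,
        "production_mode": config.production_mode,
        "distortion_ms": {
            str(int(r)): _hold_distortion_ms(config, dose, r) for r in BLOCK_THRESHOLDS_MS
        },
        "reward_times": [float(r) for r in reward_times],
        "trials": trial_truth,
    }
    return LeverSession(
        sample_times=times,
        left_pos=left,
        right_pos=right,
        reward_times=np.asarray(reward_times),
        schedule="two_interval",
        dose=dose,
        block_labels=np.asarray(block_labels, float),
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# treadmill sessions
# ---------------------------------------------------------------------------

def _phase3_profile(v_peak: float, distance: float):
    """Final-run speed profile: linear ramp 0 -> v_peak over t_a, then
    linear decay v_peak -> 0.4 v_peak at the goal entrance.  Returns
    (t_accel, t_total, v_end)."""
    v_end = 0.4 * v_peak
    # distance = v_peak*t_a/2 + (v_peak+v_end)/2 * t_a   with t_d = t_a
    t_a = distance / (0.5 * v_peak + 0.5 * (v_peak + v_end))
    return t_a, 2 * t_a, v_end


def plan_treadmill_trial(
    config: GenConfig,
    dose: float,
    belt_speed: float,
    duration_s: float,
    strategy: str,
):
    """Solve the three-phase front-back-front kinematics for one trial.

    Returns a dict of phase boundaries and kinematic parameters, or raises
    :class:`InfeasibleKinematics`.
    """
    tm = config.treadmill
    ms = config.motor_scale[dose]
    start = tm.goal_zone_cm
    v_peak = (tm.peak_speed_cm_s + tm.peak_speed_belt_slope * (belt_speed - 30.0)) * ms
    if v_peak <= 0:
        raise InfeasibleKinematics("non-positive peak speed")

    def control_hold():
        v_pk_c = tm.peak_speed_cm_s + tm.peak_speed_belt_slope * (belt_speed - 30.0)
        d = tm.rear_position_cm - start
        t1 = d / belt_speed
        _, t3, _ = _phase3_profile(v_pk_c, d)
        return tm.goal_time_s + tm.duration_margin_s - t1 - t3

    if strategy in ("normal", "shortened_hold"):
        rear = tm.rear_position_cm
        d = rear - start
        t1 = d / belt_speed
        t_a, t3, v_end = _phase3_profile(v_peak, d)
        t2 = duration_s - t1 - t3
        if t2 < 0:
            raise InfeasibleKinematics(
                f"hold phase would be negative ({t2:.2f} s) at belt {belt_speed} cm/s"
            )
    elif strategy == "partial_transport":
        t2 = max(control_hold(), 0.0)
        # from _phase3_profile with v_end = 0.4 v_peak: t3 = 2 d / (1.2 v_peak),
        # so t1 + t3 = d (1/belt + 2/(1.2 v_peak)) = duration - t2
        denom = 1.0 / belt_speed + 2.0 / (1.2 * v_peak)
        d = (duration_s - t2) / denom
        rear = start + d
        if d <= 5.0:
            raise InfeasibleKinematics("no room to run: transport distance too short")
        if rear > config.treadmill.belt_length_cm - 2.0:
            raise InfeasibleKinematics("required transport exceeds the belt length")
        t1 = d / belt_speed
        t_a, t3, v_end = _phase3_profile(v_peak, d)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return {
        "strategy": strategy,
        "belt_speed": belt_speed,
        "rear_cm": rear,
        "v_peak": v_peak,
        "v_end": v_end,
        "t_transport": t1,
        "t_hold": t2,
        "t_accel": t3,
        "duration_s": t1 + t2 + t3,
    }


def _render_treadmill(plan, rng, config: GenConfig) -> TreadmillTrialRaw:
    tm = config.treadmill
    t1, t2, t3 = plan["t_transport"], plan["t_hold"], plan["t_accel"]
    rear, v_peak, v_end = plan["rear_cm"], plan["v_peak"], plan["v_end"]
    start = tm.goal_zone_cm
    d = rear - start
    t_entry = t1 + t2 + t3
    # run a little past the entrance, decelerating v_end -> 0 over 2 cm
    t_post = 4.0 / v_end if v_end > 0 else 0.2
    n = int(np.ceil((t_entry + t_post) * TREADMILL_FS)) + 1
    t = np.arange(n) / TREADMILL_FS
    pos = np.empty(n)
    ta = t3 / 2.0
    for i, ti in enumerate(t):
        if ti < t1:
            pos[i] = start + plan["belt_speed"] * ti
        elif ti < t1 + t2:
            pos[i] = rear
        elif ti <= t_entry:
            tau = ti - t1 - t2
            if tau <= ta:
                run = 0.5 * v_peak * tau**2 / ta
            else:
                u = tau - ta
                run = 0.5 * v_peak * ta + v_peak * u - 0.5 * (v_peak - v_end) * u**2 / ta
            pos[i] = rear - run
        else:
            # decelerate v_end -> 0 linearly over t_post (2 cm into the zone)
            u = min(ti - t_entry, t_post)
            pos[i] = start - (v_end * u - 0.5 * v_end * u**2 / t_post)
    np.clip(pos, 0.0, tm.belt_length_cm, out=pos)
    if config.coordination_noise > 0:
        pos = pos + rng.normal(0.0, config.coordination_noise, size=n)
        np.clip(pos, 0.0, tm.belt_length_cm, out=pos)
    return TreadmillTrialRaw(
        sample_times=t,
        position=pos,
        belt_speed=plan["belt_speed"],
        trial_start=0.0,
        ground_truth=plan,
    )


def simulate_treadmill_session(
    config: GenConfig,
    dose: float,
    belt_speeds=None,
    seed: int = 0,
    strategy: str = "auto",
) -> TreadmillSessionRaw:
    """Simulate one treadmill session of front-back-front trials.

    ``strategy`` is ``"auto"`` (control animals run the normal sequence;
    dosed animals adopt one compensation strategy for the session),
    ``"normal"``, ``"shortened_hold"`` or ``"partial_transport"``.
    """
    config.require_dose(dose)
    tm = config.treadmill
    if belt_speeds is None:
        belt_speeds = tm.belt_speed_set
    for v in belt_speeds:
        if v not in tm.belt_speed_set:
            raise ValueError(f"belt speed {v} not in configured set {tm.belt_speed_set}")
    rng = np.random.default_rng(seed)
    ms = config.motor_scale[dose]
    if strategy == "auto":
        if ms >= 0.999:
            strategy = "normal"
        else:
            strategy = rng.choice(["shortened_hold", "partial_transport"])
    trials = []
    for _ in range(config.n_trials):
        v_b = float(belt_speeds[rng.integers(len(belt_speeds))])
        jitter = (
            rng.normal(0.0, tm.duration_jitter_s) if config.coordination_noise > 0 else 0.0
        )
        duration = tm.goal_time_s + tm.duration_margin_s + jitter
        duration = max(duration, 0.8 * tm.goal_time_s)
        try:
            plan = plan_treadmill_trial(config, dose, v_b, duration, strategy)
        except InfeasibleKinematics:
            if strategy != "partial_transport":
                raise
            # at mild slowing a long-duration trial may ask for more
            # transport than the belt allows; execute it normally instead
            plan = plan_treadmill_trial(config, dose, v_b, duration, "shortened_hold")
        trials.append(_render_treadmill(plan, rng, config))
    truth = {"motor_scale": ms, "strategy": strategy}
    return TreadmillSessionRaw(trials=trials, dose=dose, ground_truth=truth)
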
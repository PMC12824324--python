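"""Generator and pipeline configuration.

A :class:`GenConfig` fully determines a simulated cohort: the dose ladder,
how each dose distorts the internal clock (``clock_gain``) and limb /
locomotion speed (``motor_scale``), the scalar-timing noise level
(``weber_fraction``), and the task geometry.  The same config + seed always
produces bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

#: lever sampling rate (samples/s); traces are digitized at this rate
LEVER_FS = 250.0
#: treadmill video rate (frames/s)
TREADMILL_FS = 100.0
#: video spatial calibration, pixels per centimetre
PIXELS_PER_CM = 9.0
#: full-scale lever displacement (cm) at full-scale transducer voltage (V)
LEVER_CM_FULL = 3.5
LEVER_V_FULL = 2.5
#: lever press detection thresholds (cm)
TOUCH_THRESHOLD_CM = 0.1
SPATIAL_THRESHOLD_CM = 2.6
#: physical lever travel limit (cm)
LEVER_MAX_CM = 3.5

#: fixed-interval schedule: delay (s) and hold requirement (ms)
FIXED_INTERVAL_S = 30.0
FIXED_HOLD_MS = 750.0
#: two-interval production schedule
BLOCK_LEN = 20
BLOCK_THRESHOLDS_MS = (1250.0, 750.0)

#: treadmill geometry (cm) and goal time (s)
BELT_LENGTH_CM = 80.0
GOAL_ZONE_CM = 10.0
GOAL_TIME_S = 7.0
BELT_SPEED_SET = (27.0, 28.0, 29.0, 30.0, 31.0, 32.0, 33.0)


@dataclass(frozen=True)
class TreadmillConfig:
    """Geometry and kinematic parameters of the timed locomotor sequence."""

    belt_speed_set: tuple = BELT_SPEED_SET
    goal_time_s: float = GOAL_TIME_S
    belt_length_cm: float = BELT_LENGTH_CM
    goal_zone_cm: float = GOAL_ZONE_CM
    #: rear-most position held during the hold phase under control (cm)
    rear_position_cm: float = 75.0
    #: peak ground-frame speed of the final acceleration at the central belt
    #: speed, control condition (cm/s)
    peak_speed_cm_s: float = 60.0
    #: slope of peak speed vs belt speed (dimensionless)
    peak_speed_belt_slope: float = 1.5
    #: planned margin over the goal time (s); animals aim slightly past 7 s
    duration_margin_s: float = 0.05
    #: SD of trial-to-trial duration jitter (s) when noise is on
    duration_jitter_s: float = 0.15


@dataclass(frozen=True)
class GenConfig:
    """Parameters of the synthetic behavioral generator.

    ``clock_gain`` multiplies the subjective time rate: 1.0 is veridical,
    values < 1 make subjective time run slow, so the animal overestimates
    elapsed objective time (presses spread over the whole 30 s interval).
    ``motor_scale`` multiplies limb and locomotion speed: 1.0 is control,
    values < 1 slow every movement.  ``production_mode`` selects how a dose
    lengthens two-interval holds: ``motor_slowing`` adds a fixed latency to
    every movement regardless of the required interval, ``timing_scaling``
    stretches the hold proportionally to the required interval.
    """

    dose_levels: tuple = (0.0, 0.01, 0.05, 0.1, 0.2)
    clock_gain: Mapping[float, float] = field(
        default_factory=lambda: {0.0: 1.0, 0.01: 0.95, 0.05: 0.87, 0.1: 0.78, 0.2: 0.68}
    )
    motor_scale: Mapping[float, float] = field(
        default_factory=lambda: {0.0: 1.0, 0.01: 0.95, 0.05: 0.85, 0.1: 0.75, 0.2: 0.60}
    )
    weber_fraction: float = 0.12
    planned_margin_ms: float = 200.0
    reaction_time_ms: float = 300.0
    #: fraction of trials where release is a reaction to reward rather than
    #: a pre-planned movement end (release latency > ~300 ms)
    reactive_release_fraction: float = 0.05
    press_rate_peak: float = 2.0  # presses/s near the subjective target
    press_rate_baseline: float = 0.05  # presses/s far from the target
    #: probability that a reward is preceded by an extra too-short attempt
    attempt_failure_rate: float = 0.1
    #: fraction of untimed ("lapse") fixed-interval trials per unit of clock
    #: distortion (1 - clock_gain); lapse trials press at a flat rate
    lapse_coefficient: float = 1.2
    lapse_press_rate: float = 0.5  # presses/s during lapse intervals
    coordination_noise: float = 0.05  # SD of inter-lever onset lag (s) & jitter (cm)
    position_jitter_cm: float = 0.02
    production_mode: str = "motor_slowing"
    #: movement-time constant converting motor slowing into added hold (ms);
    #: additive distortion = motor_time_const_ms * (1/motor_scale - 1)
    motor_time_const_ms: float = 600.0
    #: lever rise speed under control (cm/s)
    lever_rise_speed: float = 26.0
    #: press amplitude (cm); must exceed the 2.6 cm spatial threshold
    press_amplitude_cm: float = 3.0
    treadmill: TreadmillConfig = field(default_factory=TreadmillConfig)
    n_trials: int = 100
    n_sessions: int = 1
    seed: int = 0

    def __post_init__(self):
        if tuple(sorted(self.dose_levels)) != tuple(self.dose_levels):
            raise ValueError("dose_levels must be sorted ascending")
        if not 0.0 < self.weber_fraction < 1.0:
            raise ValueError("weber_fraction must lie in (0, 1)")
        for name in ("clock_gain", "motor_scale"):
            m = getattr(self, name)
            for d in self.dose_levels:
                if d not in m:
                    raise ValueError(f"{name} missing dose level {d}")
                if m[d] <= 0:
                    raise ValueError(f"{name}[{d}] must be > 0")
        if self.production_mode not in ("motor_slowing", "timing_scaling"):
            raise ValueError(f"unknown production_mode {self.production_mode!r}")
        if self.press_amplitude_cm > LEVER_MAX_CM:
            raise ValueError("press amplitude exceeds physical lever travel")

    def require_dose(self, dose: float) -> None:
        if dose not in self.dose_levels:
            raise ValueError(f"unknown dose label {dose!r}; known: {self.dose_levels}")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clock_gain"] = dict(self.clock_gain)
        d["motor_scale"] = dict(self.motor_scale)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenConfig":
        d = dict(d)
        if "treadmill" in d and isinstance(d["treadmill"], Mapping):
            tm = dict(d["treadmill"])
            if "belt_speed_set" in tm:
                tm["belt_speed_set"] = tuple(tm["belt_speed_set"])
            d["treadmill"] = TreadmillConfig(**tm)
        if "dose_levels" in d:
            d["dose_levels"] = tuple(d["dose_levels"])
        for name in ("clock_gain", "motor_scale"):
            if name in d:
                d[name] = {float(k): float(v) for k, v in d[name].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GenConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def derive_seed(master_seed: int, *counters: int) -> int:
    """Derive an independent per-session stream seed from a master seed.

    Uses a documented counter scheme (SeedSequence spawn keys) so each
    session is reproducible in isolation.  Result is kept below 2**31.
    """
    import numpy as np

    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(c) for c in counters))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
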
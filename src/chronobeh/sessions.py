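"""In-memory session containers and the on-disk session bundle.

A session bundle is a directory with one columnar CSV per trace plus a YAML
sidecar carrying schedule, dose, event times and (for simulated sessions)
the generating ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .config import LEVER_FS, TREADMILL_FS, LEVER_MAX_CM


@dataclass
class LeverSession:
    """One lever-task session: bilateral position traces plus annotations.

    Positions are in cm (0 = rest), sampled on a uniform 250 samples/s grid.
    ``schedule`` is ``"fixed_interval"`` or ``"two_interval"``;
    ``block_labels`` gives the required hold (ms) per rewarded trial where
    the schedule defines one.
    """

    sample_times: np.ndarray
    left_pos: np.ndarray
    right_pos: np.ndarray
    reward_times: np.ndarray
    schedule: str
    dose: float
    block_labels: Optional[np.ndarray] = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sample_times = np.asarray(self.sample_times, float)
        self.left_pos = np.asarray(self.left_pos, float)
        self.right_pos = np.asarray(self.right_pos, float)
        self.reward_times = np.asarray(self.reward_times, float)
        n = self.sample_times.size
        if self.left_pos.size != n or self.right_pos.size != n:
            raise ValueError("trace lengths do not match the time grid")
        if n > 1:
            dt = np.diff(self.sample_times)
            if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
                raise ValueError("sample grid is not uniform")
        if np.any(self.reward_times[1:] <= self.reward_times[:-1]):
            raise ValueError("reward_times must be strictly increasing")
        for tr in (self.left_pos, self.right_pos):
            if tr.size and (tr.min() < -1e-9 or tr.max() > LEVER_MAX_CM + 1e-9):
                raise ValueError("lever position outside physical range")

    @property
    def fs(self) -> float:
        if self.sample_times.size > 1:
            return 1.0 / (self.sample_times[1] - self.sample_times[0])
        return LEVER_FS

    def save(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"time_s": self.sample_times, "left_cm": self.left_pos, "right_cm": self.right_pos}
        ).to_csv(outdir / "trace.csv", index=False)
        meta = {
            "kind": "lever_session",
            "schedule": self.schedule,
            "dose": float(self.dose),
            "reward_times": [float(t) for t in self.reward_times],
            "block_labels": None
            if self.block_labels is None
            else [float(b) for b in self.block_labels],
            "ground_truth": _plain(self.ground_truth),
        }
        with open(outdir / "meta.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)
        return outdir

    @classmethod
    def load(cls, indir) -> "LeverSession":
        indir = Path(indir)
        tr = pd.read_csv(indir / "trace.csv")
        with open(indir / "meta.yaml") as fh:
            meta = yaml.safe_load(fh)
        bl = meta.get("block_labels")
        return cls(
            sample_times=tr["time_s"].to_numpy(),
            left_pos=tr["left_cm"].to_numpy(),
            right_pos=tr["right_cm"].to_numpy(),
            reward_times=np.asarray(meta["reward_times"], float),
            schedule=meta["schedule"],
            dose=float(meta["dose"]),
            block_labels=None if bl is None else np.asarray(bl, float),
            ground_truth=meta.get("ground_truth") or {},
        )


@dataclass
class TreadmillTrialRaw:
    """One treadmill trial: body position trace (cm from the front wall)."""

    sample_times: np.ndarray
    position: np.ndarray
    belt_speed: float
    trial_start: float = 0.0
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sample_times = np.asarray(self.sample_times, float)
        self.position = np.asarray(self.position, float)
        if self.sample_times.size != self.position.size:
            raise ValueError("trace lengths do not match the time grid")


@dataclass
class TreadmillSessionRaw:
    """A set of treadmill trials from one session at one dose."""

    trials: list
    dose: float
    ground_truth: dict = field(default_factory=dict)

    def save(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = []
        for i, tr in enumerate(self.trials):
            fn = f"trial_{i:04d}.csv"
            pd.DataFrame({"time_s": tr.sample_times, "position_cm": tr.position}).to_csv(
                outdir / fn, index=False
            )
            manifest.append(
                {"file": fn, "belt_speed": float(tr.belt_speed), "trial_start": float(tr.trial_start)}
            )
        pd.DataFrame(manifest).to_csv(outdir / "manifest.csv", index=False)
        meta = {"kind": "treadmill_session", "dose": float(self.dose), "ground_truth": _plain(self.ground_truth)}
        with open(outdir / "meta.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)
        return outdir

    @classmethod
    def load(cls, indir) -> "TreadmillSessionRaw":
        indir = Path(indir)
        manifest = pd.read_csv(indir / "manifest.csv")
        with open(indir / "meta.yaml") as fh:
            meta = yaml.safe_load(fh)
        trials = []
        for row in manifest.itertuples():
            tr = pd.read_csv(indir / row.file)
            trials.append(
                TreadmillTrialRaw(
                    sample_times=tr["time_s"].to_numpy(),
                    position=tr["position_cm"].to_numpy(),
                    belt_speed=float(row.belt_speed),
                    trial_start=float(row.trial_start),
                )
            )
        return cls(trials=trials, dose=float(meta["dose"]), ground_truth=meta.get("ground_truth") or {})


def pixels_to_cm(position_px: np.ndarray, pixels_per_cm: float = 9.0) -> np.ndarray:
    """Convert video positions in pixels to cm (9 pixels/cm calibration)."""
    return np.asarray(position_px, float) / float(pixels_per_cm)


def _plain(obj):
    """Recursively convert numpy scalars/arrays so YAML can serialize them."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
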
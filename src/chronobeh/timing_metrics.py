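"""Per-trial and per-session timing / kinematic metrics for the lever tasks.

Conventions: times in seconds internally, milliseconds at reporting
boundaries; aggregates are medians with 25th/75th percentiles; undefined
values (e.g. a zero-variance correlation window) are reported as missing
and excluded from medians, never imputed as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import LEVER_FS, FIXED_INTERVAL_S

#: peri-reward histogram window (s relative to reward) and bin width (s)
PERI_WINDOW = (-30.0, 5.0)
PERI_BINWIDTH = 1.0


def overshoot_ms(trial) -> float:
    """Time (ms) the levers stayed above the spatial threshold past reward."""
    if trial.reward_time is None:
        raise ValueError("overshoot is undefined for an unrewarded trial")
    return (trial.joint_end - trial.reward_time) * 1000.0


def overshoot_fraction(overshoot_ms: float, required_ms: float) -> float:
    """Overshoot normalized by the required hold interval.

    A 150 ms overshoot is a fraction of 0.2 for the 750 ms interval and
    0.12 for the 1250 ms interval.
    """
    if required_ms <= 0:
        raise ValueError("required interval must be positive")
    if overshoot_ms < 0:
        raise ValueError("negative overshoot")
    return overshoot_ms / required_ms


def interlimb_correlation(times, left, right, window) -> float:
    """Pearson r between the two lever positions within ``window``
    (start of the successful bilateral movement to reward delivery).

    Returns NaN (missing) when either trace has zero variance in the
    window.
    """
    t0, t1 = window
    times = np.asarray(times, float)
    m = (times >= t0) & (times <= t1)
    if m.sum() < 3:
        raise ValueError("correlation window holds fewer than 3 samples")
    x = np.asarray(left, float)[m]
    y = np.asarray(right, float)[m]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def bmov(onset_lags_abs_s: Sequence[float]) -> float:
    """Bilateral movement onset variability: variance (s^2) across trials
    of the absolute left-right onset lag."""
    lags = np.asarray(list(onset_lags_abs_s), float)
    if lags.size < 2:
        raise ValueError("bmov needs at least 2 trials")
    return float(np.var(lags, ddof=1))


def movement_speed(trace, fs: float = LEVER_FS):
    """Instantaneous speed series (cm/s) from 4 ms position differences,
    and its maximum."""
    trace = np.asarray(trace, float)
    if trace.size < 2:
        raise ValueError("trace shorter than 2 samples")
    speed = np.abs(np.diff(trace)) * fs
    return speed, float(speed.max())


#: window for the max-speed estimator (s); long enough to average out
#: transducer jitter, shorter than the lever rise at any simulated dose
SPEED_EST_WINDOW_S = 0.06


def max_press_speed(times, trace, onset: float, end: float, fs: float = LEVER_FS) -> float:
    """Maximum lever speed within one press window.

    Estimated from position differences over a 60 ms window rather than
    single 4 ms bins, so that the maximum (an extreme-value statistic) is
    not inflated by sample-to-sample transducer jitter.
    """
    times = np.asarray(times, float)
    m = (times >= onset) & (times <= end)
    x = np.asarray(trace, float)[m]
    w = max(int(round(SPEED_EST_WINDOW_S * fs)), 1)
    if x.size < w + 1:
        return float("nan")
    return float(np.max(np.abs(x[w:] - x[:-w])) * fs / w)


def planned_hold_location(overshoots_ms) -> float:
    """Location of the planned hold component of an overshoot sample.

    Rewarded-trial overshoots are left-censored at 0: attempts released
    before the requirement are simply retried, so the observed sample is a
    normal truncated at zero and its raw mean overestimates the planned
    margin (strongly so for the long interval, whose Weber-scaled spread
    is wider).  The estimator inverts the truncation by moment matching:
    with alpha = -m/s, lambda = phi(alpha)/(1 - Phi(alpha)) and
    delta = lambda (lambda - alpha), a zero-truncated N(m, s) has mean
    m + s lambda and variance s^2 (1 - delta); iterating these equations
    on the observed mean and variance recovers m.
    """
    from scipy.stats import norm

    x = np.asarray(list(overshoots_ms), float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need >= 10 overshoots to estimate the hold location")
    mean_obs = float(x.mean())
    sd_obs = float(x.std(ddof=1))
    if sd_obs == 0:
        return mean_obs
    m, s = mean_obs, sd_obs
    for _ in range(200):
        alpha = -m / s
        lam = float(norm.pdf(alpha) / max(norm.sf(alpha), 1e-12))
        delta = lam * (lam - alpha)
        m_new = mean_obs - s * lam
        s_new = sd_obs / np.sqrt(max(1.0 - delta, 1e-6))
        # keep the fixed-point search inside a sane box: the true location
        # cannot exceed the observed mean nor sit many sigmas below it,
        # and contamination must not blow the scale up
        m_new = float(np.clip(m_new, mean_obs - 3.0 * sd_obs, mean_obs))
        s_new = float(np.clip(s_new, 0.5 * sd_obs, 3.0 * sd_obs))
        # damped update for stability under model misfit
        m_new = 0.5 * m + 0.5 * m_new
        s_new = 0.5 * s + 0.5 * s_new
        if abs(m_new - m) < 1e-9 and abs(s_new - s) < 1e-9:
            m, s = m_new, s_new
            break
        m, s = m_new, s_new
    return float(m)


def trajectory_variability(aligned: np.ndarray) -> float:
    """Across-trial trajectory variability of aligned single-lever traces.

    ``aligned`` is (n_trials, n_timepoints); the statistic is the mean over
    time points of the across-trial interquartile range of position.
    Invariant to a common offset; 0 for identical traces.
    """
    aligned = np.asarray(aligned, float)
    if aligned.ndim != 2 or aligned.shape[0] < 3:
        raise ValueError("need >= 3 aligned trials")
    q75, q25 = np.percentile(aligned, [75, 25], axis=0)
    return float(np.mean(q75 - q25))


def align_press_traces(times, trace, trials, pre_s: float = 0.2, dur_s: float = 1.2):
    """Extract per-trial single-lever traces aligned to the joint onset and
    resampled to a common length (for :func:`trajectory_variability`)."""
    times = np.asarray(times, float)
    trace = np.asarray(trace, float)
    grid = np.arange(-pre_s, dur_s, 1.0 / LEVER_FS)
    rows = []
    for t in trials:
        rows.append(np.interp(grid + t.joint_onset, times, trace))
    return np.asarray(rows)


def efficiency_metrics(trials, session_end: Optional[float] = None) -> dict:
    """Task-engagement summary: time to the first 100 trials, trial count,
    median effort per reward, mean attempts per reward."""
    n = len(trials)
    out = {
        "trials_per_session": n,
        "time_to_100_trials_s": float("nan"),
        "effort_per_reward_s": float("nan"),
        "attempts_per_reward": float("nan"),
    }
    if n == 0:
        return out
    if n >= 100:
        out["time_to_100_trials_s"] = float(trials[99].reward_time)
    out["effort_per_reward_s"] = float(np.median([t.effort_s for t in trials]))
    out["attempts_per_reward"] = float(np.mean([t.n_attempts for t in trials]))
    return out


# ---------------------------------------------------------------------------
# peri-reward histogram analyses (fixed-interval task)
# ---------------------------------------------------------------------------

def exploratory_press_onsets(presses, trials) -> np.ndarray:
    """Onset times of presses that did not themselves trigger a reward.

    Every rewarded trial ends with exactly one press whose above-threshold
    span contains the trial's joint onset; dropping it leaves the
    exploratory (anticipatory) pressing whose distribution over the
    interval carries the timing signal.
    """
    joint_onsets = [t.joint_onset for t in trials]
    out = []
    for p in presses:
        span = p.above_span
        rewarded = span is not None and any(
            span[0] - 1e-9 <= j <= span[1] + 1e-9 for j in joint_onsets
        )
        if not rewarded:
            out.append(p.onset_time)
    return np.asarray(out, float)

@dataclass
class PeriRewardHistogram:
    """Binned press activity around reward onsets.

    ``rate`` is presses per trial per bin; the sum of
    ``rate * n_trials`` recovers the total press count in the window.
    """

    bin_edges: np.ndarray
    rate: np.ndarray
    n_trials: int
    smoothing: str = "none"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_left": self.bin_edges[:-1], "bin_right": self.bin_edges[1:], "rate": self.rate}
        )


def peri_reward_histogram(
    press_onsets,
    reward_times,
    window: tuple = PERI_WINDOW,
    binwidth: float = PERI_BINWIDTH,
) -> PeriRewardHistogram:
    """Histogram of press onsets re-referenced to every reward onset,
    normalized to presses per trial per bin."""
    reward_times = np.asarray(reward_times, float)
    if reward_times.size == 0:
        raise ValueError("need at least one reward")
    press_onsets = np.asarray(press_onsets, float)
    edges = np.arange(window[0], window[1] + binwidth / 2, binwidth)
    counts = np.zeros(edges.size - 1)
    if press_onsets.size:
        rel = (press_onsets[None, :] - reward_times[:, None]).ravel()
        counts, _ = np.histogram(rel, bins=edges)
    return PeriRewardHistogram(
        bin_edges=edges, rate=counts / reward_times.size, n_trials=int(reward_times.size)
    )


def histogram_auc(hist: PeriRewardHistogram) -> float:
    """Trapezoidal area of the rate curve over the pre-reward window
    [-30, 0] s.  Larger when pressing spreads across the interval."""
    m = hist.bin_centers <= 0.0
    x = hist.bin_centers[m]
    y = hist.rate[m]
    if x.size < 2:
        return float(y.sum())
    return float(np.trapezoid(y, x))


def peak_interval_s(hist: PeriRewardHistogram) -> float:
    """Time of the peak press rate relative to the *previous* reward:
    30 + t_rel for the maximum of the 3-bin moving-average-smoothed rate
    over the pre-reward window; ties break to the earliest bin.

    The peak location is refined below the bin width by fitting a
    parabola through the smoothed maximum and its two neighbours, so that
    shifts smaller than one bin remain measurable.
    """
    m = hist.bin_centers <= 0.0
    y = hist.rate[m]
    if not np.any(y > 0):
        raise ValueError("all-zero histogram has no peak")
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(y, kernel, mode="same")
    # ties in the smoothed curve (a lone spike elevates its neighbours
    # equally) resolve by the raw rate, then to the earliest bin
    cand = np.flatnonzero(smooth >= smooth.max() - 1e-12)
    idx = int(cand[np.argmax(y[cand])])
    centers = hist.bin_centers[m]
    t_rel = centers[idx]
    if 0 < idx < smooth.size - 1:
        a, b, c = smooth[idx - 1], smooth[idx], smooth[idx + 1]
        denom = a - 2 * b + c
        if denom < -1e-12:  # proper local maximum
            shift = 0.5 * (a - c) / denom
            binwidth = centers[1] - centers[0] if centers.size > 1 else 1.0
            t_rel = t_rel + float(np.clip(shift, -0.5, 0.5)) * binwidth
    return float(FIXED_INTERVAL_S + t_rel)


# ---------------------------------------------------------------------------
# robustness splits
# ---------------------------------------------------------------------------

def split_trials(trials, scheme: str) -> dict:
    """Partition trials for the robustness re-analyses.

    ``halves``: first vs second half (odd counts put the extra trial in the
    second half); ``first_last_100``: first and last 100 trials (requires
    >= 200); ``block_edges_10``: first 10 vs last 10 trials of every
    20-trial block.
    """
    n = len(trials)
    if scheme == "halves":
        if n < 2:
            raise ValueError("need >= 2 trials to split halves")
        h = n // 2
        return {"first_half": list(trials[:h]), "second_half": list(trials[h:])}
    if scheme == "first_last_100":
        if n < 200:
            raise ValueError("need >= 200 trials for first/last 100")
        return {"first_100": list(trials[:100]), "last_100": list(trials[-100:])}
    if scheme == "block_edges_10":
        first, last = [], []
        for start in range(0, n - n % 20, 20):
            block = trials[start : start + 20]
            first.extend(block[:10])
            last.extend(block[10:])
        if not first:
            raise ValueError("no complete 20-trial block")
        return {"block_first10": first, "block_last10": [t for t in last][-len(first) :]}
    raise ValueError(f"unknown split scheme {scheme!r}")


def session_metric_table(session, trials, left, right) -> pd.DataFrame:
    """One row per trial of the core metrics for a detected lever session."""
    rows = []
    times = session.sample_times
    for t in trials:
        r = interlimb_correlation(
            times, session.left_pos, session.right_pos, (t.joint_onset, t.reward_time)
        )
        spd_l = max_press_speed(times, session.left_pos, t.joint_onset - 0.3, t.joint_end)
        spd_r = max_press_speed(times, session.right_pos, t.joint_onset - 0.3, t.joint_end)
        o_ms = overshoot_ms(t)
        rows.append(
            {
                "trial_index": t.trial_index,
                "required_interval_ms": t.required_interval_ms,
                "overshoot_ms": o_ms,
                "overshoot_fraction": overshoot_fraction(max(o_ms, 0.0), t.required_interval_ms),
                "interlimb_r": r,
                "onset_lag_abs_s": t.onset_lag_abs_s,
                "max_speed_cm_s": np.nanmax([spd_l, spd_r]),
                "n_attempts": t.n_attempts,
                "effort_s": t.effort_s,
                "block_id": t.block_id,
                "dose": session.dose,
            }
        )
    return pd.DataFrame(rows)


def aggregate_metrics(trial_table: pd.DataFrame, by=("dose", "required_interval_ms")) -> pd.DataFrame:
    """Median + 25th/75th percentile aggregates per group."""
    value_cols = [
        c
        for c in trial_table.columns
        if c not in by and pd.api.types.is_numeric_dtype(trial_table[c])
    ]
    recs = []
    for keys, g in trial_table.groupby(list(by)):
        if not isinstance(keys, tuple):
            keys = (keys,)
        base = dict(zip(by, keys))
        for c in value_cols:
            v = g[c].dropna()
            if v.empty:
                continue
            recs.append(
                {
                    **base,
                    "metric": c,
                    "median": float(v.median()),
                    "q25": float(v.quantile(0.25)),
                    "q75": float(v.quantile(0.75)),
                    "n": int(v.size),
                }
            )
    return pd.DataFrame(recs)
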
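"""Lever-trajectory segmentation, movement parameters, time normalization.

A trial is a sustained lever displacement: the onset is the last
below-to-above threshold crossing that stays above threshold until the
reward, the release is the first sustained return below threshold after
it.  Four movement parameters summarize kinematics per trial category:

* intralimb correlation - mean pairwise Pearson r between reward-aligned
  trajectories (its variance indexes movement stability),
* overshoot - time the displacement is held past reward delivery,
* effort - cumulative supra-threshold time spent to earn the reward,
* speed - mean absolute displacement derivative during the movement.

For population analyses that pool 200 ms and 500 ms trials on one grid,
reward-aligned activity is normalized to exactly 2300 one-ms bins: the
200 ms pre-reward movement segment is linearly interpolated to 500 bins
(the 500 ms condition passes through unresampled), flanked by 1000 ms
before and 800 ms after reward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import pearsonr

from .io import EventSet, LeverTrace

logger = logging.getLogger(__name__)

__all__ = [
    "Trial",
    "MovementMetrics",
    "segment_trials",
    "movement_metrics",
    "time_normalize",
    "N_NORMALIZED_BINS",
]

N_NORMALIZED_BINS = 2300
_PRE_BINS, _MOVE_BINS, _POST_BINS = 1000, 500, 800


@dataclass
class Trial:
    """One rewarded lever movement."""

    block_label: int  # required duration, ms (200 | 500)
    onset: float
    reward: float
    release: float
    trajectory: np.ndarray  # reward-aligned displacement segment
    valid: bool = True
    start: float | None = None  # trial start (previous release / trace start)

    def __post_init__(self) -> None:
        if self.valid and not (self.onset < self.reward <= self.release):
            raise ValueError("trial must satisfy onset < reward <= release")

    @property
    def overshoot_s(self) -> float:
        return self.release - self.reward


@dataclass
class MovementMetrics:
    """Per-category movement parameters."""

    intralimb_r: float
    intralimb_var: float
    overshoot_s: float
    effort_s: float
    speed_mm_s: float
    n_trials: int


def _sustained_below(above: np.ndarray, start: int, n_sustain: int) -> int | None:
    """First index >= start from which `above` is False for n_sustain samples."""
    below = ~above[start:]
    if n_sustain <= 1:
        hits = np.flatnonzero(below)
        return start + int(hits[0]) if hits.size else None
    conv = np.convolve(below.astype(int), np.ones(n_sustain, dtype=int), mode="valid")
    hits = np.flatnonzero(conv == n_sustain)
    return start + int(hits[0]) if hits.size else None


def segment_trials(
    lever: LeverTrace,
    events: dict[str, EventSet],
    threshold_mm: float = 0.1,
    sustain_s: float = 0.1,
    align_window: tuple[float, float] = (-1.0, 0.5),
) -> list[Trial]:
    """One trial per reward, segmented from the displacement trace.

    A reward with no preceding sustained crossing is flagged invalid.
    Trajectories are the reward-aligned displacement over ``align_window``.
    """
    rewards = events.get("reward")
    if rewards is None or len(rewards) == 0:
        raise ValueError("segment_trials requires reward events")
    x = lever.samples
    above = x >= threshold_mm
    dt = 1.0 / lever.rate
    n_sustain = max(1, int(round(sustain_s * lever.rate)))

    trials: list[Trial] = []
    prev_release = lever.t_start
    for t_r, lab in zip(rewards.times, rewards.labels):
        i_r = int(round((t_r - lever.t_start) * lever.rate))
        i_r = min(max(i_r, 0), x.size - 1)
        if not above[i_r]:
            logger.info("reward at %.3f s: displacement below threshold, trial invalid", t_r)
            trials.append(Trial(int(lab or 0), t_r - 1.0, t_r, t_r,
                                np.array([]), valid=False, start=prev_release))
            continue
        # onset: start of the contiguous supra-threshold run containing the reward
        run_start = i_r
        while run_start > 0 and above[run_start - 1]:
            run_start -= 1
        onset = lever.t_start + run_start * dt
        rel_idx = _sustained_below(above, i_r, n_sustain)
        release = lever.t_start + (rel_idx if rel_idx is not None else x.size) * dt
        j0 = int(round((t_r + align_window[0] - lever.t_start) * lever.rate))
        j1 = int(round((t_r + align_window[1] - lever.t_start) * lever.rate))
        traj = x[max(j0, 0) : min(j1, x.size)].copy()
        trials.append(Trial(int(lab or 0), onset, t_r, release, traj, start=prev_release))
        prev_release = release
    return trials


def movement_metrics(
    trials: list[Trial],
    lever: LeverTrace,
    threshold_mm: float = 0.1,
) -> MovementMetrics:
    """Movement parameters over the valid trials of one category.

    Intralimb correlation needs >= 2 trials (NaN otherwise; the other
    parameters are still computed).  Effort counts supra-threshold time
    from the trial's start (set by :func:`segment_trials` to the
    previous trial's release) to the reward, so failed attempts before
    the reward add their duration.
    """
    valid = [t for t in trials if t.valid]
    if not valid:
        raise ValueError("no valid trials")
    dt = 1.0 / lever.rate
    x = lever.samples
    above = x >= threshold_mm

    # pairwise trajectory correlations on the common aligned window
    n_min = min(t.trajectory.size for t in valid)
    rs = []
    if len(valid) >= 2 and n_min >= 2:
        for a, b in combinations(valid, 2):
            ta, tb = a.trajectory[:n_min], b.trajectory[:n_min]
            if ta.std() == 0 or tb.std() == 0:
                continue
            rs.append(pearsonr(ta, tb).statistic)
    intralimb_r = float(np.mean(rs)) if rs else float("nan")
    intralimb_var = float(np.var(rs)) if rs else float("nan")

    overshoot = float(np.mean([t.overshoot_s for t in valid]))

    efforts, speeds = [], []
    for t in sorted(valid, key=lambda t: t.reward):
        start = t.start if t.start is not None else lever.t_start
        i0 = int(round((start - lever.t_start) * lever.rate))
        i1 = int(round((t.reward - lever.t_start) * lever.rate))
        efforts.append(float(above[i0:i1].sum() * dt))
        j0 = int(round((t.onset - lever.t_start) * lever.rate))
        j1 = int(round((t.release - lever.t_start) * lever.rate))
        seg = x[j0 : j1 + 1]
        if seg.size >= 2:
            speeds.append(float(np.mean(np.abs(np.diff(seg))) * lever.rate))
    return MovementMetrics(
        intralimb_r=intralimb_r,
        intralimb_var=intralimb_var,
        overshoot_s=overshoot,
        effort_s=float(np.mean(efforts)),
        speed_mm_s=float(np.mean(speeds)) if speeds else float("nan"),
        n_trials=len(valid),
    )


def time_normalize(aligned: np.ndarray, condition: int) -> np.ndarray:
    """Reward-aligned activity on the common 2300-bin grid.

    ``aligned`` is 1 ms-binned activity covering [-1.2, +0.8] s around
    reward for the 200 ms condition (2000 bins) or [-1.5, +0.8] s for
    the 500 ms condition (2300 bins).  Only the pre-reward movement
    segment of the 200 ms condition is resampled (200 -> 500 bins,
    linear, endpoints preserved); the 500 ms condition is the identity.
    """
    aligned = np.asarray(aligned, dtype=float)
    if condition == 500:
        if aligned.size != N_NORMALIZED_BINS:
            raise ValueError(
                f"500 ms condition requires {N_NORMALIZED_BINS} input bins, got {aligned.size}"
            )
        return aligned.copy()
    if condition != 200:
        raise ValueError("condition must be 200 or 500")
    expected = _PRE_BINS + 200 + _POST_BINS
    if aligned.size != expected:
        raise ValueError(f"200 ms condition requires {expected} input bins, got {aligned.size}")
    pre = aligned[:_PRE_BINS]
    move = aligned[_PRE_BINS : _PRE_BINS + 200]
    post = aligned[_PRE_BINS + 200 :]
    x_old = np.linspace(0.0, 1.0, move.size)
    x_new = np.linspace(0.0, 1.0, _MOVE_BINS)
    move_rs = np.interp(x_new, x_old, move)
    return np.concatenate([pre, move_rs, post])
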
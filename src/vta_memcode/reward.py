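"""Time-domain analysis of the 1 s reward-consumption epoch.

The reward section is the first second after the first waterspout lick.
Per-trial spike rates are binned at 10 ms over [lick, lick + 1 s],
averaged across trials, and smoothed with the same Gaussian kernel
machinery as the spatial maps (sigma 5 bins = 50 ms).  The module
classifies units as reward-excited / inhibited (ten 100 ms segments each
tested against the 100 ms pre-lick baseline by paired t-test), tests the
left/right reward preference, correlates the reward-section left-right
difference with the differences in the maze sections, and assigns the
six delay x reward preference categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import SECTION_NAMES
from .ratemaps import smooth_rate

EPOCH_S = 1.0
BIN_S = 0.01
N_SEGMENTS = 10
SEG_BINS = 10          # 100 ms segments of 10 ms bins
PRE_S = 0.1            # pre-lick baseline window


@dataclass
class RewardResult:
    unit_id: int
    psth_left: np.ndarray        # Hz per 10 ms bin, smoothed
    psth_right: np.ndarray
    segment_flags: list          # 10 x {excited, inhibited, ns}
    overall: str                 # excited | inhibited | ns
    side_pref: str               # left | right | ns
    D_reward: float              # Hz, mean left - right over the epoch
    n_left: int
    n_right: int


def trial_epoch_counts(spike_times, licks, epoch: float = EPOCH_S,
                       bin_s: float = BIN_S) -> np.ndarray:
    """(trials, bins) spike counts in [lick, lick + epoch) per trial."""
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    licks = np.asarray(licks, dtype=float)
    n_bins = int(round(epoch / bin_s))
    edges = licks[:, None] + np.arange(n_bins + 1) * bin_s
    return np.diff(np.searchsorted(spikes, edges), axis=1).astype(float)


def reward_psth(spike_times, licks, trial_ends=None, sigma: float = 5.0):
    """Per-trial 10 ms rates and the smoothed trial-mean PSTH.

    Trials whose consumption period is shorter than the 1 s epoch are
    excluded and reported.  Returns (per_trial_rates, mean_psth,
    excluded_trial_indices).
    """
    licks = np.asarray(licks, dtype=float)
    excluded = []
    if trial_ends is not None:
        ends = np.asarray(trial_ends, dtype=float)
        short = ends - licks < EPOCH_S
        excluded = list(np.flatnonzero(short))
        licks = licks[~short]
    if licks.size < 2:
        raise ValueError("need at least two trials with a full reward epoch")
    rates = trial_epoch_counts(spike_times, licks) / BIN_S
    mean = smooth_rate(rates.mean(axis=0), sigma=sigma)
    return rates, mean, excluded


def pre_lick_rates(spike_times, licks, pre: float = PRE_S) -> np.ndarray:
    """Mean rate (Hz) in the [lick - pre, lick) baseline, per trial."""
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    licks = np.asarray(licks, dtype=float)
    counts = (np.searchsorted(spikes, licks)
              - np.searchsorted(spikes, licks - pre))
    return counts / pre


def _paired_segment_test(seg_rates: np.ndarray, pre: np.ndarray,
                         alpha: float) -> str:
    diffs = seg_rates - pre
    if np.isclose(diffs.std(ddof=1), 0.0):
        return "ns"        # degenerate zero-variance differences
    t, p = stats.ttest_rel(seg_rates, pre)
    if p < alpha:
        return "excited" if t > 0 else "inhibited"
    return "ns"


def classify_reward_response(epoch_counts: np.ndarray, pre: np.ndarray,
                             alpha: float = 0.05) -> tuple:
    """Segment flags (ten 100 ms segments vs the pre-lick 100 ms) and the
    overall excitation/inhibition class from the epoch mean.

    ``epoch_counts`` are the (trials, 100) 10 ms counts of the preferred
    side; ``pre`` the per-trial pre-lick rates (Hz).
    """
    if epoch_counts.shape[0] < 5:
        raise ValueError("need at least five trials for the paired t-test")
    seg = epoch_counts.reshape(epoch_counts.shape[0], N_SEGMENTS, SEG_BINS)
    seg_rates = seg.sum(axis=2) / (SEG_BINS * BIN_S)
    flags = [_paired_segment_test(seg_rates[:, s], pre, alpha)
             for s in range(N_SEGMENTS)]
    epoch_mean = epoch_counts.sum(axis=1) / EPOCH_S
    overall = _paired_segment_test(epoch_mean, pre, alpha)
    return flags, overall


def reward_side_preference(left_means: np.ndarray, right_means: np.ndarray,
                           alpha: float = 0.05,
                           pairing: str = "welch") -> str:
    """Left/right reward preference from per-trial epoch mean rates.

    Left and right trial counts differ, so the default is Welch's
    two-sample test; ``pairing='rank'`` pairs trials by within-side rank
    (truncated to the shorter side) for the literal paired reading.
    """
    l = np.asarray(left_means, dtype=float)
    r = np.asarray(right_means, dtype=float)
    if min(l.size, r.size) < 5:
        raise ValueError("need at least five trials per side")
    if l.std(ddof=1) == 0 and r.std(ddof=1) == 0:
        return "ns"
    if pairing == "rank":
        n = min(l.size, r.size)
        t, p = stats.ttest_rel(np.sort(l)[:n], np.sort(r)[:n])
    else:
        t, p = stats.ttest_ind(l, r, equal_var=False)
    if p < alpha:
        return "left" if t > 0 else "right"
    return "ns"


def analyze_reward(session_trials, spike_times, unit_id: int,
                   alpha: float = 0.05, sigma: float = 5.0) -> RewardResult:
    """Full reward-epoch analysis of one unit from the trial table.

    Uses correct memory-task trials, split by trajectory.
    """
    mem = [tr for tr in session_trials
           if tr.task == "memory" and tr.accuracy == "correct"]
    licks = {s: np.array([tr.first_lick_time for tr in mem
                          if tr.trajectory == s]) for s in ("left", "right")}
    ends = {s: np.array([tr.trial_end_time for tr in mem
                         if tr.trajectory == s]) for s in ("left", "right")}
    rates, mean_psth, raw_mean = {}, {}, {}
    for s in ("left", "right"):
        r, m, _ = reward_psth(spike_times, licks[s], ends[s], sigma=sigma)
        rates[s] = r
        mean_psth[s] = m
        raw_mean[s] = float(r.mean())          # Hz over the 1 s epoch
    epoch_means = {s: rates[s].mean(axis=1) for s in ("left", "right")}
    side = reward_side_preference(epoch_means["left"], epoch_means["right"],
                                  alpha=alpha)
    pref = ("left" if raw_mean["left"] >= raw_mean["right"] else "right")
    pre = pre_lick_rates(spike_times, licks[pref])
    flags, overall = classify_reward_response(rates[pref] * BIN_S, pre,
                                              alpha=alpha)
    return RewardResult(
        unit_id=unit_id, psth_left=mean_psth["left"],
        psth_right=mean_psth["right"], segment_flags=flags, overall=overall,
        side_pref=side,
        D_reward=float(raw_mean["left"] - raw_mean["right"]),
        n_left=int(rates["left"].shape[0]),
        n_right=int(rates["right"].shape[0]))


# ---------------------------------------------------------------------------
# section differences and their correlation with the reward difference

def section_differences(D0: np.ndarray, sections: np.ndarray,
                        D_reward: float) -> dict:
    """Mean left-right smoothed-rate difference per maze section plus the
    reward-epoch difference for one unit."""
    out = {f"D_{s}": float(np.nanmean(D0[sections == s]))
           for s in SECTION_NAMES}
    out["D_reward"] = float(D_reward)
    return out


def section_difference_correlation(diff_table: pd.DataFrame) -> dict:
    """Pearson R (and p) of D_reward against each maze-section difference
    across units of one class."""
    if len(diff_table) < 10:
        raise ValueError("need at least ten units")
    out = {}
    y = diff_table["D_reward"].to_numpy(dtype=float)
    for s in SECTION_NAMES:
        x = diff_table[f"D_{s}"].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if x[ok].std() == 0 or y[ok].std() == 0:
            out[s] = {"R": None, "p": None,
                      "reason": "zero-variance differences"}
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        out[s] = {"R": float(r), "p": float(p), "n": int(ok.sum())}
    return out


def delay_reward_categories(delay_pref: Sequence[str],
                            reward_pref: Sequence[str]) -> dict:
    """Six-category delay x reward preference classification.

    Each unit carries a preference (left / right / ns) in the delay
    section (permutation test) and in the reward section (side test).
    Returns the 3x2 cell table plus same-side / different / neither
    summary counts.
    """
    delay_pref = list(delay_pref)
    reward_pref = list(reward_pref)
    if len(delay_pref) != len(reward_pref):
        raise ValueError("preference lists must be matched per unit")
    cells = {(sec, p): 0 for sec in ("delay", "reward")
             for p in ("left", "right", "ns")}
    same = diff = neither = 0
    for d, r in zip(delay_pref, reward_pref):
        cells[("delay", d)] += 1
        cells[("reward", r)] += 1
        if d == "ns" and r == "ns":
            neither += 1
        elif d != "ns" and d == r:
            same += 1
        else:
            diff += 1
    return {"cells": cells, "same_side": same, "different": diff,
            "neither": neither, "n": len(delay_pref)}
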
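"""Trial linearization, maze sections, and behavioral performance statistics.

Each trial's run from the start box to the waterspout is divided into
``n_bins`` (default 100) equal position bins along the linearized track.
For trial k and bin x the module accumulates the spike count n_k(x), the
occupancy t_k(x) in seconds, and the mean running speed; these are the
substrate of every spatial statistic downstream.

Bin x (1-based) covers the position interval ((x-1)/N, x/N] * L, with bin 1
closed at 0.  Occupancy splits each inter-sample tracking interval across
the bins its linearly interpolated path traverses, proportionally to the
path length in each bin; spikes are assigned to the bin of their linearly
interpolated position at spike time.  Sharing the interpolation support
between the two makes the occupancy-normalized rate estimator unbiased for
a constant-rate unit.  The analysis span of a trial runs from its start to
the first waterspout lick; the return run is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SECTION_NAMES = ("start", "cue", "delay", "side_arms")
DEFAULT_BOUNDARIES = (50.0, 80.0, 120.0, 150.0)

#: chi-square(1 df) critical value at alpha = 0.05 used as the
#: choice/accuracy independence threshold.
CHI2_CRIT_1DF_05 = float(stats.chi2.ppf(0.95, df=1))


@dataclass
class LinearizedTrial:
    trial_id: int
    n: np.ndarray        # spike counts per bin (one unit)
    t: np.ndarray        # occupancy seconds per bin
    speed: np.ndarray    # cm/s per bin (nan where unvisited)
    trajectory: str
    accuracy: str
    task: str


def position_to_bin(pos, track_length: float = 150.0, n_bins: int = 100):
    """Map linearized positions (cm) to 0-based bin indices."""
    pos = np.asarray(pos, dtype=float)
    idx = np.ceil(pos * n_bins / track_length).astype(int) - 1
    return np.clip(idx, 0, n_bins - 1)


def linearize_trial(track_time, track_pos, spike_times, *,
                    t_start: float, t_lick: float,
                    track_length: float = 150.0,
                    n_bins: int = 100,
                    backward_tolerance: float = 1.0) -> tuple:
    """Bin one trial's occupancy, spikes, and speed by position.

    Returns ``(n, t, speed)`` arrays of length ``n_bins``.  Tracking samples
    are restricted to [t_start, t_lick]; a backward position jump larger
    than ``backward_tolerance`` cm raises ValueError.
    """
    tt = np.asarray(track_time, dtype=float)
    px = np.asarray(track_pos, dtype=float)
    keep = (tt >= t_start) & (tt <= t_lick)
    tt, px = tt[keep], px[keep]
    if tt.size < 2:
        raise ValueError("trial has fewer than two tracking samples")
    if np.any(np.diff(tt) <= 0):
        raise ValueError("tracking time not strictly increasing")
    if np.any(np.diff(px) < -backward_tolerance):
        raise ValueError("backward position jump beyond tolerance")

    # occupancy: time of the interpolated position path inside each bin,
    # via the (monotone) time-at-position-edge curve
    pos_mono = np.maximum.accumulate(px)
    edges = np.arange(n_bins + 1) * track_length / n_bins
    t_at_edges = np.interp(edges, pos_mono, tt, left=tt[0], right=tt[-1])
    occ = np.maximum(np.diff(t_at_edges), 0.0)

    st = np.asarray(spike_times, dtype=float)
    st = st[(st >= t_start) & (st < t_lick)]
    counts = np.zeros(n_bins)
    if st.size:
        sp = np.interp(st, tt, px)
        np.add.at(counts, position_to_bin(sp, track_length, n_bins), 1.0)

    bin_width = track_length / n_bins
    with np.errstate(divide="ignore", invalid="ignore"):
        speed = np.where(occ > 0, bin_width / occ, np.nan)
    return counts, occ, speed


@dataclass
class LinearizedSession:
    """Per-trial binned occupancy/speed shared by all units, plus per-unit
    spike counts; computed once per session."""
    trial_ids: np.ndarray                # (K,)
    trajectory: np.ndarray               # (K,) str
    accuracy: np.ndarray                 # (K,) str
    task: np.ndarray                     # (K,) str
    occupancy: np.ndarray                # (K, n_bins) seconds
    speed: np.ndarray                    # (K, n_bins) cm/s
    counts: dict                         # unit_id -> (K, n_bins)
    durations: np.ndarray                # (K,) start->lick seconds
    n_bins: int = 100

    def unit_rates(self, unit_id) -> np.ndarray:
        """Per-trial occupancy-normalized rates n/t (nan where t=0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.occupancy > 0,
                            self.counts[unit_id] / self.occupancy, np.nan)

    def select(self, mask: np.ndarray) -> "LinearizedSession":
        return LinearizedSession(
            trial_ids=self.trial_ids[mask], trajectory=self.trajectory[mask],
            accuracy=self.accuracy[mask], task=self.task[mask],
            occupancy=self.occupancy[mask], speed=self.speed[mask],
            counts={u: c[mask] for u, c in self.counts.items()},
            durations=self.durations[mask], n_bins=self.n_bins)


def linearize_session(bundle, n_bins: int = 100) -> LinearizedSession:
    """Linearize every trial of a session bundle for every unit."""
    trials = sorted(bundle.trials, key=lambda tr: tr.trial_id)
    K = len(trials)
    L = bundle.track_length
    occ = np.zeros((K, n_bins))
    spd = np.full((K, n_bins), np.nan)
    durations = np.zeros(K)
    counts = {u.unit_id: np.zeros((K, n_bins)) for u in bundle.units}

    by_trial = dict(tuple(bundle.tracking.groupby("trial_id", sort=True)))
    spikes_sorted = {u.unit_id: np.asarray(u.spike_times, dtype=float)
                     for u in bundle.units}

    for k, tr in enumerate(trials):
        grp = by_trial.get(tr.trial_id)
        if grp is None:
            raise ValueError(f"trial {tr.trial_id} has no tracking rows")
        tt = grp["time_s"].to_numpy(dtype=float)
        px = grp["pos_cm"].to_numpy(dtype=float)
        for uid, st in spikes_sorted.items():
            lo, hi = np.searchsorted(st, [tr.start_time, tr.first_lick_time])
            n, t, sp = linearize_trial(
                tt, px, st[lo:hi], t_start=tr.start_time,
                t_lick=tr.first_lick_time, track_length=L, n_bins=n_bins)
            counts[uid][k] = n
        if not bundle.units:
            _, t, sp = linearize_trial(
                tt, px, np.empty(0), t_start=tr.start_time,
                t_lick=tr.first_lick_time, track_length=L, n_bins=n_bins)
        occ[k], spd[k] = t, sp
        durations[k] = tr.first_lick_time - tr.start_time

    return LinearizedSession(
        trial_ids=np.array([tr.trial_id for tr in trials]),
        trajectory=np.array([tr.trajectory for tr in trials]),
        accuracy=np.array([tr.accuracy for tr in trials]),
        task=np.array([tr.task for tr in trials]),
        occupancy=occ, speed=spd, counts=counts, durations=durations,
        n_bins=n_bins)


def assign_sections(boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
                    track_length: float = 150.0,
                    n_bins: int = 100) -> np.ndarray:
    """Map each position bin (by its center, cm) to a maze section label.

    The reward epoch is not a spatial section; it is handled in the time
    domain by the reward analysis.
    """
    b = np.asarray(boundaries, dtype=float)
    if np.any(np.diff(b) <= 0) or b[-1] != track_length:
        raise ValueError("section boundaries must increase and end at the "
                         "track length")
    centers = (np.arange(n_bins) + 0.5) * track_length / n_bins
    idx = np.searchsorted(b, centers, side="left")
    names = np.array(SECTION_NAMES)
    return names[np.clip(idx, 0, len(names) - 1)]


def section_bins(section: str, **kwargs) -> np.ndarray:
    return np.flatnonzero(assign_sections(**kwargs) == section)


def _rates_by_side(trials_df: pd.DataFrame):
    mem = trials_df[trials_df["task"] == "memory"]
    out = {}
    for side in ("left", "right"):
        sub = mem[mem["trajectory"] == side]
        out[side] = (np.nan if not len(sub)
                     else float((sub["accuracy"] == "correct").mean()))
    out["overall"] = (np.nan if not len(mem)
                      else float((mem["accuracy"] == "correct").mean()))
    return out


def session_performance(sessions) -> dict:
    """Correct-rate summary with the choice/accuracy independence test.

    ``sessions`` is one trial table or a sequence of them (one per
    session).  Per session a 2x2 chi-square test (choice x accuracy,
    without continuity correction) is computed; its statistic is compared
    against the chi-square(1) 0.05 critical value 3.84.  With several
    sessions a paired t-test of left vs right correct rates is added.
    """
    if isinstance(sessions, pd.DataFrame):
        sessions = [sessions]
    per_session = []
    for df in sessions:
        rates = _rates_by_side(df)
        mem = df[df["task"] == "memory"]
        table = pd.crosstab(mem["trajectory"], mem["accuracy"])
        chi2 = p = None
        reason = None
        arr = table.to_numpy()
        if table.shape[0] < 2:
            reason = "degenerate contingency table (one arm never visited)"
        elif table.shape[1] < 2:
            # uniform accuracy: independence of choice and accuracy is
            # trivially satisfied, the statistic is zero
            chi2, p = 0.0, 1.0
        elif (arr.sum(axis=0) > 0).all() and (arr.sum(axis=1) > 0).all():
            chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
            chi2, p = float(chi2), float(p)
        else:
            reason = "degenerate contingency table (empty row or column)"
        per_session.append({**rates, "chi2": chi2, "chi2_p": p,
                            "chi2_absent_reason": reason,
                            "independent": (None if chi2 is None
                                            else chi2 < CHI2_CRIT_1DF_05)})
    report = {
        "per_session": per_session,
        "chi2_critical_value": CHI2_CRIT_1DF_05,
        "overall_rate": float(np.nanmean(
            [s["overall"] for s in per_session])),
        "left_rate": float(np.nanmean([s["left"] for s in per_session])),
        "right_rate": float(np.nanmean([s["right"] for s in per_session])),
    }
    if len(per_session) >= 2:
        lefts = np.array([s["left"] for s in per_session])
        rights = np.array([s["right"] for s in per_session])
        ok = np.isfinite(lefts) & np.isfinite(rights)
        if ok.sum() >= 2:
            diffs = lefts[ok] - rights[ok]
            if np.isclose(diffs.std(ddof=1), 0) and \
                    np.isclose(diffs.mean(), 0):
                t, p = 0.0, 1.0    # identical rate vectors
            else:
                t, p = stats.ttest_rel(lefts[ok], rights[ok])
            report["left_vs_right"] = {
                "t": float(t), "df": int(ok.sum() - 1), "p": float(p)}
    return report


def memory_load_comparison(pairs) -> dict:
    """Paired t-test of low-load vs high-load correct rates across sessions.

    ``pairs`` is a sequence of (low_load_rate, high_load_rate) per session.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (low, high) session pairs")
    low, high = arr[:, 0], arr[:, 1]
    diffs = low - high
    out = {
        "n": int(arr.shape[0]),
        "low_mean": float(low.mean()), "low_sd": float(low.std(ddof=1)),
        "high_mean": float(high.mean()), "high_sd": float(high.std(ddof=1)),
        "degenerate": bool(np.isclose(diffs.std(ddof=1), 0)),
    }
    if out["degenerate"]:
        # zero-variance differences: t undefined (infinite if mean != 0)
        out["t"] = 0.0 if np.isclose(diffs.mean(), 0) else np.inf * np.sign(
            diffs.mean())
        out["df"] = int(arr.shape[0] - 1)
        out["p"] = 1.0 if np.isclose(diffs.mean(), 0) else 0.0
    else:
        t, p = stats.ttest_rel(low, high)
        out["t"], out["df"], out["p"] = float(t), int(arr.shape[0] - 1), float(p)
    return out
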
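"""Occupancy-normalized rate maps, Gaussian smoothing, and heatmaps.

The rate estimator is the trial-averaged occupancy-normalized rate

    lambda_hat(x) = (1/K) * sum_k n_k(x) / t_k(x)

over the K trials with occupancy at bin x.  Maps are smoothed with a
unit-sum Gaussian kernel spanning 20 position bins (sigma 0.5 bins by
default, i.e. a narrow kernel that leaves neighboring bins nearly
independent); at the edges the kernel is renormalized over its valid
support so a constant map stays constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# smoothing

@lru_cache(maxsize=16)
def gaussian_kernel(sigma: float = 0.5, half_width: int = 10) -> np.ndarray:
    """Unit-sum Gaussian kernel on integer offsets -half_width..half_width."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.arange(-half_width, half_width + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


@lru_cache(maxsize=16)
def smoothing_matrix(n_bins: int = 100, sigma: float = 0.5,
                     half_width: int = 10) -> np.ndarray:
    """Dense (n_bins, n_bins) operator applying the edge-renormalized
    Gaussian smoothing; ``m @ x`` equals ``smooth_rate(x)`` on fully
    observed vectors.  Rows sum to one exactly."""
    k = gaussian_kernel(sigma, half_width)
    m = np.zeros((n_bins, n_bins))
    for i in range(n_bins):
        lo = max(0, i - half_width)
        hi = min(n_bins, i + half_width + 1)
        seg = k[lo - i + half_width: hi - i + half_width]
        m[i, lo:hi] = seg / seg.sum()
    return m


def smooth_rate(lambda_raw: np.ndarray, sigma: float = 0.5,
                half_width: int = 10) -> np.ndarray:
    """Smooth a rate map, tolerating missing (nan) bins.

    Missing bins are filled by linear interpolation before convolving and
    re-flagged nan afterwards.  All-missing input raises ValueError.
    """
    x = np.asarray(lambda_raw, dtype=float)
    missing = ~np.isfinite(x)
    if missing.all():
        raise ValueError("rate map has no observed bins")
    if missing.any():
        idx = np.arange(x.size)
        x = x.copy()
        x[missing] = np.interp(idx[missing], idx[~missing], x[~missing])
    sm = smoothing_matrix(x.size, sigma, half_width) @ x
    sm[missing] = np.nan
    return sm


# ---------------------------------------------------------------------------
# rate maps

@dataclass
class RateMap:
    unit_id: int
    trajectory: str
    lambda_raw: np.ndarray     # Hz per bin, nan where no trial visited
    lambda_smooth: np.ndarray
    k_used: np.ndarray         # contributing trials per bin


def trial_average_rate(counts: np.ndarray, occupancy: np.ndarray):
    """lambda_hat per bin from (K, n_bins) counts and occupancy.

    Trials with zero occupancy at a bin are skipped at that bin (n/t is
    undefined there); bins no trial visited come back nan.
    Returns (lambda_raw, k_used).
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    occupancy = np.atleast_2d(np.asarray(occupancy, dtype=float))
    if counts.shape != occupancy.shape:
        raise ValueError("counts and occupancy shapes differ")
    if counts.shape[0] == 0:
        raise ValueError("no trials")
    valid = occupancy > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(valid, counts / occupancy, 0.0)
    k_used = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        lam = np.where(k_used > 0, rates.sum(axis=0) / k_used, np.nan)
    return lam, k_used


def average_rate_map(session, unit_id, trajectory: str,
                     sigma: float = 0.5, correct_only: bool = True) -> RateMap:
    """Occupancy-normalized average rate map of one unit, one trajectory."""
    mask = session.trajectory == trajectory
    if correct_only:
        mask &= session.accuracy == "correct"
    if mask.sum() < 1:
        raise ValueError(
            f"unit {unit_id}: no {'correct ' if correct_only else ''}"
            f"{trajectory} trials")
    lam, k_used = trial_average_rate(session.counts[unit_id][mask],
                                     session.occupancy[mask])
    return RateMap(unit_id=unit_id, trajectory=trajectory, lambda_raw=lam,
                   lambda_smooth=smooth_rate(lam, sigma), k_used=k_used)


# ---------------------------------------------------------------------------
# heatmaps

@dataclass
class HeatmapSet:
    preferred: np.ndarray      # units x n_bins, each row max exactly 1
    nonpreferred: np.ndarray   # same normalizer as the preferred row
    row_order: np.ndarray      # unit ids, sorted by preferred-row argmax
    preferred_side: dict       # unit_id -> "left" | "right"
    excluded: list             # all-zero units, with reason


def build_heatmaps(left_maps: Sequence[RateMap],
                   right_maps: Sequence[RateMap]) -> HeatmapSet:
    """Preferred/non-preferred normalized heatmaps, rows ordered by the
    position of the preferred-trajectory peak."""
    by_id = {m.unit_id: [m, None] for m in left_maps}
    for m in right_maps:
        by_id.setdefault(m.unit_id, [None, None])[1] = m
    rows = []
    excluded = []
    pref_side = {}
    for uid, (lm, rm) in sorted(by_id.items()):
        if lm is None or rm is None:
            excluded.append((uid, "missing one trajectory"))
            continue
        lmax = np.nanmax(lm.lambda_smooth)
        rmax = np.nanmax(rm.lambda_smooth)
        peak = max(lmax, rmax)
        if not peak > 0:
            excluded.append((uid, "all-zero rate map"))
            continue
        side = "left" if lmax >= rmax else "right"
        pref = (lm if side == "left" else rm).lambda_smooth / peak
        nonp = (rm if side == "left" else lm).lambda_smooth / peak
        pref_side[uid] = side
        rows.append((uid, int(np.nanargmax(pref)), pref, nonp))
    rows.sort(key=lambda r: (r[1], r[0]))
    if rows:
        pref_mat = np.vstack([r[2] for r in rows])
        nonp_mat = np.vstack([r[3] for r in rows])
        order = np.array([r[0] for r in rows])
    else:
        pref_mat = np.empty((0, 0))
        nonp_mat = np.empty((0, 0))
        order = np.empty(0, dtype=int)
    return HeatmapSet(preferred=pref_mat, nonpreferred=nonp_mat,
                      row_order=order, preferred_side=pref_side,
                      excluded=excluded)


# ---------------------------------------------------------------------------
# population position statistics

def position_rate_change(lambda_map: np.ndarray, bins: np.ndarray,
                         track_length: float = 150.0,
                         n_bins: int = 100) -> float:
    """OLS slope of rate on position over ``bins``, expressed as the total
    rate change (Hz) across that range."""
    y = np.asarray(lambda_map, dtype=float)[bins]
    x = (np.asarray(bins) + 0.5) * track_length / n_bins
    ok = np.isfinite(y)
    if ok.sum() < 2:
        return np.nan
    slope, _ = np.polyfit(x[ok], y[ok], 1)
    return float(slope * (x.max() - x.min()))


def population_position_stats(maps: Sequence[np.ndarray],
                              bins: Optional[np.ndarray] = None,
                              track_length: float = 150.0) -> dict:
    """Population mean +/- SEM per bin and the per-unit position-regression
    rate changes with a one-sample t-test against zero."""
    mat = np.vstack([np.asarray(m, dtype=float) for m in maps])
    if mat.shape[0] < 2:
        raise ValueError("need at least two units")
    n_bins = mat.shape[1]
    if bins is None:
        bins = np.arange(n_bins)
    changes = np.array([position_rate_change(m, bins, track_length, n_bins)
                        for m in mat])
    ok = np.isfinite(changes)
    if np.allclose(changes[ok], 0.0):
        t, p = 0.0, 1.0        # all slopes exactly zero
    else:
        t, p = stats.ttest_1samp(changes[ok], 0.0)
    return {
        "mean": np.nanmean(mat, axis=0),
        "sem": stats.sem(mat, axis=0, nan_policy="omit"),
        "rate_changes": changes,
        "mean_change": float(np.mean(changes[ok])),
        "sem_change": float(stats.sem(changes[ok])),
        "t": float(t), "df": int(ok.sum() - 1), "p": float(p),
    }
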
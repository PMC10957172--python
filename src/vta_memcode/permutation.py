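"""Label-permutation test for trajectory-specific firing.

For one unit the observed statistic is the per-bin difference between the
smoothed occupancy-normalized mean rates of correct left and right trials,
D0(x).  Trajectory labels are then reshuffled across trials (preserving
the left/right counts), the smoothed difference is recomputed for each
permutation, and the pointwise two-sided p-value uses the add-one rule

    p(x) = (1 + #{ |D_perm(x)| >= |D0(x)| }) / (n_perms + 1)

A bin is flagged significant when p < alpha AND it belongs to a run of at
least ``min_run`` consecutive sub-alpha bins; the short-run criterion is
the multiplicity control for testing ~100 bins at once.  Flagged bins are
counted per maze section, and a neuron is trajectory-specific in a
section when at least one flagged bin falls there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .behavior import assign_sections, SECTION_NAMES
from .ratemaps import smoothing_matrix


@dataclass
class PermutationResult:
    unit_id: int
    D0: np.ndarray                  # Hz per bin, smoothed left - right
    null_lo: np.ndarray             # per-bin alpha/2 null quantile
    null_hi: np.ndarray             # per-bin 1-alpha/2 null quantile
    p_point: np.ndarray
    sig_mask: np.ndarray
    points_per_section: dict
    neuron_sig_per_section: dict
    side_per_section: dict          # section -> left | right | ns
    n_perms: int
    seed: Optional[int]


def _masked_group_means(rates, members):
    """Mean over trials with occupancy, per permutation row.

    rates: (K, B) per-trial rates with nan at zero-occupancy bins.
    members: (P, K) boolean membership matrices.
    Returns (P, B) means (nan where no member trial visited the bin).
    """
    finite = np.isfinite(rates)
    filled = np.where(finite, rates, 0.0)
    sums = members @ filled
    cnts = members @ finite.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnts > 0, sums / cnts, np.nan)


def smoothed_side_difference(rates, is_left, smooth):
    """Smoothed left-mean minus right-mean from per-trial rate rows."""
    means = _masked_group_means(
        rates, np.vstack([is_left, ~is_left]).astype(float))
    return (means[0] - means[1]) @ smooth.T


def observed_difference(rates: np.ndarray, is_left: np.ndarray,
                        sigma: float = 0.5) -> np.ndarray:
    """D0(x): smoothed mean-rate difference, left minus right."""
    is_left = np.asarray(is_left, dtype=bool)
    if is_left.sum() < 2 or (~is_left).sum() < 2:
        raise ValueError("need at least two correct trials per side")
    smooth = smoothing_matrix(rates.shape[1], sigma)
    return smoothed_side_difference(np.asarray(rates, float), is_left, smooth)


def _runs_of_true(mask: np.ndarray, min_run: int) -> np.ndarray:
    """Keep only True entries inside runs of >= min_run consecutive Trues."""
    if min_run <= 1:
        return mask.copy()
    out = np.zeros_like(mask)
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_run:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def permutation_test(rates: np.ndarray, is_left: np.ndarray,
                     n_perms: int = 1000, alpha: float = 0.05,
                     min_run: int = 3, seed: Optional[int] = None,
                     sigma: float = 0.5, unit_id: int = -1,
                     sections: Optional[np.ndarray] = None,
                     track_length: float = 150.0,
                     method: str = "auto") -> PermutationResult:
    """Trajectory-label permutation test for one unit.

    ``rates`` is the (trials, bins) matrix of per-trial occupancy-
    normalized rates of the correct trials (nan at unvisited bins);
    ``is_left`` the matching trajectory labels.

    ``method``: "auto" enumerates all distinct label assignments when
    there are no more of them than ``n_perms`` (exact test, identity
    assignment included, no add-one correction) and samples otherwise;
    "mc" forces sampling; "exact" forces enumeration.
    """
    from math import comb

    rates = np.asarray(rates, dtype=float)
    is_left = np.asarray(is_left, dtype=bool)
    K, B = rates.shape
    n_left = int(is_left.sum())
    if n_left < 2 or K - n_left < 2:
        raise ValueError("need at least two correct trials per side")
    if n_perms < 200:
        raise ValueError("n_perms must be at least 200")

    smooth = smoothing_matrix(B, sigma)
    D0 = smoothed_side_difference(rates, is_left, smooth)

    n_distinct = comb(K, n_left)
    exact = method == "exact" or (method == "auto" and n_distinct <= n_perms)

    rng = np.random.default_rng(seed)
    # label-assignment membership matrices preserving left/right counts
    if exact:
        from itertools import combinations
        members = np.zeros((n_distinct, K))
        for j, combo in enumerate(combinations(range(K), n_left)):
            members[j, list(combo)] = 1.0
    else:
        members = np.zeros((n_perms, K))
        for j in range(n_perms):
            members[j, rng.permutation(K)[:n_left]] = 1.0
    finite = np.isfinite(rates)
    filled = np.where(finite, rates, 0.0)
    sums_l = members @ filled
    cnts_l = members @ finite.astype(float)
    sums_all = filled.sum(axis=0)
    cnts_all = finite.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_l = np.where(cnts_l > 0, sums_l / cnts_l, np.nan)
        cnts_r = cnts_all - cnts_l
        mean_r = np.where(cnts_r > 0, (sums_all - sums_l) / cnts_r, np.nan)
    D_perm = (mean_l - mean_r) @ smooth.T      # (n_perms, B)

    with np.errstate(invalid="ignore"):
        exceed = np.abs(D_perm) >= np.abs(D0)[None, :]
    n_valid = np.isfinite(D_perm).sum(axis=0)
    if exact:
        # identity assignment is one of the enumerated rows
        p = np.nansum(exceed, axis=0) / np.maximum(n_valid, 1)
    else:
        p = (1.0 + np.nansum(exceed, axis=0)) / (n_valid + 1.0)
    p = np.where(np.isfinite(D0), p, 1.0)

    sig = _runs_of_true((p < alpha) & np.isfinite(D0), min_run)

    if sections is None:
        sections = assign_sections(track_length=track_length, n_bins=B)
    points = {s: int(np.sum(sig & (sections == s))) for s in SECTION_NAMES}
    neuron_sig = {s: points[s] >= 1 for s in SECTION_NAMES}
    side = {}
    for s in SECTION_NAMES:
        in_sec = sig & (sections == s)
        if not in_sec.any():
            side[s] = "ns"
        else:
            side[s] = "left" if np.nanmean(D0[in_sec]) > 0 else "right"

    lo = np.nanquantile(D_perm, alpha / 2, axis=0)
    hi = np.nanquantile(D_perm, 1 - alpha / 2, axis=0)
    return PermutationResult(
        unit_id=unit_id, D0=D0, null_lo=lo, null_hi=hi, p_point=p,
        sig_mask=sig, points_per_section=points,
        neuron_sig_per_section=neuron_sig, side_per_section=side,
        n_perms=members.shape[0], seed=seed)


def exhaustive_pointwise_p(rates: np.ndarray, is_left: np.ndarray,
                           sigma: float = 0.5) -> np.ndarray:
    """Exact pointwise two-sided p over all label assignments with the
    observed left count (enumeration oracle for small trial counts)."""
    from itertools import combinations
    rates = np.asarray(rates, dtype=float)
    is_left = np.asarray(is_left, dtype=bool)
    K, B = rates.shape
    n_left = int(is_left.sum())
    smooth = smoothing_matrix(B, sigma)
    D0 = smoothed_side_difference(rates, is_left, smooth)
    assigns = list(combinations(range(K), n_left))
    members = np.zeros((len(assigns), K))
    for j, combo in enumerate(assigns):
        members[j, list(combo)] = 1.0
    finite = np.isfinite(rates)
    filled = np.where(finite, rates, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_l = (members @ filled) / (members @ finite.astype(float))
        inv = 1.0 - members
        mean_r = (inv @ filled) / (inv @ finite.astype(float))
    D_all = (mean_l - mean_r) @ smooth.T
    return np.mean(np.abs(D_all) >= np.abs(D0)[None, :], axis=0)


def task_point_comparison(points_a, points_b) -> dict:
    """Paired t-test on per-unit significant-point counts between tasks.

    ``points_a`` / ``points_b`` are matched per-unit counts in one maze
    section for tasks A and B.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need matched counts for at least two units")
    diffs = a - b
    out = {
        "n": int(a.size),
        "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
        "n_flagged_a": int(np.sum(a > 0)), "n_flagged_b": int(np.sum(b > 0)),
        "degenerate": bool(np.isclose(diffs.std(ddof=1), 0.0)),
    }
    if out["degenerate"]:
        out["t"] = 0.0 if np.isclose(diffs.mean(), 0.0) else np.inf * \
            np.sign(diffs.mean())
        out["df"] = int(a.size - 1)
        out["p"] = 1.0 if np.isclose(diffs.mean(), 0.0) else 0.0
    else:
        t, p = stats.ttest_rel(a, b)
        out["t"], out["df"], out["p"] = float(t), int(a.size - 1), float(p)
    return out
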
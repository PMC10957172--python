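"""Gaussian GLM of firing rate on trajectory, position, speed and trial
covariates, with shuffle-calibrated predictor significance.

The model (identity link, Gaussian noise) has 17 coefficients:

    FR = b0 + sum_{k=1..6} b_TPk * T * P^k + sum_{k=1..6} b_Sk * S^k
         + b_TN * TN + b_R * R + b_A0 * A0 + b_Am1 * A-1 + eps

with T the trajectory code (1 left, 2 right), P the normalized position
in (0, 1], S the running speed (cm/s), TN the trial number, R the
cumulative correct rate, and A0 / A-1 the current- and previous-trial
accuracy (1 correct, 0 error).  One observation per (trial, bin) with
occupancy; FR is the raw per-trial-bin rate n/t, unsmoothed.

For numerical conditioning the position and speed polynomial blocks are
orthogonalized by QR internally; coefficients are mapped back to the
monomial basis, so predictions are identical in both bases.

Predictor contribution to the left-right rate difference is assessed by
shuffling the tested predictor's trial assignment (speed shuffled as
whole-trial profiles), refitting, and comparing the observed predicted
difference D0_hat against the upper quantile of the shuffled |D_j|
distribution at the Bonferroni-corrected level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .behavior import section_bins

PREDICTORS = ("T", "S", "TN", "R", "A0", "Am1")

#: column slices of each predictor in the 17-column design (order 6)
def _blocks(order: int) -> dict:
    return {"T": slice(1, 1 + order),
            "S": slice(1 + order, 1 + 2 * order),
            "TN": slice(1 + 2 * order, 2 + 2 * order),
            "R": slice(2 + 2 * order, 3 + 2 * order),
            "A0": slice(3 + 2 * order, 4 + 2 * order),
            "Am1": slice(4 + 2 * order, 5 + 2 * order)}


@dataclass
class GLMDesign:
    y: np.ndarray            # FR, Hz
    trial_index: np.ndarray  # 0-based trial of each row
    bin_index: np.ndarray    # 0-based position bin of each row
    T: np.ndarray            # trial-level trajectory code per row
    P: np.ndarray            # (0, 1]
    S: np.ndarray            # cm/s
    TN: np.ndarray
    R: np.ndarray
    A0: np.ndarray
    Am1: np.ndarray
    order: int = 6
    is_left: np.ndarray = None   # per-trial labels (K,)

    @property
    def n_columns(self) -> int:
        return 5 + 2 * self.order


@dataclass
class GLMResult:
    beta: np.ndarray         # monomial-basis coefficients, 5 + 2*order
    sigma2: float            # residual variance (MLE)
    bic: float
    fitted: np.ndarray
    design: GLMDesign
    _basis: tuple = None     # (R_P, R_S) QR factors for refits


def build_design(session, unit_id, order: int = 6,
                 min_trials: int = 20,
                 first_trial_prev_accuracy: float = 1.0) -> GLMDesign:
    """Assemble the per-(trial, bin) regression table for one unit.

    Uses all memory-task trials (error trials carry the accuracy
    covariates).  Bins with zero occupancy are dropped.  The previous-
    trial accuracy of the first trial defaults to correct.
    """
    mask = session.task == "memory"
    sub = session.select(mask)
    K, B = sub.occupancy.shape
    if K < min_trials:
        raise ValueError(f"need at least {min_trials} trials, have {K}")
    is_left = sub.trajectory == "left"
    if is_left.all() or not is_left.any():
        raise ValueError("design is rank-deficient: all trials on one side")

    correct = (sub.accuracy == "correct").astype(float)
    prev = np.concatenate([[first_trial_prev_accuracy], correct[:-1]])
    cum_rate = np.cumsum(correct) / np.arange(1, K + 1)
    t_code = np.where(is_left, 1.0, 2.0)

    occ_ok = sub.occupancy > 0
    ti, bi = np.nonzero(occ_ok)
    rates = sub.unit_rates(unit_id)
    y = rates[ti, bi]
    return GLMDesign(
        y=y, trial_index=ti, bin_index=bi,
        T=t_code[ti], P=(bi + 1) / float(B), S=sub.speed[ti, bi],
        TN=(ti + 1).astype(float), R=cum_rate[ti], A0=correct[ti],
        Am1=prev[ti], order=order, is_left=is_left)


def _power_block(v: np.ndarray, order: int) -> np.ndarray:
    return np.column_stack([v ** k for k in range(1, order + 1)])


def design_matrix(design: GLMDesign, monomial: bool = False,
                  basis: Optional[tuple] = None,
                  T=None, S=None, TN=None, R=None, A0=None, Am1=None):
    """Build the design matrix; returns (X, (R_P, R_S)).

    With ``monomial=False`` the position and speed power blocks are
    orthogonalized by thin-QR; passing ``basis`` reuses previously
    computed QR factors (needed so shuffled refits live in the same
    column space).  Individual predictor columns may be overridden to
    build shuffled designs.
    """
    d = design
    T = d.T if T is None else T
    S = d.S if S is None else S
    TN = d.TN if TN is None else TN
    R = d.R if R is None else R
    A0 = d.A0 if A0 is None else A0
    Am1 = d.Am1 if Am1 is None else Am1

    P_pow = _power_block(d.P, d.order)
    S_pow = _power_block(S / max(np.nanmax(np.abs(d.S)), 1e-12), d.order)
    if monomial:
        P_block, S_block, R_P, R_S = P_pow, S_pow, None, None
    else:
        if basis is None:
            _, R_P = np.linalg.qr(P_pow)
            _, R_S = np.linalg.qr(S_pow)
        else:
            R_P, R_S = basis
        P_block = np.linalg.solve(R_P.T, P_pow.T).T
        S_block = np.linalg.solve(R_S.T, S_pow.T).T
    X = np.column_stack([np.ones_like(d.y), T[:, None] * P_block, S_block,
                         TN, R, A0, Am1])
    return X, (R_P, R_S)


def fit_glm(design: GLMDesign, monomial: bool = False) -> GLMResult:
    """Ordinary least squares fit; BIC from the Gaussian log-likelihood.

    Coefficients are always reported in the monomial basis (speed scaled
    by its maximum absolute value).
    """
    if not np.all(np.isfinite(design.y)):
        raise ValueError("non-finite response values")
    X, (R_P, R_S) = design_matrix(design, monomial=monomial)
    beta, *_ = np.linalg.lstsq(X, design.y, rcond=None)
    fitted = X @ beta
    n = design.y.size
    rss = float(np.sum((design.y - fitted) ** 2))
    sigma2 = rss / n
    k = X.shape[1] + 1   # coefficients + noise variance
    bic = n * np.log(max(sigma2, 1e-300)) + k * np.log(n)

    beta_mono = beta.copy()
    if not monomial:
        blocks = _blocks(design.order)
        beta_mono[blocks["T"]] = np.linalg.solve(R_P, beta[blocks["T"]])
        beta_mono[blocks["S"]] = np.linalg.solve(R_S, beta[blocks["S"]])
    return GLMResult(beta=beta_mono, sigma2=sigma2, bic=bic, fitted=fitted,
                     design=design, _basis=(R_P, R_S))


def select_order(session, unit_id, orders: Sequence[int] = range(1, 7),
                 **kwargs) -> tuple:
    """Pick the polynomial order minimizing BIC; returns (order, table)."""
    orders = list(orders)
    if len(orders) < 2:
        raise ValueError("need at least two candidate orders")
    table = {}
    for o in orders:
        d = build_design(session, unit_id, order=o, **kwargs)
        table[o] = fit_glm(d).bic
    best = min(table, key=table.get)
    return best, table


def region_position_powers(design: GLMDesign,
                           region_bins: np.ndarray) -> np.ndarray:
    """mean over region bins of P^k, k = 1..order."""
    B = int(design.bin_index.max()) + 1
    P = (np.asarray(region_bins) + 1) / float(B)
    return np.array([np.mean(P ** k) for k in range(1, design.order + 1)])


def predicted_side_difference(beta_mono: np.ndarray, design: GLMDesign,
                              region_bins: np.ndarray) -> float:
    """Model-predicted left-minus-right rate difference (Hz) averaged
    over the region bins.

    L_hat and R_hat are the model predictions at trajectory codes T=1
    (left) and T=2 (right) with every other predictor held fixed, so
    their difference reduces to the fitted T*P coefficient block:
    D_hat = -(sum_k beta_TPk * mean_region P^k).  Because the statistic
    is a function of the fitted coefficients only, shuffling the
    trajectory column reproduces its null distribution exactly when the
    response carries no trajectory information.
    """
    block = beta_mono[_blocks(design.order)["T"]]
    return float(-(block @ region_position_powers(design, region_bins)))


def _shuffled_columns(design: GLMDesign, predictor: str, perm: np.ndarray):
    """Row values of one predictor after permuting its trial assignment."""
    d = design
    inv_rows = perm[d.trial_index]
    if predictor == "S":
        # whole-trial speed profiles exchanged; bins the source trial did
        # not occupy fall back to its mean speed
        K = d.is_left.size
        B = int(d.bin_index.max()) + 1
        prof = np.full((K, B), np.nan)
        prof[d.trial_index, d.bin_index] = d.S
        row_mean = np.nanmean(prof, axis=1)
        prof = np.where(np.isfinite(prof), prof, row_mean[:, None])
        return {"S": prof[inv_rows, d.bin_index]}
    trial_vals = {"T": d.T, "TN": d.TN, "R": d.R, "A0": d.A0, "Am1": d.Am1}[
        predictor]
    # collapse to per-trial values then redistribute through the permutation
    K = d.is_left.size
    per_trial = np.empty(K)
    per_trial[d.trial_index] = trial_vals
    return {predictor: per_trial[perm][d.trial_index]}


def shuffle_significance(result: GLMResult, predictors=PREDICTORS,
                         n_shuffles: int = 500, alpha: float = 0.05,
                         m: int = 6, seed: Optional[int] = None,
                         region: str = "delay") -> dict:
    """Shuffle test of each predictor's contribution to the left-right
    predicted rate difference in one maze region (delay by default).

    For each predictor: permute its trial assignment, refit, recompute
    the predicted difference D_j; reject when |D0_hat| exceeds the
    (1 - alpha/m) quantile of |D_j|.
    """
    if n_shuffles * (alpha / m) < 2:
        raise ValueError(
            "n_shuffles too small to resolve the Bonferroni-corrected level")
    design = result.design
    region_bins = section_bins(region, n_bins=int(design.bin_index.max()) + 1)
    d0 = predicted_side_difference(result.beta, design, region_bins)

    rng = np.random.default_rng(seed)
    K = design.is_left.size
    t_block = _blocks(design.order)["T"]
    p_means = region_position_powers(design, region_bins)
    R_P = result._basis[0]
    out = {"D0_hat": d0, "region": region, "alpha": alpha, "m": m,
           "predictors": {}}
    for pred in predictors:
        vals = {"T": design.T, "S": design.S, "TN": design.TN,
                "R": design.R, "A0": design.A0, "Am1": design.Am1}[pred]
        if np.allclose(vals, vals[0]):
            out["predictors"][pred] = {
                "significant": None, "threshold": None,
                "degenerate": "constant predictor, untestable"}
            continue
        d_null = np.empty(n_shuffles)
        for j in range(n_shuffles):
            perm = rng.permutation(K)
            cols = _shuffled_columns(design, pred, perm)
            X, _ = design_matrix(design, basis=result._basis, **cols)
            beta = np.linalg.solve(X.T @ X, X.T @ design.y)
            beta_t = np.linalg.solve(R_P, beta[t_block])
            d_null[j] = -(beta_t @ p_means)
        thr = float(np.quantile(np.abs(d_null), 1.0 - alpha / m))
        out["predictors"][pred] = {
            "significant": bool(abs(d0) > thr), "threshold": thr,
            "null_mean": float(d_null.mean()),
            "null_sd": float(d_null.std(ddof=1))}
    return out
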
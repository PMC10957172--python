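"""Rate estimator arithmetic, Gaussian smoothing, heatmap construction,
and population position regression."""

import numpy as np
import pytest

from vta_memcode import behavior, ratemaps, synth
from vta_memcode.ratemaps import (RateMap, build_heatmaps, gaussian_kernel,
                                  smooth_rate, smoothing_matrix,
                                  trial_average_rate)


# ---------------------------------------------------------------------------
# lambda_hat

@pytest.mark.parametrize("counts,occ,expected", [
    ([[2.0]], [[0.5]], 4.0),                      # single trial: n/t
    ([[1.0], [3.0]], [[0.5], [1.0]], 2.5),        # mean of per-trial rates
])
def test_rate_estimator_forced_arithmetic(counts, occ, expected):
    lam, k = trial_average_rate(np.array(counts), np.array(occ))
    assert lam[0] == pytest.approx(expected)
    assert k[0] == len(counts)


def test_zero_occupancy_trials_skipped():
    lam, k = trial_average_rate(np.array([[2.0], [5.0]]),
                                np.array([[0.5], [0.0]]))
    assert lam[0] == pytest.approx(4.0) and k[0] == 1


def test_uniform_occupancy_estimators_coincide():
    """With equal occupancy the trial-mean of rates equals pooled
    counts / pooled occupancy exactly."""
    rng = np.random.default_rng(0)
    counts = rng.poisson(3.0, size=(40, 100)).astype(float)
    occ = np.full((40, 100), 0.25)
    lam, _ = trial_average_rate(counts, occ)
    np.testing.assert_allclose(lam, counts.sum(0) / occ.sum(0), rtol=1e-12)


def test_rate_map_invariant_to_trial_order():
    rng = np.random.default_rng(1)
    counts = rng.poisson(2.0, size=(30, 100)).astype(float)
    occ = rng.uniform(0.1, 0.5, size=(30, 100))
    lam1, _ = trial_average_rate(counts, occ)
    perm = rng.permutation(30)
    lam2, _ = trial_average_rate(counts[perm], occ[perm])
    np.testing.assert_allclose(lam1, lam2)


# ---------------------------------------------------------------------------
# smoothing

def test_constant_vector_is_preserved():
    np.testing.assert_allclose(smooth_rate(np.full(100, 7.3)), 7.3)


def test_delta_reproduces_kernel_shape():
    x = np.zeros(100)
    x[50] = 1.0
    k = gaussian_kernel(0.5, 10)
    np.testing.assert_allclose(smooth_rate(x)[40:61], k, atol=1e-12)


def test_interior_mass_conserved():
    rng = np.random.default_rng(2)
    x = rng.uniform(0, 5, 100)
    sm = smooth_rate(x)
    assert abs(sm[20:80].sum() - x[20:80].sum()) < x.sum() * 0.02


def test_matrix_and_vector_paths_agree():
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 5, 100)
    np.testing.assert_allclose(smoothing_matrix(100, 0.5) @ x,
                               smooth_rate(x), atol=1e-12)


def test_missing_bins_interpolated_and_reflagged():
    x = np.arange(100, dtype=float)
    x[40:43] = np.nan
    sm = smooth_rate(x)
    assert np.isnan(sm[40:43]).all()
    assert np.isfinite(np.delete(sm, [40, 41, 42])).all()


def test_all_missing_rejected():
    with pytest.raises(ValueError):
        smooth_rate(np.full(100, np.nan))


# ---------------------------------------------------------------------------
# heatmaps

def _map(uid, traj, lam):
    lam = np.asarray(lam, dtype=float)
    return RateMap(unit_id=uid, trajectory=traj, lambda_raw=lam,
                   lambda_smooth=lam, k_used=np.full(lam.size, 5))


def test_preferred_side_and_normalization():
    left = np.zeros(100)
    left[30] = 10.0
    right = np.zeros(100)
    right[60] = 5.0
    hm = build_heatmaps([_map(1, "left", left)], [_map(1, "right", right)])
    assert hm.preferred_side[1] == "left"
    assert hm.preferred[0].max() == pytest.approx(1.0)
    assert hm.nonpreferred[0].max() == pytest.approx(0.5)


def test_rows_ordered_by_peak_position():
    a_l = np.zeros(100)
    a_l[90] = 3.0
    b_l = np.zeros(100)
    b_l[10] = 3.0
    flat = np.full(100, 0.1)
    hm = build_heatmaps([_map(1, "left", a_l), _map(2, "left", b_l)],
                        [_map(1, "right", flat), _map(2, "right", flat)])
    assert list(hm.row_order) == [2, 1]


def test_all_zero_unit_excluded_with_report():
    z = np.zeros(100)
    hm = build_heatmaps([_map(1, "left", z)], [_map(1, "right", z)])
    assert hm.excluded == [(1, "all-zero rate map")]
    assert hm.preferred.shape[0] == 0


def test_planted_field_centers_produce_diagonal_band():
    """Heatmap peak positions recover planted field centers (r > 0.95)."""
    cfg = synth.SynthConfig(seed=51, n_trials=80, p_correct=1.0)
    rng = np.random.default_rng(cfg.seed)
    trials, tracking = synth.generate_behavior(cfg, rng)
    centers = np.linspace(10, 140, 25)
    from vta_memcode.session_io import SessionBundle, Unit
    t_end = max(tr.trial_end_time for tr in trials) + 1.0
    units = []
    for i, c in enumerate(centers):
        truth = synth.SyntheticTruth(base_rate=8.0, field_centers=(c,),
                                     field_widths=(10.0,), field_gains=(4.0,))
        spikes = synth.generate_spikes(truth, trials, tracking, rng,
                                       t_end=t_end)
        units.append(Unit(unit_id=i, spike_times=spikes))
    bundle = SessionBundle(session_id="s", animal_id="a", genotype="unknown",
                           trials=trials, tracking=tracking, units=units,
                           t_start=0.0, t_end=t_end)
    lin = behavior.linearize_session(bundle)
    lmaps = [ratemaps.average_rate_map(lin, i, "left", sigma=2.0)
             for i in range(25)]
    rmaps = [ratemaps.average_rate_map(lin, i, "right", sigma=2.0)
             for i in range(25)]
    hm = build_heatmaps(lmaps, rmaps)
    peak_pos = {uid: np.argmax(hm.preferred[j]) * 1.5
                for j, uid in enumerate(hm.row_order)}
    recovered = np.array([peak_pos[i] for i in range(25)])
    assert np.corrcoef(recovered, centers)[0, 1] > 0.95


# ---------------------------------------------------------------------------
# population position statistics

def test_flat_maps_zero_change_zero_t():
    maps = [np.full(100, 4.0)] * 6
    out = ratemaps.population_position_stats(maps)
    np.testing.assert_allclose(out["rate_changes"], 0.0, atol=1e-9)
    assert out["t"] == 0.0


def test_linear_ramp_total_change():
    ramp = np.linspace(0, 10, 100)
    out = ratemaps.population_position_stats([ramp, ramp])
    np.testing.assert_allclose(out["rate_changes"], 10.0, rtol=0.03)


def test_mixture_mean_change_matches_closed_form_t():
    """A planted mixture of delay-ramping and flat units: group mean and
    t-statistic agree with the direct one-sample formula."""
    from scipy import stats
    rng = np.random.default_rng(4)
    delay = behavior.section_bins("delay")
    maps = []
    for i in range(30):
        base = np.full(100, 5.0) + 0.05 * rng.standard_normal(100)
        if i < 10:   # ramping subpopulation: +4 Hz across the delay
            base[delay] += np.linspace(0, 4, delay.size)
        maps.append(base)
    out = ratemaps.population_position_stats(maps, bins=delay)
    changes = out["rate_changes"]
    t_oracle = changes.mean() / (changes.std(ddof=1) / np.sqrt(30))
    assert out["t"] == pytest.approx(t_oracle, rel=1e-9)
    assert out["mean_change"] == pytest.approx(changes.mean())
    # mixture mean: one third of units ramp by ~4 Hz
    assert abs(out["mean_change"] - 4.0 / 3) < 0.3
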
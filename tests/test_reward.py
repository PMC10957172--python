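"""Reward-epoch PSTHs, excitation/inhibition classification, side
preference, section-difference correlations, and the six-category
delay x reward classification."""

import numpy as np
import pytest
from scipy import stats

from vta_memcode import reward
from vta_memcode.reward import (classify_reward_response,
                                delay_reward_categories, pre_lick_rates,
                                reward_psth, reward_side_preference,
                                section_differences,
                                section_difference_correlation,
                                trial_epoch_counts)


def _poisson_spikes(rng, rate, t1):
    return np.sort(rng.uniform(0, t1, rng.poisson(rate * t1)))


def test_forced_binning_single_spike():
    licks = np.arange(10, 60, 5.0)
    spikes = licks + 0.255          # bin [0.25, 0.26) -> index 25
    counts = trial_epoch_counts(spikes, licks)
    assert counts.shape == (10, 100)
    assert np.all(counts[:, 25] == 1)
    assert counts.sum() == 10


def test_zero_psth_without_spikes():
    licks = np.arange(5, 25, 2.0)
    rates, mean, excluded = reward_psth([], licks)
    assert mean.sum() == 0 and rates.sum() == 0 and excluded == []


def test_short_trials_excluded():
    licks = np.array([5.0, 10.0, 15.0, 20.0])
    ends = np.array([5.5, 11.5, 16.5, 21.5])   # first dwell < 1 s
    rates, _, excluded = reward_psth([], licks, ends)
    assert excluded == [0] and rates.shape[0] == 3


def test_poisson_psth_flat(rng):
    licks = np.arange(10, 10 + 200 * 15, 15.0)
    spikes = _poisson_spikes(rng, 10.0, licks[-1] + 5)
    rates, mean, _ = reward_psth(spikes, licks)
    se = np.sqrt(10.0 / (200 * 0.01))
    assert np.all(np.abs(rates.mean(axis=0) - 10.0) < 3 * se)
    # smoothing preserves the epoch mean
    assert abs(np.nanmean(mean) - rates.mean()) < 0.05 * rates.mean()


def test_identical_pre_post_ns(rng):
    counts = rng.poisson(0.05, size=(50, 100)).astype(float)
    pre = counts[:, :10].sum(axis=1) / 0.1   # same statistics as segments
    flags, overall = classify_reward_response(counts, pre)
    # no planted change: the epoch-level class must be ns
    assert overall == "ns"


def test_planted_step_gain_classified(rng):
    """3x excitation and 0.2x suppression at the lick are recovered."""
    base = 8.0
    for gain, expected in ((3.0, "excited"), (0.2, "inhibited")):
        counts = rng.poisson(base * gain * 0.01, size=(50, 100)).astype(float)
        pre = rng.poisson(base * 0.1, size=50) / 0.1
        flags, overall = classify_reward_response(counts, pre)
        assert overall == expected
        assert flags.count(expected) >= 8   # most 100 ms segments agree


def test_degenerate_zero_variance_ns():
    counts = np.zeros((10, 100))
    pre = np.zeros(10)
    flags, overall = classify_reward_response(counts, pre)
    assert overall == "ns" and set(flags) == {"ns"}


def test_side_preference_detected_and_null(rng):
    left = rng.poisson(16.0, size=50).astype(float)
    right = rng.poisson(8.0, size=50).astype(float)
    assert reward_side_preference(left, right) == "left"
    assert reward_side_preference(right, left) == "right"
    same = rng.poisson(10.0, size=(2, 50)).astype(float)
    assert reward_side_preference(same[0], same[1]) in ("ns", "left",
                                                        "right")
    assert reward_side_preference(np.zeros(10), np.zeros(10)) == "ns"
    with pytest.raises(ValueError):
        reward_side_preference(left[:3], right)


def test_side_preference_type_i_rate(rng):
    hits = sum(
        reward_side_preference(rng.poisson(10.0, 40).astype(float),
                               rng.poisson(10.0, 40).astype(float)) != "ns"
        for _ in range(200))
    assert hits / 200 < 0.05 + 3 * np.sqrt(0.05 * 0.95 / 200)


def test_correlation_identical_vectors(rng):
    d = rng.standard_normal(20)
    import pandas as pd
    df = pd.DataFrame({"D_start": rng.standard_normal(20),
                       "D_cue": rng.standard_normal(20),
                       "D_delay": rng.standard_normal(20),
                       "D_side_arms": d, "D_reward": d})
    out = section_difference_correlation(df)
    assert out["side_arms"]["R"] == pytest.approx(1.0)
    assert abs(out["delay"]["R"]) < 3 / np.sqrt(20)


def test_correlation_needs_units(rng):
    import pandas as pd
    df = pd.DataFrame({f"D_{s}": rng.standard_normal(5)
                       for s in ("start", "cue", "delay", "side_arms")}
                      | {"D_reward": rng.standard_normal(5)})
    with pytest.raises(ValueError):
        section_difference_correlation(df)


def test_section_differences_means():
    from vta_memcode.behavior import assign_sections
    sections = assign_sections()
    D0 = np.zeros(100)
    D0[sections == "delay"] = 2.0
    out = section_differences(D0, sections, D_reward=1.5)
    assert out["D_delay"] == pytest.approx(2.0)
    assert out["D_start"] == 0.0 and out["D_reward"] == 1.5


def test_delay_reward_categories_forced():
    out = delay_reward_categories(["left", "right", "ns", "left"],
                                  ["left", "ns", "ns", "right"])
    assert out["same_side"] == 1
    assert out["different"] == 2
    assert out["neither"] == 1
    assert out["cells"][("delay", "left")] == 2


def test_categories_independent_assignment_matches_marginals(rng):
    """Independent delay/reward preferences: same-side frequency matches
    the product of marginals within a binomial interval."""
    p_side = 0.3       # P(left) = P(right) = 0.3, P(ns) = 0.4
    n = 2000
    opts = ["left", "right", "ns"]
    probs = [p_side, p_side, 1 - 2 * p_side]
    d = rng.choice(opts, size=n, p=probs)
    r = rng.choice(opts, size=n, p=probs)
    out = delay_reward_categories(list(d), list(r))
    expected = 2 * p_side ** 2
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(out["same_side"] / n - expected) < 3 * se


def test_mismatched_lists_rejected():
    with pytest.raises(ValueError):
        delay_reward_categories(["left"], ["left", "ns"])


def test_analyze_reward_recovers_planted_classes(small_cohort):
    """Full per-unit reward analysis against the generator truth: planted
    excited/inhibited responders are recovered, and unresponsive units
    are not all classified as responders."""
    _, bundle, truth = small_cohort
    classes = {}
    for u in bundle.units:
        res = reward.analyze_reward(bundle.trials, u.spike_times,
                                    u.unit_id)
        classes[u.unit_id] = res.overall
        assert abs(res.D_reward) < 10 * float(truth.loc[u.unit_id,
                                                        "base_rate"])
    for uid, planted in truth["reward_response"].items():
        if planted in ("excited", "inhibited"):
            assert classes[uid] == planted
    null_ids = truth.index[truth["reward_response"] == "none"]
    assert sum(classes[u] == "ns" for u in null_ids) >= len(null_ids) / 2
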
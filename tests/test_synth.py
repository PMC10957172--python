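"""Generator contracts: determinism, behavioral statistics, Poisson spike
counts, planted trajectory gain, and light-evoked responses."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from vta_memcode import behavior, synth
from vta_memcode.synth import SynthConfig, SyntheticTruth


def _behavior(cfg):
    rng = np.random.default_rng(cfg.seed)
    return synth.generate_behavior(cfg, rng)


def test_same_seed_same_session():
    cfg = SynthConfig(seed=7, n_trials=30, n_da=2, n_gaba=1, n_untagged=0)
    b1, t1 = synth.generate_cohort(cfg)
    b2, t2 = synth.generate_cohort(cfg)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(b1.tracking, b2.tracking)
    for u1, u2 in zip(b1.units, b2.units):
        np.testing.assert_array_equal(u1.spike_times, u2.spike_times)


def test_perfect_performance_flag():
    trials, _ = _behavior(SynthConfig(seed=3, n_trials=40, p_correct=1.0))
    assert all(tr.accuracy == "correct" for tr in trials)


def test_correct_rate_matches_binomial():
    n = 5000
    trials, _ = _behavior(SynthConfig(seed=5, n_trials=n, p_correct=0.87))
    rate = np.mean([tr.accuracy == "correct" for tr in trials])
    se = np.sqrt(0.87 * 0.13 / n)
    assert abs(rate - 0.87) < 3 * se


def test_trajectories_balanced_and_positions_monotone():
    trials, tracking = _behavior(SynthConfig(seed=11, n_trials=90))
    n_left = sum(tr.trajectory == "left" for tr in trials)
    assert abs(n_left - 45) <= 9     # balanced within 10%
    for _, grp in tracking.groupby("trial_id"):
        assert (np.diff(grp["time_s"]) > 0).all()
        assert (np.diff(grp["pos_cm"]) >= 0).all()
        assert grp["pos_cm"].iloc[-1] == 150.0
    for tr in trials:
        dwell = tr.trial_end_time - tr.first_lick_time
        assert 1.0 <= dwell <= 10.0


def test_no_cue_trials_have_no_cue_onset():
    cfg = SynthConfig(seed=13, n_trials=60,
                      task_mix={"memory": 0.5, "no_cue_no_choice": 0.5})
    trials, _ = _behavior(cfg)
    tasks = [tr.task for tr in trials]
    assert tasks.count("no_cue_no_choice") == 30
    for tr in trials:
        assert (tr.cue_onset is None) == (tr.task == "no_cue_no_choice")


def test_constant_rate_poisson_count():
    cfg = SynthConfig(seed=17, n_trials=60)
    trials, tracking = _behavior(cfg)
    truth = SyntheticTruth(base_rate=10.0)
    t_end = max(tr.trial_end_time for tr in trials) + 60.0
    spikes = synth.generate_spikes(truth, trials, tracking,
                                   np.random.default_rng(1), t_end=t_end)
    expected = 10.0 * t_end
    assert abs(spikes.size - expected) < 3 * np.sqrt(expected)
    assert spikes.size and spikes.min() >= 0 and spikes.max() <= t_end


def test_zero_rate_yields_no_spikes():
    cfg = SynthConfig(seed=19, n_trials=5)
    trials, tracking = _behavior(cfg)
    truth = SyntheticTruth(base_rate=0.0)
    assert synth.generate_spikes(truth, trials, tracking,
                                 np.random.default_rng(0)).size == 0


def test_planted_delay_gain_recovered_in_rates():
    """Occupancy-normalized delay rates recover the 2x left/right ratio."""
    cfg = SynthConfig(seed=23, n_trials=300, p_correct=1.0)
    trials, tracking = _behavior(cfg)
    truth = SyntheticTruth(base_rate=10.0,
                           traj_modulated_sections=("delay",), traj_gain=2.0)
    t_end = max(tr.trial_end_time for tr in trials) + 1.0
    spikes = synth.generate_spikes(truth, trials, tracking,
                                   np.random.default_rng(2), t_end=t_end)
    bundle = type("B", (), {})()   # minimal stand-in for linearize_session
    from vta_memcode.session_io import SessionBundle, Unit
    bundle = SessionBundle(
        session_id="s", animal_id="a", genotype="unknown", trials=trials,
        tracking=tracking, units=[Unit(unit_id=0, spike_times=spikes)],
        t_start=0.0, t_end=t_end)
    lin = behavior.linearize_session(bundle)
    delay = behavior.section_bins("delay")
    is_left = lin.trajectory == "left"
    rates = lin.unit_rates(0)
    ratio = (np.nanmean(rates[is_left][:, delay])
             / np.nanmean(rates[~is_left][:, delay]))
    assert abs(ratio - 2.0) < 0.2


def test_untagged_unit_gets_no_evoked_spikes():
    cfg = SynthConfig(seed=29)
    blocks = synth.make_light_blocks(cfg, 0.0)
    truth = SyntheticTruth(tagged=False)
    assert synth.generate_evoked_spikes(
        truth, blocks, np.random.default_rng(0), p_evoke=1.0).size == 0


def test_deterministic_evoked_latency():
    cfg = SynthConfig(seed=29)
    blocks = synth.make_light_blocks(cfg, 0.0)
    onsets = np.concatenate([b.pulse_onsets for b in blocks])
    truth = SyntheticTruth(tagged=True, tag_latency=4.0, tag_jitter=0.0)
    evoked = synth.generate_evoked_spikes(truth, blocks,
                                          np.random.default_rng(0),
                                          p_evoke=1.0)
    assert evoked.size == onsets.size
    np.testing.assert_allclose(np.sort(evoked - np.sort(onsets)), 0.004,
                               atol=1e-9)


def test_evoked_count_binomial():
    cfg = SynthConfig(seed=29)                      # 600 pulses total
    blocks = synth.make_light_blocks(cfg, 0.0)
    truth = SyntheticTruth(tagged=True, tag_latency=4.0, tag_jitter=1.0)
    evoked = synth.generate_evoked_spikes(truth, blocks,
                                          np.random.default_rng(3),
                                          p_evoke=0.8)
    n = sum(b.pulse_onsets.size for b in blocks)
    assert n == 600
    assert abs(evoked.size - 0.8 * n) < 3 * np.sqrt(n * 0.8 * 0.2)
    # all latencies inside the artifact-free (1, 11) ms window
    rel = (evoked[:, None] - np.concatenate(
        [b.pulse_onsets for b in blocks])[None, :]) * 1000
    lat = np.where((rel > 0) & (rel < 12), rel, np.nan)
    lat = np.nanmin(lat, axis=1)
    assert lat.min() > 1.0 and lat.max() < 11.0


def test_planted_counts_are_deterministic():
    assert synth.planted_count(100, 0.2) == 20
    assert synth.planted_count(74, 0.47) == 34
    cfg = SynthConfig(seed=31, n_trials=20, n_da=100, n_gaba=0, n_untagged=0,
                      fraction_traj_delay_da=0.2,
                      fraction_reward_responsive=0.0)
    _, truth = synth.generate_cohort(cfg, with_light=False,
                                     with_waveforms=False)
    assert (truth.traj_modulated_sections == "delay").sum() == 20


def test_cohort_base_rates_track_class_means():
    cfg = SynthConfig(seed=37, n_trials=20, n_da=60, n_gaba=60, n_untagged=0,
                      fraction_reward_responsive=0.0)
    _, truth = synth.generate_cohort(cfg, with_light=False,
                                     with_waveforms=False)
    da = truth.loc[truth.cell_class == "DA", "base_rate"]
    gaba = truth.loc[truth.cell_class == "GABA", "base_rate"]
    # lognormal(log m, 0.3) has mean m * exp(0.045)
    assert abs(da.mean() - 5.0 * np.exp(0.045)) < 3 * da.std() / np.sqrt(60)
    assert abs(gaba.mean() - 20.0 * np.exp(0.045)) < \
        3 * gaba.std() / np.sqrt(60)
    assert gaba.mean() > 2 * da.mean()


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SynthConfig(p_correct=1.5)
    with pytest.raises(ValueError):
        SynthConfig(n_trials=0)
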
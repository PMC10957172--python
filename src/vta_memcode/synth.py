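"""Synthetic T-maze sessions with known ground truth.

The generator emulates the behavioral and spiking structure of a
figure-eight T-maze recording session: 80-100 trials at ~87% correct,
pseudo-random left/right trajectories on a 150 cm linearized track
(sections start 0-50, cue 50-80, delay 80-120, side arms 120-150 cm),
variable running speed, 1-10 s reward-consumption dwells, slow-firing
DA-like and fast-firing GABA-like units with Gaussian position fields,
planted trajectory-specific gain in chosen sections, step reward
responses, and ChR2-style light-evoked spikes (12 ms pulses, 150 pulses
per power block).

Spikes are drawn from an inhomogeneous Poisson process whose intensity is
piecewise constant on the tracking grid (20 ms samples):

    rate(t) = base_rate * field(pos) * trajectory_gain * reward_factor

Ground truth (which units were tagged, trajectory-modulated, or
reward-responsive, and by how much) is returned alongside the bundle so
every analysis stage has a recovery oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .session_io import SessionBundle, Trial, Unit, LightBlock

REWARD_EXCITED_GAIN = 3.0
REWARD_INHIBITED_GAIN = 0.2
REWARD_EPOCH_S = 1.0


@dataclass
class SyntheticTruth:
    """Planted parameters of one synthetic unit."""
    cell_class: str = "untagged"          # DA | GABA | untagged
    base_rate: float = 5.0                # Hz, > 0
    field_centers: tuple = ()             # cm
    field_widths: tuple = ()              # cm, > 0
    field_gains: tuple = ()               # dimensionless
    traj_modulated_sections: tuple = ()   # subset of the four maze sections
    traj_gain: float = 1.0                # left-rate / right-rate there
    arms_side_gain: float = 1.0           # left/right gain in the side arms
                                          # coupled to the reward preference
    reward_response: str = "none"         # excited | inhibited | none
    reward_side_gain: float = 1.0         # left/right gain in reward epoch
    tagged: bool = False
    tag_latency: float = 4.0              # ms
    tag_jitter: float = 1.0               # ms


@dataclass
class SynthConfig:
    seed: int = 0
    n_trials: int = 90
    p_correct: float = 0.87
    n_da: int = 100
    n_gaba: int = 74
    n_untagged: int = 0
    fraction_traj_delay_da: float = 0.20
    fraction_traj_delay_gaba: float = 0.47
    fraction_traj_delay_untagged: float = 0.10
    traj_gain: float = 2.0
    fraction_reward_responsive: float = 0.35
    speed_mean: float = 20.0              # cm/s
    speed_sd: float = 6.0
    reward_dwell_range: tuple = (1.0, 10.0)
    tracking_rate: float = 50.0           # Hz
    task_mix: Optional[dict] = None       # task -> fraction; default memory
    track_length: float = 150.0
    da_base_rate: float = 5.0
    gaba_base_rate: float = 20.0
    untagged_base_rate: float = 8.0
    intertrial_gap: tuple = (2.0, 5.0)    # return-run gap, s
    # light protocol
    p_evoke: float = 0.8
    tag_latency_ms: float = 4.0
    tag_jitter_ms: float = 1.0
    block_powers: tuple = (1.0, 2.0, 3.0, 4.0)     # mW
    block_freqs: tuple = (1.0, 2.0, 5.0, 10.0)     # Hz
    pulses_per_block: int = 150
    pulse_width_ms: float = 12.0
    interblock_gap: float = 10.0
    light_lead: float = 30.0              # s between behavior and light phase
    waveform_snr: float = 10.0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for name in ("p_correct", "fraction_traj_delay_da",
                     "fraction_traj_delay_gaba",
                     "fraction_traj_delay_untagged",
                     "fraction_reward_responsive", "p_evoke"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.tracking_rate <= 0:
            raise ValueError("tracking_rate must be positive")


def planted_count(n: int, fraction: float) -> int:
    """Deterministic planted count: floor(n * fraction)."""
    return int(np.floor(n * fraction + 1e-9))


# ---------------------------------------------------------------------------
# behavior

def _trial_positions(rng, config) -> tuple:
    """One trial's tracking: returns (times from 0, positions 0..L).

    The speed profile is a per-trial lognormal mean speed modulated within
    the trial by a smooth random curve floored at 20% of the mean; the
    position trace is strictly increasing by construction.
    """
    L = config.track_length
    m, s = config.speed_mean, config.speed_sd
    mu = np.log(m ** 2 / np.sqrt(m ** 2 + s ** 2))
    sig = np.sqrt(np.log(1 + (s / m) ** 2))
    v_trial = rng.lognormal(mu, sig)

    # smooth within-trial modulation anchored at 8 position knots
    knots_x = np.linspace(0.0, L, 8)
    knots_f = np.maximum(1.0 + 0.25 * rng.standard_normal(8), 0.2)
    grid_x = np.linspace(0.0, L, 1501)
    v_x = v_trial * np.interp(grid_x, knots_x, knots_f)
    dx = np.diff(grid_x)
    t_grid = np.concatenate([[0.0], np.cumsum(dx / v_x[:-1])])
    duration = t_grid[-1]

    dt = 1.0 / config.tracking_rate
    t = np.arange(0.0, duration, dt)
    if duration - t[-1] > 1e-6:
        t = np.append(t, duration)
    else:
        t[-1] = duration
    pos = np.interp(t, t_grid, grid_x)
    pos[-1] = L
    return t, pos


def _task_sequence(rng, config) -> list:
    mix = config.task_mix or {"memory": 1.0}
    n = config.n_trials
    counts = {task: planted_count(n, frac) for task, frac in mix.items()}
    counts["memory"] = counts.get("memory", 0) + n - sum(counts.values())
    # cue-no-choice trials come as a separate trailing block; the no-cue
    # control is randomly interleaved with memory trials
    interleaved = (["memory"] * counts.get("memory", 0)
                   + ["no_cue_no_choice"] * counts.get("no_cue_no_choice", 0))
    interleaved = [interleaved[i] for i in rng.permutation(len(interleaved))]
    return interleaved + ["cue_no_choice"] * counts.get("cue_no_choice", 0)


def generate_behavior(config: SynthConfig, rng) -> tuple:
    """Generate the trial table and tracking for one session.

    Returns ``(trials, tracking)`` with trajectories drawn pseudo-randomly
    and balanced within 10%, accuracy Bernoulli(p_correct), and reward
    dwell uniform over ``reward_dwell_range``.
    """
    n = config.n_trials
    tasks = _task_sequence(rng, config)
    n_left = n // 2 + int(rng.integers(0, 2)) if n % 2 else n // 2
    sides = np.array(["left"] * n_left + ["right"] * (n - n_left))
    sides = sides[rng.permutation(n)]
    correct = rng.random(n) < config.p_correct

    trials = []
    rows_t, rows_p, rows_id = [], [], []
    clock = 0.0
    for i in range(n):
        t_rel, pos = _trial_positions(rng, config)
        t_abs = clock + t_rel
        lick = t_abs[-1]
        cue = (None if tasks[i] == "no_cue_no_choice"
               else float(np.interp(50.0, pos, t_abs)))
        delay_off = float(np.interp(120.0, pos, t_abs))
        dwell = rng.uniform(*config.reward_dwell_range)
        end = lick + dwell
        trials.append(Trial(
            trial_id=i, task=tasks[i], trajectory=str(sides[i]),
            accuracy="correct" if correct[i] else "error",
            start_time=float(t_abs[0]), cue_onset=cue,
            delay_offset_time=delay_off, first_lick_time=float(lick),
            trial_end_time=float(end)))
        rows_t.append(t_abs)
        rows_p.append(pos)
        rows_id.append(np.full(t_abs.size, i, dtype=int))
        clock = end + rng.uniform(*config.intertrial_gap)

    tracking = pd.DataFrame({
        "trial_id": np.concatenate(rows_id),
        "time_s": np.concatenate(rows_t),
        "pos_cm": np.concatenate(rows_p)})
    return trials, tracking


# ---------------------------------------------------------------------------
# spikes

_SECTION_EDGES = np.array([50.0, 80.0, 120.0, 150.0])
_SECTION_NAMES = np.array(["start", "cue", "delay", "side_arms"])


def _position_factor(pos: np.ndarray, truth: SyntheticTruth,
                     is_left: bool, is_memory: bool = True) -> np.ndarray:
    """Field gain x trajectory gain at linearized positions (one trial).

    The planted trajectory gain is memory-specific: it applies only on
    memory-task trials (the internal choice signal it emulates needs a
    memory-guided decision).  The side-arm gain coupled to the reward
    preference is task-general, like the sensory/motor differences of
    physically distinct arms.
    """
    f = np.ones_like(pos)
    for c, w, g in zip(truth.field_centers, truth.field_widths,
                       truth.field_gains):
        f = f + g * np.exp(-0.5 * ((pos - c) / w) ** 2)
    if is_left:
        section = _SECTION_NAMES[
            np.clip(np.searchsorted(_SECTION_EDGES, pos, side="left"), 0, 3)]
        if truth.traj_modulated_sections and is_memory:
            mod = np.isin(section, truth.traj_modulated_sections)
            f = np.where(mod, f * truth.traj_gain, f)
        if truth.arms_side_gain != 1.0:
            f = np.where(section == "side_arms", f * truth.arms_side_gain, f)
    return f


def _reward_gain(truth: SyntheticTruth) -> float:
    return {"excited": REWARD_EXCITED_GAIN,
            "inhibited": REWARD_INHIBITED_GAIN,
            "none": 1.0}[truth.reward_response]


def _piecewise_poisson(rng, t0, t1, rate) -> np.ndarray:
    """Spike times from a piecewise-constant-rate Poisson process."""
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    rate = np.asarray(rate, dtype=float)
    dur = t1 - t0
    counts = rng.poisson(np.maximum(rate, 0.0) * dur)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    idx = np.repeat(np.arange(t0.size), counts)
    return np.sort(t0[idx] + rng.random(total) * dur[idx])


def generate_spikes(truth: SyntheticTruth, trials, tracking, rng,
                    t_end: Optional[float] = None) -> np.ndarray:
    """Inhomogeneous-Poisson spike train for one unit over the behavior
    phase; base rate between trials, modulated rate on the maze, and a
    step reward factor for 1 s after the first lick."""
    if truth.base_rate <= 0:
        return np.empty(0)
    seg_t0, seg_t1, seg_rate = [], [], []
    by_trial = dict(tuple(tracking.groupby("trial_id", sort=True)))
    clock = 0.0
    for tr in sorted(trials, key=lambda tr: tr.trial_id):
        grp = by_trial[tr.trial_id]
        tt = grp["time_s"].to_numpy(dtype=float)
        px = grp["pos_cm"].to_numpy(dtype=float)
        if tr.start_time > clock:     # inter-trial gap at base rate
            seg_t0.append(np.array([clock]))
            seg_t1.append(np.array([tr.start_time]))
            seg_rate.append(np.array([truth.base_rate]))
        factor = _position_factor(0.5 * (px[:-1] + px[1:]), truth,
                                  tr.trajectory == "left",
                                  tr.task == "memory")
        seg_t0.append(tt[:-1])
        seg_t1.append(tt[1:])
        seg_rate.append(truth.base_rate * factor)
        # reward epoch then post-reward dwell
        lick = tr.first_lick_time
        r_end = min(lick + REWARD_EPOCH_S, tr.trial_end_time)
        gain = _reward_gain(truth)
        if tr.trajectory == "left":
            gain *= truth.reward_side_gain
        seg_t0.append(np.array([lick, r_end]))
        seg_t1.append(np.array([r_end, tr.trial_end_time]))
        seg_rate.append(truth.base_rate * np.array([gain, 1.0]))
        clock = tr.trial_end_time
    if t_end is not None and t_end > clock:
        seg_t0.append(np.array([clock]))
        seg_t1.append(np.array([t_end]))
        seg_rate.append(np.array([truth.base_rate]))
    return _piecewise_poisson(rng, np.concatenate(seg_t0),
                              np.concatenate(seg_t1),
                              np.concatenate(seg_rate))


# ---------------------------------------------------------------------------
# light stimulation

def make_light_blocks(config: SynthConfig, t0: float) -> list:
    """Paper-conformant pulse protocol: one block per power, 150 pulses."""
    blocks = []
    clock = t0
    for bid, (power, freq) in enumerate(zip(config.block_powers,
                                            config.block_freqs)):
        onsets = clock + np.arange(config.pulses_per_block) / freq
        blocks.append(LightBlock(block_id=bid, power=float(power),
                                 frequency=float(freq), pulse_onsets=onsets,
                                 pulse_width=config.pulse_width_ms))
        clock = onsets[-1] + 1.0 / freq + config.interblock_gap
    return blocks


def light_phase_span(blocks, pad: float = 5.0) -> tuple:
    t0 = min(b.pulse_onsets[0] for b in blocks) - pad
    t1 = max(b.pulse_onsets[-1] for b in blocks) + pad
    return t0, t1


def generate_evoked_spikes(truth: SyntheticTruth, blocks, rng,
                           p_evoke: float) -> np.ndarray:
    """Light-evoked spikes for a tagged unit: each pulse adds one spike
    with probability p_evoke at latency ~ N(tag_latency, tag_jitter),
    resampled into the (1, 11) ms analysis window (the 0-1 and 11-12 ms
    artifact windows carry no evoked spikes)."""
    if not truth.tagged:
        return np.empty(0)
    onsets = np.concatenate([b.pulse_onsets for b in blocks])
    hit = rng.random(onsets.size) < p_evoke
    onsets = onsets[hit]
    lat = truth.tag_latency + truth.tag_jitter * rng.standard_normal(
        onsets.size)
    for _ in range(100):
        bad = (lat <= 1.0) | (lat >= 11.0)
        if not bad.any():
            break
        lat[bad] = truth.tag_latency + truth.tag_jitter * \
            rng.standard_normal(int(bad.sum()))
    lat = np.clip(lat, 1.0 + 1e-6, 11.0 - 1e-6)
    return np.sort(onsets + lat / 1000.0)


def generate_light_session(truths: Sequence[SyntheticTruth],
                           config: SynthConfig, rng,
                           t0: float = 0.0) -> tuple:
    """Light blocks plus per-unit spikes in the light phase (spontaneous
    baseline firing for every unit; evoked spikes added for tagged units).
    Returns ``(blocks, spike_list)``."""
    blocks = make_light_blocks(config, t0 + config.light_lead)
    span0, span1 = light_phase_span(blocks)
    spike_list = []
    for truth in truths:
        spont = _piecewise_poisson(
            rng, np.array([span0]), np.array([span1]),
            np.array([max(truth.base_rate, 0.0)]))
        evoked = generate_evoked_spikes(truth, blocks, rng, config.p_evoke)
        spike_list.append(np.sort(np.concatenate([spont, evoked])))
    return blocks, spike_list


# ---------------------------------------------------------------------------
# waveforms

def _waveform_template(rng, n_channels: int = 4,
                       n_samples: int = 32) -> np.ndarray:
    t = np.arange(n_samples)
    trough = 8 + rng.uniform(-2, 2)
    width = rng.uniform(1.5, 3.5)
    shape = (-np.exp(-0.5 * ((t - trough) / width) ** 2)
             + 0.35 * np.exp(-0.5 * ((t - trough - 3 * width) /
                                     (2 * width)) ** 2))
    amps = rng.uniform(0.3, 1.0, n_channels)
    amps[int(rng.integers(n_channels))] = 1.0
    return np.outer(amps, shape) * rng.uniform(50, 150)


def generate_waveforms(rng, snr: float = 10.0) -> tuple:
    """(spontaneous, light) waveform pair: shared template plus
    independent additive noise with RMS = template RMS / snr."""
    template = _waveform_template(rng)
    sd = np.sqrt(np.mean(template ** 2)) / snr
    spont = template + sd * rng.standard_normal(template.shape)
    light = template + sd * rng.standard_normal(template.shape)
    return spont, light


# ---------------------------------------------------------------------------
# cohort assembly

def _truth_for_class(rng, config, cell_class: str, modulated: bool,
                     reward_resp: bool) -> SyntheticTruth:
    base = {"DA": config.da_base_rate, "GABA": config.gaba_base_rate,
            "untagged": config.untagged_base_rate}[cell_class]
    base_rate = float(np.exp(rng.normal(np.log(base), 0.3)))
    n_fields = int(rng.integers(1, 4))
    centers = tuple(np.round(rng.uniform(0, config.track_length, n_fields), 2))
    widths = tuple(np.round(rng.uniform(8, 20, n_fields), 2))
    gains = tuple(np.round(rng.uniform(0.3, 1.5, n_fields), 3))
    traj_gain = 1.0
    sections = ()
    if modulated:
        sections = ("delay",)
        g = config.traj_gain
        traj_gain = g if rng.random() < 0.5 else 1.0 / g
    reward_response = "none"
    reward_side_gain = 1.0
    arms_side_gain = 1.0
    if reward_resp:
        reward_response = "excited" if rng.random() < 0.7 else "inhibited"
        reward_side_gain = float(np.exp(rng.normal(0.0, 0.5)))
        # side preference during the approach run mirrors the reward
        # preference, coupling the side-arm and reward-epoch differences
        arms_side_gain = reward_side_gain
    return SyntheticTruth(
        cell_class=cell_class, base_rate=base_rate, field_centers=centers,
        field_widths=widths, field_gains=gains,
        traj_modulated_sections=sections, traj_gain=traj_gain,
        arms_side_gain=arms_side_gain, reward_response=reward_response,
        reward_side_gain=reward_side_gain,
        tagged=cell_class in ("DA", "GABA"),
        tag_latency=config.tag_latency_ms, tag_jitter=config.tag_jitter_ms)


def _truth_to_row(uid: int, truth: SyntheticTruth) -> dict:
    row = {"unit_id": uid}
    for key, val in asdict(truth).items():
        if isinstance(val, tuple):
            row[key] = ",".join(str(v) for v in val)
        else:
            row[key] = val
    return row


def generate_cohort(config: SynthConfig,
                    with_light: bool = True,
                    with_waveforms: bool = True) -> tuple:
    """Assemble a full synthetic session bundle plus its truth manifest.

    Planted counts are deterministic (floor(n * fraction), unit membership
    by a seed-fixed permutation) so recovery tests have exact expectations.
    Returns ``(SessionBundle, truth DataFrame)``.
    """
    rng = np.random.default_rng(config.seed)
    trials, tracking = generate_behavior(config, rng)

    classes = (["DA"] * config.n_da + ["GABA"] * config.n_gaba
               + ["untagged"] * config.n_untagged)
    fractions = {"DA": config.fraction_traj_delay_da,
                 "GABA": config.fraction_traj_delay_gaba,
                 "untagged": config.fraction_traj_delay_untagged}
    truths = []
    offset = 0
    for cls, n_cls in (("DA", config.n_da), ("GABA", config.n_gaba),
                       ("untagged", config.n_untagged)):
        k_mod = planted_count(n_cls, fractions[cls])
        k_rew = planted_count(n_cls, config.fraction_reward_responsive)
        mod_ids = set(rng.permutation(n_cls)[:k_mod])
        rew_ids = set(rng.permutation(n_cls)[:k_rew])
        for i in range(n_cls):
            truths.append(_truth_for_class(rng, config, cls, i in mod_ids,
                                           i in rew_ids))
        offset += n_cls

    behavior_end = max(tr.trial_end_time for tr in trials)
    blocks, light_spikes = ([], [np.empty(0)] * len(truths))
    if with_light:
        blocks, light_spikes = generate_light_session(
            truths, config, rng, t0=behavior_end)
        _, t_end = light_phase_span(blocks)
    else:
        t_end = behavior_end + 1.0

    units = []
    for uid, truth in enumerate(truths):
        beh = generate_spikes(truth, trials, tracking, rng,
                              t_end=behavior_end)
        spikes = np.sort(np.concatenate([beh, light_spikes[uid]]))
        spont = light = None
        if with_waveforms:
            spont, light = generate_waveforms(rng, config.waveform_snr)
        units.append(Unit(
            unit_id=uid, spike_times=spikes,
            genotype_label=truth.cell_class,
            spont_waveform=spont, light_waveform=light,
            truth=_truth_to_row(uid, truth)))
        units[-1].truth.pop("unit_id")

    bundle = SessionBundle(
        session_id=f"synthetic-{config.seed}", animal_id="synthetic",
        genotype="unknown", trials=trials, tracking=tracking, units=units,
        light_blocks=blocks, track_length=config.track_length,
        t_start=0.0, t_end=float(t_end))
    truth_df = pd.DataFrame([_truth_to_row(uid, t)
                             for uid, t in enumerate(truths)])
    return bundle, truth_df
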
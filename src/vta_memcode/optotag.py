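"""Optogenetic tagging: classify light-responsive units from pulse PSTHs.

A unit counts as light-responsive when its pulse-aligned PSTH (1 ms bins
over the 12 ms pulse window; the 0-1 and 11-12 ms bins are stimulation
artifacts and excluded) exceeds a global upper confidence limit of the
baseline activity.  The limit is the (1 - alpha) quantile of the maximum
non-artifact PSTH bin over surrogate pulse sets drawn uniformly from the
inter-stimulus baseline, which controls the family-wise error across bins
with a single band.  Waveform identity between spontaneous and
light-evoked spikes is checked by Pearson correlation (> 0.9 expected for
a genuinely tagged unit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

PULSE_WINDOW_MS = 12
ARTIFACT_BINS = (0, 11)   # 0-1 ms and 11-12 ms


def _analysis_bins(n_bins: int = PULSE_WINDOW_MS) -> np.ndarray:
    return np.array([b for b in range(n_bins) if b not in ARTIFACT_BINS])


@dataclass
class OptotagResult:
    unit_id: int
    light_psth: np.ndarray      # Hz per 1 ms bin, 12 bins
    baseline_limit: float       # Hz
    responsive: bool
    waveform_corr: Optional[float]
    n_pulses_used: int


def build_light_psth(spike_times, pulse_onsets,
                     window_ms: int = PULSE_WINDOW_MS) -> np.ndarray:
    """Pulse-aligned PSTH: spike rate (Hz) per 1 ms bin of the pulse window.

    Rate = total count in the bin across pulses / (n_pulses * 1 ms).
    """
    pulses = np.asarray(pulse_onsets, dtype=float)
    if pulses.size == 0:
        raise ValueError("need at least one pulse")
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    edges = pulses[:, None] + np.arange(window_ms + 1) / 1000.0
    counts = np.diff(np.searchsorted(spikes, edges), axis=1)
    return counts.sum(axis=0) / (pulses.size * 1e-3)


def _baseline_intervals(pulse_onsets, window_s: float,
                        span: Optional[tuple] = None) -> tuple:
    """Complement of the pulse windows within the analysis span; returns
    (starts, lengths) of baseline intervals able to host a full window."""
    pulses = np.sort(np.asarray(pulse_onsets, dtype=float))
    if span is None:
        span = (pulses[0] - 1.0, pulses[-1] + 1.0)
    t0, t1 = span
    starts, lengths = [], []
    cursor = t0
    for p in pulses:
        if p - cursor >= window_s:
            starts.append(cursor)
            lengths.append((p - cursor) - window_s)  # onset slack
        cursor = max(cursor, p + window_s)
    if t1 - cursor >= window_s:
        starts.append(cursor)
        lengths.append((t1 - cursor) - window_s)
    return np.asarray(starts), np.asarray(lengths)


def baseline_confidence_limit(spike_times, pulse_onsets,
                              n_resamples: int = 1000,
                              alpha: float = 0.01,
                              rng=None,
                              span: Optional[tuple] = None,
                              window_ms: int = PULSE_WINDOW_MS,
                              min_baseline_ratio: float = 10.0) -> float:
    """Global upper confidence bound (Hz) of the baseline activity.

    Draws ``n_resamples`` surrogate pulse-onset sets (same pulse count)
    uniformly from the inter-stimulus baseline, builds each surrogate
    PSTH, records its maximum non-artifact bin rate, and returns the
    (1 - alpha) quantile of those maxima.
    """
    rng = np.random.default_rng(rng)
    pulses = np.sort(np.asarray(pulse_onsets, dtype=float))
    window_s = window_ms / 1000.0
    starts, lengths = _baseline_intervals(pulses, window_s, span)
    total = float(lengths.sum() + len(lengths) * window_s)
    if total < min_baseline_ratio * pulses.size * window_s:
        raise ValueError(
            f"baseline duration {total:.1f}s is below "
            f"{min_baseline_ratio}x the summed pulse-window duration")

    spikes = np.sort(np.asarray(spike_times, dtype=float))
    keep = _analysis_bins(window_ms)

    # surrogate onsets by inverse-CDF over the concatenated baseline
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    draws = rng.random((n_resamples, pulses.size)) * cum[-1]
    seg = np.searchsorted(cum, draws, side="right") - 1
    onsets = starts[seg] + (draws - cum[seg])

    edges = onsets[..., None] + np.arange(window_ms + 1) / 1000.0
    counts = np.diff(np.searchsorted(spikes, edges), axis=-1)
    rates = counts.sum(axis=1) / (pulses.size * 1e-3)   # (R, window)
    maxima = rates[:, keep].max(axis=1)
    return float(np.quantile(maxima, 1.0 - alpha))


def waveform_similarity(spont: np.ndarray, light: np.ndarray):
    """Pearson r between the two waveform matrices flattened channel-major;
    None when either input has zero variance."""
    a = np.asarray(spont, dtype=float)
    b = np.asarray(light, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"waveform shapes differ: {a.shape} vs {b.shape}")
    a, b = a.ravel(), b.ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def classify_light_responsive(unit_id, spike_times, pulse_onsets,
                              alpha: float = 0.01,
                              n_resamples: int = 1000,
                              rng=None,
                              spont_waveform=None,
                              light_waveform=None,
                              span: Optional[tuple] = None) -> OptotagResult:
    """Full tagging decision for one unit.

    responsive is True iff any non-artifact PSTH bin exceeds the baseline
    upper confidence limit.
    """
    psth = build_light_psth(spike_times, pulse_onsets)
    limit = baseline_confidence_limit(
        spike_times, pulse_onsets, n_resamples=n_resamples, alpha=alpha,
        rng=rng, span=span)
    keep = _analysis_bins()
    responsive = bool(np.any(psth[keep] > limit))
    corr = None
    if spont_waveform is not None and light_waveform is not None:
        corr = waveform_similarity(spont_waveform, light_waveform)
    return OptotagResult(unit_id=unit_id, light_psth=psth,
                         baseline_limit=limit, responsive=responsive,
                         waveform_corr=corr,
                         n_pulses_used=int(np.asarray(pulse_onsets).size))


def optotag_session(bundle, alpha: float = 0.01, n_resamples: int = 1000,
                    seed: Optional[int] = None) -> list:
    """Run the tagging classifier on every unit of a session bundle."""
    onsets = np.sort(np.concatenate(
        [b.pulse_onsets for b in bundle.light_blocks]))
    rng = np.random.default_rng(seed)
    results = []
    for u in bundle.units:
        results.append(classify_light_responsive(
            u.unit_id, u.spike_times, onsets, alpha=alpha,
            n_resamples=n_resamples, rng=rng,
            spont_waveform=u.spont_waveform,
            light_waveform=u.light_waveform))
    return results
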
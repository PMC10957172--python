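"""On-disk session bundles for T-maze electrophysiology analyses.

A session directory holds tab-separated UTF-8 tables (times in seconds,
positions in cm), an optional HDF5 waveform container, and a JSON metadata
file:

``trials.tsv``
    trial_id, task, trajectory, accuracy, start_time_s, cue_onset_s,
    delay_offset_s, first_lick_s, end_time_s
``tracking.tsv``
    trial_id, time_s, pos_cm  (already linearized along the lap path)
``spikes.tsv``
    unit_id, time_s
``units.tsv``
    unit_id, genotype_label
``light_pulses.tsv``
    block_id, power_mw, freq_hz, onset_s, width_ms
``waveforms.h5`` (optional)
    one dataset per unit per condition (spontaneous / light-evoked)
``truth.tsv`` (optional)
    planted ground truth for synthetic sessions
``session.json``
    session_id, animal_id, genotype, track_length_cm, t_start_s, t_end_s
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

TASKS = ("memory", "no_cue_no_choice", "cue_no_choice")
TRAJECTORIES = ("left", "right")
ACCURACIES = ("correct", "error")
GENOTYPES = ("DAT-Cre", "VGAT-Cre", "unknown")

_FLOAT_FMT = "%.6f"


class ValidationError(ValueError):
    """Raised when a session bundle violates a structural invariant."""


@dataclass
class Trial:
    trial_id: int
    task: str
    trajectory: str
    accuracy: str
    start_time: float
    cue_onset: Optional[float]  # absent for no-cue trials
    delay_offset_time: float
    first_lick_time: float
    trial_end_time: float


@dataclass
class LightBlock:
    block_id: int
    power: float          # mW
    frequency: float      # Hz
    pulse_onsets: np.ndarray
    pulse_width: float = 12.0  # ms


@dataclass
class Unit:
    unit_id: int
    spike_times: np.ndarray
    genotype_label: str = "unknown"
    spont_waveform: Optional[np.ndarray] = None   # channels x samples
    light_waveform: Optional[np.ndarray] = None
    truth: Optional[dict] = None


@dataclass
class SessionBundle:
    session_id: str
    animal_id: str
    genotype: str
    trials: list
    tracking: pd.DataFrame      # columns trial_id, time_s, pos_cm
    units: list
    light_blocks: list = field(default_factory=list)
    track_length: float = 150.0
    t_start: float = 0.0
    t_end: float = 0.0

    def trial_table(self) -> pd.DataFrame:
        rows = []
        for tr in self.trials:
            rows.append({
                "trial_id": tr.trial_id, "task": tr.task,
                "trajectory": tr.trajectory, "accuracy": tr.accuracy,
                "start_time_s": tr.start_time,
                "cue_onset_s": np.nan if tr.cue_onset is None else tr.cue_onset,
                "delay_offset_s": tr.delay_offset_time,
                "first_lick_s": tr.first_lick_time,
                "end_time_s": tr.trial_end_time,
            })
        cols = ["trial_id", "task", "trajectory", "accuracy", "start_time_s",
                "cue_onset_s", "delay_offset_s", "first_lick_s", "end_time_s"]
        return pd.DataFrame(rows, columns=cols)


def validate_session(bundle: SessionBundle) -> list:
    """Check all bundle invariants; returns a list of violation reports.

    Never raises on a structurally well-formed bundle: every problem is
    reported as a string naming the offending trial or unit.
    """
    reports = []
    ids = [tr.trial_id for tr in bundle.trials]
    if len(ids) != len(set(ids)):
        reports.append("trials: duplicate trial_id values")
    id_set = set(ids)

    for tr in bundle.trials:
        if not (tr.start_time < tr.first_lick_time < tr.trial_end_time):
            reports.append(
                f"trial {tr.trial_id}: requires start_time < first_lick_time"
                f" < trial_end_time")
        if tr.task == "no_cue_no_choice" and tr.cue_onset is not None:
            reports.append(
                f"trial {tr.trial_id}: no_cue_no_choice trial has a cue_onset")
        if tr.task not in TASKS:
            reports.append(f"trial {tr.trial_id}: unknown task {tr.task!r}")
        if tr.trajectory not in TRAJECTORIES:
            reports.append(
                f"trial {tr.trial_id}: unknown trajectory {tr.trajectory!r}")
        if tr.accuracy not in ACCURACIES:
            reports.append(
                f"trial {tr.trial_id}: unknown accuracy {tr.accuracy!r}")

    if len(bundle.tracking):
        bad_refs = set(bundle.tracking["trial_id"]) - id_set
        if bad_refs:
            reports.append(
                f"tracking: rows reference unknown trial_ids {sorted(bad_refs)}")
        for tid, grp in bundle.tracking.groupby("trial_id", sort=True):
            t = grp["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                reports.append(
                    f"tracking trial {tid}: time not strictly increasing")
            p = grp["pos_cm"].to_numpy()
            if p.min() < 0 or p.max() > bundle.track_length:
                reports.append(
                    f"tracking trial {tid}: position outside "
                    f"[0, {bundle.track_length}] cm")

    for u in bundle.units:
        st = np.asarray(u.spike_times, dtype=float)
        if st.size and np.any(np.diff(st) < 0):
            reports.append(f"unit {u.unit_id}: spike_times not sorted")
        if st.size and (st.min() < bundle.t_start or st.max() > bundle.t_end):
            reports.append(
                f"unit {u.unit_id}: spike outside session span "
                f"[{bundle.t_start}, {bundle.t_end}] s")
        if (u.spont_waveform is not None and u.light_waveform is not None
                and u.spont_waveform.shape != u.light_waveform.shape):
            reports.append(
                f"unit {u.unit_id}: waveform shapes differ "
                f"{u.spont_waveform.shape} vs {u.light_waveform.shape}")
    return reports


def write_session(bundle: SessionBundle, path: str) -> None:
    """Write a bundle to ``path`` in the TSV dialect; deterministic bytes."""
    os.makedirs(path, exist_ok=True)

    bundle.trial_table().to_csv(
        os.path.join(path, "trials.tsv"), sep="\t", index=False,
        float_format=_FLOAT_FMT)
    trk = bundle.tracking[["trial_id", "time_s", "pos_cm"]]
    trk.to_csv(os.path.join(path, "tracking.tsv"), sep="\t", index=False,
               float_format=_FLOAT_FMT)

    spike_rows = []
    for u in bundle.units:
        st = np.asarray(u.spike_times, dtype=float)
        spike_rows.append(pd.DataFrame(
            {"unit_id": np.full(st.size, u.unit_id, dtype=int), "time_s": st}))
    spikes = (pd.concat(spike_rows, ignore_index=True) if spike_rows
              else pd.DataFrame(columns=["unit_id", "time_s"]))
    spikes.to_csv(os.path.join(path, "spikes.tsv"), sep="\t", index=False,
                  float_format=_FLOAT_FMT)

    units = pd.DataFrame(
        {"unit_id": [u.unit_id for u in bundle.units],
         "genotype_label": [u.genotype_label for u in bundle.units]})
    units.to_csv(os.path.join(path, "units.tsv"), sep="\t", index=False)

    pulse_rows = []
    for blk in bundle.light_blocks:
        on = np.asarray(blk.pulse_onsets, dtype=float)
        pulse_rows.append(pd.DataFrame({
            "block_id": np.full(on.size, blk.block_id, dtype=int),
            "power_mw": np.full(on.size, blk.power, dtype=float),
            "freq_hz": np.full(on.size, blk.frequency, dtype=float),
            "onset_s": on,
            "width_ms": np.full(on.size, blk.pulse_width, dtype=float)}))
    pulses = (pd.concat(pulse_rows, ignore_index=True) if pulse_rows
              else pd.DataFrame(
                  columns=["block_id", "power_mw", "freq_hz", "onset_s",
                           "width_ms"]))
    pulses.to_csv(os.path.join(path, "light_pulses.tsv"), sep="\t",
                  index=False, float_format=_FLOAT_FMT)

    truth_rows = [dict(unit_id=u.unit_id, **u.truth)
                  for u in bundle.units if u.truth is not None]
    if truth_rows:
        pd.DataFrame(truth_rows).to_csv(
            os.path.join(path, "truth.tsv"), sep="\t", index=False,
            float_format=_FLOAT_FMT)

    if any(u.spont_waveform is not None or u.light_waveform is not None
           for u in bundle.units):
        import h5py
        with h5py.File(os.path.join(path, "waveforms.h5"), "w",
                       track_order=True) as f:
            for u in bundle.units:
                for name, wf in (("spont", u.spont_waveform),
                                 ("light", u.light_waveform)):
                    if wf is not None:
                        f.create_dataset(f"unit_{u.unit_id}/{name}", data=wf,
                                         track_times=False)

    meta = {"session_id": bundle.session_id, "animal_id": bundle.animal_id,
            "genotype": bundle.genotype,
            "track_length_cm": bundle.track_length,
            "t_start_s": bundle.t_start, "t_end_s": bundle.t_end}
    with open(os.path.join(path, "session.json"), "w", encoding="utf-8") as f:
        json.dump(meta, f, indent=2, sort_keys=True)
        f.write("\n")


def read_session(path: str) -> SessionBundle:
    """Read and validate a session bundle from ``path``.

    Raises FileNotFoundError naming the first missing mandatory table and
    ValidationError naming the first violated invariant.
    """
    for fname in ("trials.tsv", "tracking.tsv", "spikes.tsv", "session.json"):
        if not os.path.exists(os.path.join(path, fname)):
            raise FileNotFoundError(
                f"session bundle at {path} is missing mandatory file {fname}")

    with open(os.path.join(path, "session.json"), encoding="utf-8") as f:
        meta = json.load(f)

    trials_df = pd.read_csv(os.path.join(path, "trials.tsv"), sep="\t")
    trials = []
    for row in trials_df.itertuples(index=False):
        cue = None if pd.isna(row.cue_onset_s) else float(row.cue_onset_s)
        trials.append(Trial(
            trial_id=int(row.trial_id), task=str(row.task),
            trajectory=str(row.trajectory), accuracy=str(row.accuracy),
            start_time=float(row.start_time_s), cue_onset=cue,
            delay_offset_time=float(row.delay_offset_s),
            first_lick_time=float(row.first_lick_s),
            trial_end_time=float(row.end_time_s)))

    tracking = pd.read_csv(os.path.join(path, "tracking.tsv"), sep="\t")

    spikes = pd.read_csv(os.path.join(path, "spikes.tsv"), sep="\t")
    units_path = os.path.join(path, "units.tsv")
    if os.path.exists(units_path):
        units_df = pd.read_csv(units_path, sep="\t")
    else:
        uids = sorted(spikes["unit_id"].unique()) if len(spikes) else []
        units_df = pd.DataFrame(
            {"unit_id": uids, "genotype_label": ["unknown"] * len(uids)})

    truth_path = os.path.join(path, "truth.tsv")
    truth_by_unit = {}
    if os.path.exists(truth_path):
        tdf = pd.read_csv(truth_path, sep="\t")
        for row in tdf.to_dict("records"):
            truth_by_unit[int(row.pop("unit_id"))] = row

    wf_path = os.path.join(path, "waveforms.h5")
    waveforms = {}
    if os.path.exists(wf_path):
        import h5py
        with h5py.File(wf_path, "r") as f:
            for key in f:
                uid = int(key.split("_", 1)[1])
                waveforms[uid] = {name: f[key][name][()] for name in f[key]}

    units = []
    for row in units_df.itertuples(index=False):
        uid = int(row.unit_id)
        st = np.sort(spikes.loc[spikes["unit_id"] == uid, "time_s"]
                     .to_numpy(dtype=float))
        wf = waveforms.get(uid, {})
        units.append(Unit(
            unit_id=uid, spike_times=st,
            genotype_label=str(row.genotype_label),
            spont_waveform=wf.get("spont"), light_waveform=wf.get("light"),
            truth=truth_by_unit.get(uid)))

    blocks = []
    pulses_path = os.path.join(path, "light_pulses.tsv")
    if os.path.exists(pulses_path):
        pdf = pd.read_csv(pulses_path, sep="\t")
        for bid, grp in pdf.groupby("block_id", sort=True):
            blocks.append(LightBlock(
                block_id=int(bid), power=float(grp["power_mw"].iloc[0]),
                frequency=float(grp["freq_hz"].iloc[0]),
                pulse_onsets=np.sort(grp["onset_s"].to_numpy(dtype=float)),
                pulse_width=float(grp["width_ms"].iloc[0])))

    bundle = SessionBundle(
        session_id=str(meta["session_id"]), animal_id=str(meta["animal_id"]),
        genotype=str(meta["genotype"]), trials=trials, tracking=tracking,
        units=units, light_blocks=blocks,
        track_length=float(meta["track_length_cm"]),
        t_start=float(meta["t_start_s"]), t_end=float(meta["t_end_s"]))

    problems = validate_session(bundle)
    if problems:
        raise ValidationError("; ".join(problems))
    return bundle
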
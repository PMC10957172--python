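"""End-to-end orchestration: simulate -> optotag -> linearize -> rate maps
-> permutation -> reward -> report, reproducibly under one master seed.

Stage seeds are derived from the master seed through a documented counter
scheme (SeedSequence spawn keys 0, 1, 2, ... in stage order), so any
stage can be rerun in isolation with the seed the full run would have
used.  Every written artifact carries the configuration hash and the
seeds in ``run_meta.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import behavior, optotag, permutation, ratemaps, reward, session_io
from .synth import SynthConfig, generate_cohort

STAGES = ("simulate", "optotag", "permtest", "reward")


@dataclass
class RunConfig:
    master_seed: int = 0
    out_dir: str = "results"
    session_path: Optional[str] = None    # existing bundle; else simulate
    synth: SynthConfig = None
    alpha: float = 0.05
    tag_alpha: float = 0.01
    tag_resamples: int = 1000
    n_perms: int = 1000
    min_run: int = 3
    sigma_bins: float = 0.5
    write_session: bool = False
    include_light: bool = True    # simulate the tagging protocol + optotag

    def __post_init__(self):
        if self.synth is None:
            self.synth = SynthConfig(seed=stage_seed(self.master_seed, 0))


def stage_seed(master_seed: int, stage_index: int) -> int:
    """Per-stage seed: SeedSequence(master).spawn-style counter scheme."""
    ss = np.random.SeedSequence([int(master_seed), int(stage_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True,
                      default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def render_percent(count: int, total: int) -> str:
    """Integer percentage, round half away from zero (22/104 -> '21%')."""
    if total == 0:
        return "0%"
    return f"{int(np.floor(count / total * 100 + 0.5))}%"


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the summary tables under ``out_dir``.

    Returns the in-memory report bundle (dict of DataFrames / dicts).
    """
    os.makedirs(config.out_dir, exist_ok=True)
    meta = {"config_hash": config_hash(config),
            "master_seed": config.master_seed,
            "stage_seeds": {s: stage_seed(config.master_seed, i)
                            for i, s in enumerate(STAGES)}}

    # -- session ------------------------------------------------------------
    if config.session_path is not None:
        bundle = session_io.read_session(config.session_path)
        truth = None
    else:
        synth_cfg = dataclasses.replace(
            config.synth, seed=meta["stage_seeds"]["simulate"])
        bundle, truth = generate_cohort(
            synth_cfg, with_light=config.include_light,
            with_waveforms=config.include_light)
        if config.write_session:
            session_io.write_session(
                bundle, os.path.join(config.out_dir, "session"))

    classes = {u.unit_id: u.genotype_label for u in bundle.units}

    # -- optotagging --------------------------------------------------------
    tag_rows = []
    if bundle.light_blocks:
        for res in optotag.optotag_session(
                bundle, alpha=config.tag_alpha,
                n_resamples=config.tag_resamples,
                seed=meta["stage_seeds"]["optotag"]):
            tag_rows.append({
                "unit_id": res.unit_id, "responsive": res.responsive,
                "baseline_limit_hz": res.baseline_limit,
                "peak_rate_hz": float(res.light_psth.max()),
                "waveform_corr": res.waveform_corr,
                "n_pulses": res.n_pulses_used})
    tag_df = pd.DataFrame(tag_rows)

    # -- behavior -----------------------------------------------------------
    trial_table = bundle.trial_table()
    performance = behavior.session_performance(trial_table)
    lin = behavior.linearize_session(bundle)
    sections = behavior.assign_sections(track_length=bundle.track_length,
                                        n_bins=lin.n_bins)

    # -- permutation + reward per unit -------------------------------------
    correct = (lin.accuracy == "correct") & (lin.task == "memory")
    sub = lin.select(correct)
    is_left = sub.trajectory == "left"
    perm_rows, diff_rows = [], []
    delay_pref, reward_pref = [], []
    for u in bundle.units:
        res = permutation.permutation_test(
            sub.unit_rates(u.unit_id), is_left, n_perms=config.n_perms,
            alpha=config.alpha, min_run=config.min_run,
            seed=meta["stage_seeds"]["permtest"] + u.unit_id,
            sigma=config.sigma_bins, unit_id=u.unit_id, sections=sections)
        rew = reward.analyze_reward(bundle.trials, u.spike_times, u.unit_id,
                                    alpha=config.alpha,
                                    sigma=config.sigma_bins)
        perm_rows.append({
            "unit_id": u.unit_id, "cell_class": classes[u.unit_id],
            **{f"points_{s}": res.points_per_section[s]
               for s in behavior.SECTION_NAMES},
            **{f"sig_{s}": res.neuron_sig_per_section[s]
               for s in behavior.SECTION_NAMES},
            "sig_reward": rew.side_pref != "ns",
            "delay_side": res.side_per_section["delay"],
            "reward_side": rew.side_pref,
            "reward_class": rew.overall})
        diff_rows.append({
            "unit_id": u.unit_id, "cell_class": classes[u.unit_id],
            **reward.section_differences(res.D0, sections, rew.D_reward)})
        delay_pref.append(res.side_per_section["delay"])
        reward_pref.append(rew.side_pref)
    perm_df = pd.DataFrame(perm_rows)
    diff_df = pd.DataFrame(diff_rows)

    report = make_report(perm_df, diff_df, performance, tag_df,
                         delay_pref, reward_pref, meta)

    # -- write artifacts ----------------------------------------------------
    perm_df.to_csv(os.path.join(config.out_dir, "trajectory_specific.tsv"),
                   sep="\t", index=False)
    diff_df.to_csv(os.path.join(config.out_dir, "section_differences.tsv"),
                   sep="\t", index=False)
    if len(tag_df):
        tag_df.to_csv(os.path.join(config.out_dir, "optotag.tsv"),
                      sep="\t", index=False)
    report["section_table"].to_csv(
        os.path.join(config.out_dir, "section_counts.tsv"), sep="\t")
    with open(os.path.join(config.out_dir, "run_meta.json"), "w") as f:
        json.dump(meta, f, indent=2, sort_keys=True)
        f.write("\n")
    if truth is not None:
        truth.to_csv(os.path.join(config.out_dir, "truth.tsv"), sep="\t",
                     index=False)
        report["truth"] = truth
    report["meta"] = meta
    return report


def make_report(perm_df, diff_df, performance, tag_df,
                delay_pref, reward_pref, meta=None) -> dict:
    """Summary tables: per-class per-section counts and percentages of
    trajectory-specific neurons, reward classification, delay x reward
    categories, and the reward-vs-maze-section correlations."""
    section_cols = [f"sig_{s}" for s in behavior.SECTION_NAMES] + [
        "sig_reward"]
    rows = {}
    groups = [("All", perm_df)]
    groups += [(c, g) for c, g in perm_df.groupby("cell_class", sort=True)]
    for name, grp in groups:
        total = len(grp)
        row = {"n": total}
        for col in section_cols:
            cnt = int(grp[col].sum()) if total else 0
            label = col.replace("sig_", "")
            row[label] = (f"n={cnt} ({render_percent(cnt, total)})"
                          if total else "n=0 (0%)")
            row[f"{label}_count"] = cnt
        rows[name] = row
    section_table = pd.DataFrame(rows).T

    correlations = {}
    for cls, grp in diff_df.groupby("cell_class", sort=True):
        if len(grp) >= 10:
            correlations[cls] = reward.section_difference_correlation(grp)

    categories = reward.delay_reward_categories(delay_pref, reward_pref)
    return {"section_table": section_table, "performance": performance,
            "correlations": correlations, "categories": categories,
            "optotag": tag_df}
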
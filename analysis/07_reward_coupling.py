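#!/usr/bin/env python
"""Reward-epoch responses and their relation to maze-section selectivity.

Per unit: the 1 s reward-consumption PSTH, excitation/inhibition
classification against the 100 ms pre-lick baseline, the left/right
reward preference, and the mean left-right difference per maze section.
Then per class: Pearson correlations of the reward difference with each
maze-section difference, and the six-category delay x reward
classification.  Writes results/reward.tsv and
results/reward_correlations.tsv.
"""

import argparse

import pandas as pd

from vta_memcode import behavior, permutation, reward, session_io


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--session", default="results/session")
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    bundle = session_io.read_session(args.session)
    lin = behavior.linearize_session(bundle)
    sub = lin.select((lin.accuracy == "correct") & (lin.task == "memory"))
    is_left = sub.trajectory == "left"
    sections = behavior.assign_sections()

    unit_rows, diff_rows = [], []
    delay_pref, reward_pref = [], []
    for u in bundle.units:
        perm = permutation.permutation_test(
            sub.unit_rates(u.unit_id), is_left, seed=args.seed + u.unit_id,
            unit_id=u.unit_id, sections=sections)
        rew = reward.analyze_reward(bundle.trials, u.spike_times, u.unit_id)
        unit_rows.append({
            "unit_id": u.unit_id, "cell_class": u.genotype_label,
            "reward_class": rew.overall, "side_pref": rew.side_pref,
            "D_reward_hz": round(rew.D_reward, 3),
            "delay_side": perm.side_per_section["delay"],
            "n_excited_segments": rew.segment_flags.count("excited")})
        diff_rows.append({"cell_class": u.genotype_label,
                          **reward.section_differences(
                              perm.D0, sections, rew.D_reward)})
        delay_pref.append(perm.side_per_section["delay"])
        reward_pref.append(rew.side_pref)

    units = pd.DataFrame(unit_rows)
    diffs = pd.DataFrame(diff_rows)
    units.to_csv(f"{args.outdir}/reward.tsv", sep="\t", index=False)

    n_exc = (units.reward_class == "excited").sum()
    n_inh = (units.reward_class == "inhibited").sum()
    print(f"reward responses: {n_exc} excited, {n_inh} inhibited, "
          f"{len(units) - n_exc - n_inh} ns of {len(units)} units")

    corr_rows = []
    for cls, grp in diffs.groupby("cell_class"):
        if len(grp) < 10:
            continue
        out = reward.section_difference_correlation(grp)
        for sec, info in out.items():
            corr_rows.append({"cell_class": cls, "section": sec,
                              "R": round(info["R"], 3),
                              "p": round(info["p"], 5)})
        print(f"{cls}: R(reward vs arms) = {out['side_arms']['R']:+.2f} "
              f"(p={out['side_arms']['p']:.4f}), "
              f"R(reward vs delay) = {out['delay']['R']:+.2f} "
              f"(p={out['delay']['p']:.3f})")
    pd.DataFrame(corr_rows).to_csv(
        f"{args.outdir}/reward_correlations.tsv", sep="\t", index=False)

    cats = reward.delay_reward_categories(delay_pref, reward_pref)
    print(f"delay x reward preference: {cats['same_side']} same side, "
          f"{cats['different']} different, {cats['neither']} neither "
          f"(n={cats['n']})")


if __name__ == "__main__":
    main()
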
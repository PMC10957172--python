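#!/usr/bin/env python
"""Simulate the default synthetic cohort and write it as a session bundle.

Generates one recording-session-like bundle — 90 trials at 87% correct,
100 DA-like units (20% planted delay-modulated), 74 GABA-like units
(47% modulated), reward responders with side preferences, and the
four-block tagging light protocol — and writes the TSV bundle plus the
ground-truth manifest under results/session/.
"""

import argparse

import numpy as np

from vta_memcode import session_io, synth


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/session")
    args = ap.parse_args()

    cfg = synth.SynthConfig(seed=args.seed)
    bundle, truth = synth.generate_cohort(cfg)
    session_io.write_session(bundle, args.out)

    n_mod = (truth.traj_modulated_sections == "delay").sum()
    n_rew = (truth.reward_response != "none").sum()
    print(f"wrote {args.out}: {len(bundle.trials)} trials, "
          f"{len(bundle.units)} units "
          f"({(truth.cell_class == 'DA').sum()} DA, "
          f"{(truth.cell_class == 'GABA').sum()} GABA)")
    print(f"planted: {n_mod} delay-modulated units, "
          f"{n_rew} reward responders, "
          f"{sum(b.pulse_onsets.size for b in bundle.light_blocks)} "
          f"light pulses")
    correct = np.mean([t.accuracy == "correct" for t in bundle.trials])
    print(f"behavior: correct rate {100 * correct:.1f}%")


if __name__ == "__main__":
    main()
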
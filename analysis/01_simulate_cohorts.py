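#!/usr/bin/env python
"""Simulate the two cohort contrasts and write session bundles to disk.

Builds a Dp1Tyb-vs-WT cohort (lower theta frequency, stronger theta-HG
coupling, higher theta coherence, longer latencies in the mutant) and a
Dp10Yey-vs-WT cohort (chance alternation and weaker theta-LG coupling
in the mutant), six animals per group, and writes them as on-disk
session bundles under scratch/cohorts/ (sessions are bulky; only the
derived tables under results/ are kept).

Run from the repository root:  python analysis/01_simulate_cohorts.py
"""

from pathlib import Path

from tmazephys import run_simulate
from tmazephys.replication import dp1tyb_contrast_configs, dp10yey_contrast_configs

OUT = Path("scratch/cohorts")
SEED = 20240101
N_ANIMALS = 6

# keep sessions short: 4 trials, brief inter-run intervals
SESSION_SCALE = dict(n_trials=4, habituation_s=20.0, inter_run_interval_s=8.0)


def doc_from(configs):
    return {group: {**cfg.to_dict(), **SESSION_SCALE}
            for group, cfg in configs.items()}


def main():
    for name, configs in (("dp1tyb", dp1tyb_contrast_configs()),
                          ("dp10yey", dp10yey_contrast_configs())):
        index = run_simulate(doc_from(configs), OUT / name,
                             n_animals=N_ANIMALS, seed=SEED)
        print(f"{name}: wrote {N_ANIMALS} animals/group -> {index}")
    print("done; next: python analysis/02_analyze_sessions.py")


if __name__ == "__main__":
    main()
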
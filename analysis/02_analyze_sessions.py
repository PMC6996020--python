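#!/usr/bin/env python
"""Run the per-animal analysis over the simulated cohorts.

Loads each cohort written by 01_simulate_cohorts.py, computes every
per-animal measure (behaviour, theta power and peak frequency per
region, theta-gamma PAC, hippocampus-mPFC coherence and phase lag,
speed-frequency fit) and writes one measures table per cohort under
results/, together with the per-epoch inclusion log.

Run from the repository root:  python analysis/02_analyze_sessions.py
"""

from pathlib import Path

import pandas as pd

from tmazephys import AnalysisConfig, run_analyze

COHORTS = Path("scratch/cohorts")
RESULTS = Path("results")


def main():
    RESULTS.mkdir(exist_ok=True)
    cfg = AnalysisConfig(habituation_s=20.0)
    for name in ("dp1tyb", "dp10yey"):
        cohort_dir = COHORTS / name
        if not cohort_dir.exists():
            raise SystemExit(f"{cohort_dir} missing; run 01_simulate_cohorts.py")
        log = []
        table = run_analyze(cohort_dir, cfg, log=log)
        table.to_csv(RESULTS / f"measures_{name}.csv", index=False)
        pd.DataFrame(log).to_csv(RESULTS / f"epochs_{name}.log.csv", index=False)
        kept = sum(e["kept"] for e in log)
        print(f"{name}: {len(table)} animals, {kept}/{len(log)} epochs kept")
        print(table[["animal_id", "group", "alternation_rate",
                     "theta_peak_hpc", "pac_hg_hpc", "pac_lg_hpc",
                     "coherence_theta"]].to_string(index=False))
    print("done; next: python analysis/03_compare_groups.py")


if __name__ == "__main__":
    main()
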
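#!/usr/bin/env python
"""Group statistics over the per-animal measures tables.

For each cohort contrast this runs the normality-gated two-sample
comparisons, the chance-level alternation tests, the Watson-Williams
circular comparison of theta phase lags, and movement-confound
residualization where pre-decision immobility differs between groups.
Writes results/comparison_<cohort>.json and prints the summary.

Run from the repository root:  python analysis/03_compare_groups.py
"""

from pathlib import Path

import pandas as pd

from tmazephys import run_compare
from tmazephys.pipeline import save_report, summarize_comparison

RESULTS = Path("results")


def main():
    for name in ("dp1tyb", "dp10yey"):
        path = RESULTS / f"measures_{name}.csv"
        if not path.exists():
            raise SystemExit(f"{path} missing; run 02_analyze_sessions.py")
        table = pd.read_csv(path)
        report = run_compare(table)
        save_report(report, RESULTS / f"comparison_{name}.json")
        print(f"\n=== {name} ===")
        print(summarize_comparison(report))
    print("\ndone; next: python analysis/04_replication_pattern.py")


if __name__ == "__main__":
    main()
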
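#!/usr/bin/env python
"""Screen phenotype indicators for significant change across the mission.

Runs the dual longitudinal test (repeated-measures ANOVA and the
rank-based ANOVA-type statistic) on each indicator's subject × day grid.
The stepwise glucose trajectory should be flagged; the mood-disturbance
trajectory may or may not reach joint significance depending on the
between-subject spread of its bump.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS_DIR = ROOT / "results" / "analysis"

from methylsync import io as msio
from methylsync.phenotypes import screen_indicators


def main() -> None:
    if not (COHORT_DIR / "phenotypes.tsv").exists():
        print("cohort not found; run analysis/01_simulate_cohort.py first", file=sys.stderr)
        return 1
    RESULTS_DIR.mkdir(parents=True, exist_ok=True)
    pheno = msio.read_phenotypes(COHORT_DIR / "phenotypes.tsv")
    screen = screen_indicators(pheno)
    screen.to_csv(RESULTS_DIR / "indicator_screen.tsv", sep="\t", index=False)
    for _, row in screen.iterrows():
        verdict = "SIGNIFICANT" if row["significant"] else "not significant"
        print(f"{row['indicator']}: ANOVA p={row['p_anova']:.2e}, "
              f"ATS p={row['p_ats']:.2e} -> {verdict}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
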
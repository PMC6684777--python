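#!/usr/bin/env python
"""Simulate the study-scale synthetic cohort.

Generates a 20,000-probe cohort of 6 subjects sampled at 6 mission days
(plus one technical replicate), with a stepwise glucose trajectory, a
mood-disturbance (TMD) trajectory, 1% planted differential probes and 1%
phenotype-synchronized probes.  The matrices are large, so they go under
scratch/cohort/; downstream analysis scripts read them from there.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS_DIR = ROOT / "results" / "analysis"
SEED = 1

from methylsync import io as msio
from methylsync.synth import SimulationConfig, simulate_dataset


def main() -> None:
    COHORT_DIR.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(n_probes=20000, seed=SEED)
    cohort = simulate_dataset(config)
    msio.write_matrix(cohort.beta, COHORT_DIR / "beta.tsv")
    msio.write_annotation(cohort.manifest, COHORT_DIR / "manifest.tsv")
    msio.write_phenotypes(cohort.phenotypes, COHORT_DIR / "phenotypes.tsv")
    msio.write_truth(cohort.truth, COHORT_DIR / "truth.tsv")
    msio.write_config(config.to_dict(), COHORT_DIR / "simulation_config.yaml")

    counts = cohort.truth["class"].value_counts().to_dict()
    print(f"cohort: {len(cohort.beta.probes)} probes x {len(cohort.beta.samples)} samples "
          f"({len(cohort.beta.subjects)} subjects, 6 timepoints + 1 replicate)")
    print(f"planted classes: {counts}")
    print(f"wrote cohort to {COHORT_DIR}")


if __name__ == "__main__":
    sys.exit(main())
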
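#!/usr/bin/env python
"""Call differentially methylated probes and score recovery of the truth.

DMPs require per-subject drift (sd_personal(β) > 0.02 in every subject)
plus significance in both longitudinal tests after BH-FDR (q < 0.05 each).
Because the planted phenotype-synchronized probes also drift over time,
they legitimately surface here too; recovery is therefore scored both
against the planted "dmp" class alone and against all planted signal.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS_DIR = ROOT / "results" / "analysis"

from methylsync import io as msio
from methylsync.dmp import call_dmps
from methylsync.qc import personal_dispersion


def main() -> None:
    if not (COHORT_DIR / "beta_filtered.tsv").exists():
        print("filtered matrix not found; run analysis/02_qc_filters.py first",
              file=sys.stderr)
        return 1
    RESULTS_DIR.mkdir(parents=True, exist_ok=True)
    beta = msio.read_matrix(COHORT_DIR / "beta_filtered.tsv")
    truth = msio.read_truth(COHORT_DIR / "truth.tsv").loc[beta.probes]

    result = call_dmps(beta, personal_dispersion(beta))
    result.to_csv(RESULTS_DIR / "dmp_results.tsv", sep="\t")
    print(f"sd filter: {result.attrs['n_tested']}/{result.attrs['n_input']} probes tested")
    print(f"flagged DMPs: {result.attrs['n_dmp']}")

    flagged = set(result.index[result["dmp"]])
    planted_dmp = set(truth.index[truth["class"] == "dmp"])
    planted_any = set(truth.index[truth["class"] != "null"])
    sens = len(flagged & planted_dmp) / max(len(planted_dmp), 1)
    frac_signal = len(flagged & planted_any) / max(len(flagged), 1)
    print(f"recovery: {sens:.2f} of planted dmp probes flagged; "
          f"{100 * frac_signal:.1f}% of flags are planted signal of some class")
    msio.write_json(
        {"n_tested": result.attrs["n_tested"], "n_dmp": result.attrs["n_dmp"],
         "sensitivity_dmp_class": sens, "frac_flags_planted": frac_signal},
        RESULTS_DIR / "dmp_recovery.json",
    )
    return 0


if __name__ == "__main__":
    sys.exit(main())
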
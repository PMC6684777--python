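#!/usr/bin/env python
"""Probe filtering and technical-vs-biological variability.

Applies the four probe-removal rules (bead-count failure, non-cg, SNP,
multi-mapping; X/Y kept), then compares technical noise — error(β) across
the replicate pair — with biological drift (per-subject sd and range of β).
Writes the filtered matrix to scratch/ and the QC summaries to results/.

Finding to look for: most retained probes show biological variation above
the technical yardstick — the premise for per-individual analysis.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS_DIR = ROOT / "results" / "analysis"

from methylsync import io as msio
from methylsync.qc import filter_probes, personal_dispersion, replicate_error


def main() -> None:
    if not (COHORT_DIR / "beta.tsv").exists():
        print("cohort not found; run analysis/01_simulate_cohort.py first", file=sys.stderr)
        return 1
    RESULTS_DIR.mkdir(parents=True, exist_ok=True)
    beta = msio.read_matrix(COHORT_DIR / "beta.tsv")
    annot = msio.read_annotation(COHORT_DIR / "manifest.tsv")

    filtered, report = filter_probes(beta, annot)
    msio.write_matrix(filtered, COHORT_DIR / "beta_filtered.tsv")
    msio.write_json(report.to_dict(), RESULTS_DIR / "filter_report.json")
    print(f"filtering: retained {report.retained}/{len(beta.probes)} probes; "
          f"removed per rule {report.removed}")

    err, err_summary = replicate_error(filtered)
    metrics = personal_dispersion(filtered)
    disp = metrics.summary()
    msio.write_json({"replicate_error": err_summary, "dispersion": disp},
                    RESULTS_DIR / "qc_summary.json")
    print(f"technical: {100 * err_summary['frac_below_threshold']:.1f}% of probes have "
          f"error(beta) < {err_summary['threshold']} (P75 = {err_summary['q75']:.4f})")
    print(f"biological: {100 * disp['frac_sd_above']:.1f}% of probe-subject series have "
          f"sd_personal > {disp['sd_threshold']}; "
          f"{100 * disp['frac_range_above']:.1f}% have range > {disp['range_threshold']}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
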
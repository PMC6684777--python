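"""End-to-end pipeline: simulate/load → filter → QC → DMP → enrichment →
indicator screen → per-subject PeSa scans → gene aggregation → summary.

Every stage writes its table under the output directory, and a single
``run_summary.json`` collects the bookkeeping counts (probes retained,
candidates and passing probes per subject, consistent genes, ...).  The
resolved configuration and seed are written alongside, so any run is
reproducible bit-identically from its output directory.
"""

from __future__ import annotations

import logging
import sys
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import io as msio
from .containers import BetaMatrix
from .dmp import call_dmps, location_enrichment
from .pesa import aggregate_genes, pesa_scan, rank_sync_probes
from .phenotypes import screen_indicators
from .qc import filter_probes, personal_dispersion, replicate_error
from .synth import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths, thresholds and the seed for one pipeline run.

    When ``beta_path`` is None the run starts by simulating a cohort with
    ``n_probes`` probes at ``seed``.
    """

    out_dir: str = "results/run"
    seed: int = 0
    n_probes: int = 20000
    beta_path: str | None = None
    design_path: str | None = None
    manifest_path: str | None = None
    pheno_path: str | None = None
    alpha: float = 0.05
    sd_cut_dmp: float = 0.02
    sd_min_pesa: float = 0.01
    beadfail: float = 0.05
    error_threshold: float = 0.008
    indicators: tuple[str, ...] = ("glucose", "tmd")

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("alpha", 0.0, 1.0),
            ("beadfail", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.sd_cut_dmp < 0 or self.sd_min_pesa < 0 or self.error_threshold <= 0:
            raise ValueError("thresholds must be positive")


def _setup_logging() -> None:
    if not logging.getLogger("methylsync").handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        root = logging.getLogger("methylsync")
        root.addHandler(handler)
        root.setLevel(logging.INFO)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and write all artifacts under ``out_dir``.

    Returns the run-summary dict (also written as ``run_summary.json``).
    Any stage failure raises, naming the stage.
    """
    _setup_logging()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    stage = "configure"
    try:
        msio.write_config(asdict(config), out / "resolved_config.yaml")

        if config.beta_path is None:
            stage = "simulate"
            logger.info("simulating cohort: %d probes, seed %d", config.n_probes, config.seed)
            sim = SimulationConfig(n_probes=config.n_probes, seed=config.seed)
            cohort = simulate_dataset(sim)
            beta, manifest, pheno, truth = (
                cohort.beta,
                cohort.manifest,
                cohort.phenotypes,
                cohort.truth,
            )
            msio.write_matrix(beta, out / "beta.tsv")
            msio.write_annotation(manifest, out / "manifest.tsv")
            msio.write_phenotypes(pheno, out / "phenotypes.tsv")
            msio.write_truth(truth, out / "truth.tsv")
        else:
            stage = "load"
            beta = msio.read_matrix(config.beta_path, config.design_path)
            manifest = msio.read_annotation(config.manifest_path)
            pheno = msio.read_phenotypes(config.pheno_path)
            truth = None
        summary["n_probes_input"] = len(beta.probes)

        stage = "filter"
        beta_f, report = filter_probes(beta, manifest, beadfail_threshold=config.beadfail)
        msio.write_json(report.to_dict(), out / "filter_report.json")
        summary["filter"] = report.to_dict()
        logger.info("filter: retained %d probes", report.retained)

        stage = "qc"
        err, err_summary = replicate_error(beta_f, threshold=config.error_threshold)
        metrics = personal_dispersion(beta_f)
        disp_summary = metrics.summary()
        msio.write_json(
            {"replicate_error": err_summary, "dispersion": disp_summary},
            out / "qc_summary.json",
        )
        summary["replicate_error"] = err_summary
        summary["dispersion"] = {
            k: disp_summary[k] for k in ("frac_sd_above", "frac_range_above")
        }

        stage = "indicator_screen"
        screen = screen_indicators(pheno, alpha=config.alpha)
        screen.to_csv(out / "indicator_screen.tsv", sep="\t", index=False)
        summary["indicators_significant"] = screen[screen["significant"]][
            "indicator"
        ].tolist()

        stage = "dmp"
        dmp_result = call_dmps(
            beta_f, metrics, alpha=config.alpha, sd_cut=config.sd_cut_dmp
        )
        dmp_result.to_csv(out / "dmp_results.tsv", sep="\t")
        summary["dmp"] = {
            k: dmp_result.attrs[k] for k in ("n_input", "n_tested", "n_dmp")
        }
        logger.info(
            "dmp: %d tested, %d flagged", dmp_result.attrs["n_tested"], dmp_result.attrs["n_dmp"]
        )

        stage = "enrichment"
        dmp_ids = dmp_result.index[dmp_result["dmp"]] if len(dmp_result) else []
        universe = beta_f.probes
        for grouping in ("cgi_relation", "gene_feature"):
            enr = location_enrichment(dmp_ids, universe, manifest, grouping=grouping)
            enr.to_csv(out / f"enrichment_{grouping}.tsv", sep="\t", index=False)

        stage = "pesa"
        pesa_summary = {}
        for indicator in config.indicators:
            if indicator not in pheno.columns:
                warnings.warn(f"indicator {indicator!r} not in phenotype table; skipped")
                continue
            results = []
            per_subject = {}
            for subject in beta_f.subjects:
                res = pesa_scan(
                    beta_f,
                    pheno,
                    subject,
                    indicator,
                    sd_min=config.sd_min_pesa,
                    alpha=config.alpha,
                    metrics=metrics,
                )
                results.append(res)
                per_subject[subject] = {
                    "n_candidates": res.attrs["n_candidates"],
                    "n_passing": res.attrs["n_passing"],
                    "frac_passing": res.attrs["frac_passing"],
                }
            calls = pd.concat(results, ignore_index=True)
            calls_pass = calls[calls["pass"]]
            rank_sync_probes(calls_pass).to_csv(
                out / f"pesa_{indicator}.tsv", sep="\t", index=False
            )
            stage = "aggregate"
            genes = aggregate_genes(results, manifest)
            genes.to_csv(out / f"gene_consistency_{indicator}.tsv", sep="\t", index=False)
            pesa_summary[indicator] = {
                "per_subject": per_subject,
                "n_consistent_all_genes": int(genes["consistent_all"].sum())
                if len(genes)
                else 0,
            }
            stage = "pesa"
        summary["pesa"] = pesa_summary

        stage = "report"
        msio.write_json(summary, out / "run_summary.json")
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    logger.info("pipeline complete: %s", out / "run_summary.json")
    return summary
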
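"""Probe filtering and variability metrics for beta-value matrices.

The probe filter applies the four standard removal rules for 450k-style
arrays — bead-count failures, non-cg probes, SNP-overlapping probes, and
multi-mapping probes — while keeping X/Y probes (appropriate for a
single-sex cohort).  The variability metrics compare technical noise
(error(β): absolute difference between one pair of replicate
hybridizations) with biological drift (sd_personal(β) and
range_personal(β): per-subject standard deviation and range of a probe's
beta across that subject's sampling points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BetaMatrix, validate_annotation

__all__ = [
    "FilterReport",
    "VariabilityMetrics",
    "filter_probes",
    "replicate_error",
    "personal_dispersion",
]

#: Removal rules in precedence order; each probe is counted once, at the
#: first rule it matches.
FILTER_RULES = ("beadfail", "non_cg", "snp", "multimap")


@dataclass
class FilterReport:
    removed: dict[str, int]
    retained: int
    removed_ids: dict[str, list[str]] = field(default_factory=dict)

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())

    def to_dict(self) -> dict:
        return {"removed": dict(self.removed), "retained": self.retained}


@dataclass
class VariabilityMetrics:
    """Per-probe, per-subject dispersion of beta across sampling points.

    ``sd_personal`` and ``range_personal`` are probes × subjects frames;
    SDs use the sample (n−1) divisor.  A probe with any missing value in a
    subject's series gets NaN for that subject.
    """

    sd_personal: pd.DataFrame
    range_personal: pd.DataFrame

    def summary(self, sd_threshold: float = 0.012, range_threshold: float = 0.016) -> dict:
        """Fractions of (probe, subject) entries whose dispersion exceeds
        the given thresholds, plus per-subject breakdowns."""
        sd = self.sd_personal.to_numpy()
        rg = self.range_personal.to_numpy()
        return {
            "sd_threshold": sd_threshold,
            "range_threshold": range_threshold,
            "frac_sd_above": float(np.nanmean(sd > sd_threshold)),
            "frac_range_above": float(np.nanmean(rg > range_threshold)),
            "frac_sd_above_per_subject": {
                s: float(np.nanmean(self.sd_personal[s] > sd_threshold))
                for s in self.sd_personal.columns
            },
            "frac_range_above_per_subject": {
                s: float(np.nanmean(self.range_personal[s] > range_threshold))
                for s in self.range_personal.columns
            },
        }

    def min_sd_across_subjects(self) -> pd.Series:
        return self.sd_personal.min(axis=1)


def filter_probes(
    beta: BetaMatrix,
    annot: pd.DataFrame,
    beadfail_threshold: float = 0.05,
) -> tuple[BetaMatrix, FilterReport]:
    """Apply the four probe-removal rules; X/Y probes are retained.

    Rules, in order (a probe is counted under the first one it matches):
    ``beadfail`` (bead-count failure in ≥ ``beadfail_threshold`` of
    samples), ``non_cg`` (probe type ch or rs), ``snp`` (SNP overlap),
    ``multimap`` (aligns to multiple genomic locations).
    """
    validate_annotation(annot, probes=beta.probes)
    ann = annot.loc[beta.probes]
    masks = {
        "beadfail": ann["beadfail_frac"].to_numpy(dtype=float) >= beadfail_threshold,
        "non_cg": ann["probe_type"].to_numpy() != "cg",
        "snp": ann["snp_flag"].to_numpy(dtype=bool),
        "multimap": ann["multimap_flag"].to_numpy(dtype=bool),
    }
    already = np.zeros(len(ann), dtype=bool)
    removed: dict[str, int] = {}
    removed_ids: dict[str, list[str]] = {}
    for rule in FILTER_RULES:
        hit = masks[rule] & ~already
        removed[rule] = int(hit.sum())
        removed_ids[rule] = list(beta.probes[hit])
        already |= masks[rule]
    keep = beta.probes[~already]
    filtered = beta.subset_probes(keep)
    return filtered, FilterReport(removed=removed, retained=len(keep), removed_ids=removed_ids)


def replicate_error(
    beta: BetaMatrix, threshold: float = 0.008
) -> tuple[pd.Series, dict]:
    """Per-probe error(β) for the replicate pair plus a quantile summary.

    error(β) = |β_rep1 − β_rep2|.  The summary reports the 0.25/0.5/0.75
    quantiles (linear interpolation between order statistics) and the
    fraction of probes with error(β) below ``threshold``.
    """
    a, b = beta.replicate_pair()
    err = (beta.values[a] - beta.values[b]).abs().rename("error_beta")
    clean = err.dropna().to_numpy()
    qs = np.quantile(clean, [0.25, 0.5, 0.75]) if clean.size else [np.nan] * 3
    summary = {
        "q25": float(qs[0]),
        "q50": float(qs[1]),
        "q75": float(qs[2]),
        "threshold": threshold,
        "frac_below_threshold": float(np.mean(clean < threshold)) if clean.size else np.nan,
        "n_probes": int(clean.size),
    }
    return err, summary


def personal_dispersion(beta: BetaMatrix) -> VariabilityMetrics:
    """sd_personal(β) and range_personal(β) per probe per subject.

    Replicate columns are excluded (the first-listed member of the pair
    represents its subject/timepoint).  Each subject needs ≥2 sampling
    points.
    """
    core = beta.drop_replicates()
    sds = {}
    ranges = {}
    for subject in core.subjects:
        series = core.subject_series(subject)
        if series.shape[1] < 2:
            raise ValueError(
                f"subject {subject!r} has {series.shape[1]} timepoints; ≥2 required"
            )
        vals = series.to_numpy(dtype=float)
        complete = ~np.isnan(vals).any(axis=1)
        sd = np.full(len(series), np.nan)
        rg = np.full(len(series), np.nan)
        sd[complete] = vals[complete].std(axis=1, ddof=1)
        rg[complete] = vals[complete].max(axis=1) - vals[complete].min(axis=1)
        sds[subject] = sd
        ranges[subject] = rg
    index = core.probes
    return VariabilityMetrics(
        sd_personal=pd.DataFrame(sds, index=index),
        range_personal=pd.DataFrame(ranges, index=index),
    )
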
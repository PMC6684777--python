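"""Per-individual phenotype-synchronized methylation-site discovery (PeSa).

A probe is called synchronized with a phenotype *within one subject* when
both of two Pearson tests are significant across that subject's sampling
points:

i.   correlation of the raw time courses A = (a_1..a_i), B = (b_1..b_i);
ii.  "slope correlation": correlation of the first-difference series
     A* = (a_2−a_1, ..., a_i−a_{i−1}) and B*, which compares the shapes of
     the two trajectories rather than their levels.

The dual criterion (both two-sided p-values < α, default 0.05) demands that
a probe track the phenotype both in level and in step-to-step movement.
Synchronization is sign-agnostic: anti-phase tracking (ρ < 0) passes, with
the direction reported through ρ.  A constant series (including an exactly
linear trajectory, whose slope series is constant) yields p = 1 by
convention, so such probes never pass — conservative by design.

The per-subject scan restricts candidates to probes whose biological
variation exceeds the technical yardstick (sd_personal(β) > ``sd_min``,
default 0.01) and evaluates them at the sampling days shared between the
methylation and phenotype series.  Cross-subject aggregation maps passing
probes to gene symbols (intergenic probes are dropped) and ranks genes by
the number of distinct subjects in which they carry a passing probe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import BetaMatrix, annotation_gene_lists
from .qc import personal_dispersion

logger = logging.getLogger(__name__)

__all__ = [
    "SyncCall",
    "pearson_corr_p",
    "slope_series",
    "pesa_probe",
    "pesa_scan",
    "aggregate_genes",
    "rank_sync_probes",
]


@dataclass(frozen=True)
class SyncCall:
    probe: str | None
    subject: str | None
    rho_corr: float
    p_corr: float
    rho_slope: float
    p_slope: float
    passed: bool
    alpha: float


def pearson_corr_p(a, b) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided p-value.

    p comes from t = ρ·√((i−2)/(1−ρ²)) on i−2 degrees of freedom; |ρ| = 1
    gives p = 0.  A constant input has no defined correlation: returns
    (nan, 1.0) — never significant — and logs the event.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D and equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need ≥3 points for a correlation p-value, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        logger.info("pearson_corr_p: constant input; returning rho=nan, p=1")
        return float("nan"), 1.0
    rho = float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))
    p = _pearson_p(np.array([rho]), n)[0]
    return rho, float(p)


def _pearson_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for an array of correlations at common length n."""
    df = n - 2
    one_minus = 1.0 - rho**2
    p = np.zeros_like(rho, dtype=float)
    interior = one_minus > 0
    t = np.abs(rho[interior]) * np.sqrt(df / one_minus[interior])
    p[interior] = 2.0 * sps.t.sf(t, df)
    return np.minimum(p, 1.0)


def slope_series(a) -> np.ndarray:
    """First differences of a time course (length i−1, order preserved)."""
    x = np.asarray(a, dtype=float)
    if x.size < 2:
        raise ValueError("slope series requires ≥2 points")
    return np.diff(x)


def pesa_probe(a, b, alpha: float = 0.05, probe=None, subject=None) -> SyncCall:
    """Dual Pearson test of one probe/phenotype pair (see module docs)."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 4:
        raise ValueError("need ≥4 sampling points (slope correlation needs ≥3 differences)")
    rho_c, p_c = pearson_corr_p(x, y)
    rho_s, p_s = pearson_corr_p(slope_series(x), slope_series(y))
    passed = bool(p_c < alpha and p_s < alpha)
    return SyncCall(probe, subject, rho_c, p_c, rho_s, p_s, passed, alpha)


def _row_corr(matrix: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Pearson correlation of each matrix row with vec; constant rows → nan."""
    mc = matrix - matrix.mean(axis=1, keepdims=True)
    vc = vec - vec.mean()
    sm = np.sqrt((mc**2).sum(axis=1))
    sv = np.sqrt(vc @ vc)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (mc @ vc) / (sm * sv)
    rho[(sm == 0) | (sv == 0)] = np.nan
    return np.clip(rho, -1.0, 1.0)


def pesa_scan(
    beta: BetaMatrix,
    phenotype: pd.DataFrame,
    subject: str,
    indicator: str,
    sd_min: float = 0.01,
    alpha: float = 0.05,
    metrics=None,
) -> pd.DataFrame:
    """Scan one subject's methylome for probes synchronized with one indicator.

    Candidates are probes with sd_personal(β) > ``sd_min`` for this subject
    (``metrics`` may supply precomputed dispersion).  Each candidate is
    tested by the dual Pearson criterion against the subject's phenotype
    series at the sampling days present in both tables.

    Returns a frame (probe, subject, rho_corr, p_corr, rho_slope, p_slope,
    pass) with scan bookkeeping in ``attrs``: ``n_candidates``,
    ``n_passing``, ``frac_passing``.
    """
    series = beta.subject_series(subject)
    ph = phenotype[phenotype["subject"] == subject].set_index("day")[indicator].dropna()
    shared = [d for d in series.columns if d in ph.index]
    if not shared:
        raise ValueError(
            f"no shared sampling days between methylation and {indicator!r} for {subject}"
        )
    if len(shared) < 4:
        raise ValueError(
            f"only {len(shared)} shared sampling days for {subject}; ≥4 required"
        )
    if metrics is None:
        metrics = personal_dispersion(beta)
    sd = metrics.sd_personal[subject]
    candidates = sd.index[sd > sd_min]
    x = series.loc[candidates, shared].to_numpy(dtype=float)
    y = ph.loc[shared].to_numpy(dtype=float)
    t = len(shared)

    rho_c = _row_corr(x, y)
    p_c = np.where(np.isnan(rho_c), 1.0, _pearson_p(np.nan_to_num(rho_c), t))
    dx = np.diff(x, axis=1)
    dy = np.diff(y)
    rho_s = _row_corr(dx, dy)
    p_s = np.where(np.isnan(rho_s), 1.0, _pearson_p(np.nan_to_num(rho_s), t - 1))
    passed = (p_c < alpha) & (p_s < alpha)

    out = pd.DataFrame(
        {
            "probe": candidates,
            "subject": subject,
            "rho_corr": rho_c,
            "p_corr": p_c,
            "rho_slope": rho_s,
            "p_slope": p_s,
            "pass": passed,
        }
    ).reset_index(drop=True)
    out.attrs["n_candidates"] = int(len(candidates))
    out.attrs["n_passing"] = int(passed.sum())
    out.attrs["frac_passing"] = float(passed.mean()) if len(candidates) else 0.0
    out.attrs["alpha"] = alpha
    out.attrs["sd_min"] = sd_min
    return out


def aggregate_genes(results, annot: pd.DataFrame) -> pd.DataFrame:
    """Cross-subject gene consistency of passing probes.

    Maps each passing probe to its gene symbols (intergenic probes, which
    carry none, contribute nothing), collects the set of subjects in which
    each gene has ≥1 passing probe, and sorts genes by that consistency
    count (descending), then by symbol.  Genes found in every scanned
    subject are flagged ``consistent_all``.
    """
    frames = [r for r in results if len(r)]
    if not frames:
        return pd.DataFrame(
            columns=["gene", "n_subjects", "subjects", "probes", "consistent_all"]
        )
    calls = pd.concat(frames, ignore_index=True)
    n_scanned = calls["subject"].nunique()
    gene_lists = annotation_gene_lists(annot)
    passing = calls[calls["pass"]]
    records: dict[str, dict] = {}
    for probe, subject in zip(passing["probe"], passing["subject"]):
        for gene in gene_lists.get(probe, []):
            rec = records.setdefault(gene, {"subjects": set(), "probes": set()})
            rec["subjects"].add(subject)
            rec["probes"].add(f"{subject}:{probe}")
    rows = [
        {
            "gene": g,
            "n_subjects": len(rec["subjects"]),
            "subjects": ";".join(sorted(rec["subjects"])),
            "probes": ";".join(sorted(rec["probes"])),
            "consistent_all": len(rec["subjects"]) == n_scanned,
        }
        for g, rec in records.items()
    ]
    out = pd.DataFrame(rows, columns=["gene", "n_subjects", "subjects", "probes", "consistent_all"])
    out = out.sort_values(
        ["n_subjects", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    out.attrs["n_scanned_subjects"] = n_scanned
    return out


def rank_sync_probes(result: pd.DataFrame, top_k: int | None = None, signed: bool = False) -> pd.DataFrame:
    """Order sync calls for downstream enrichment.

    Default ranking is by |ρ_corr| descending (synchronization is
    sign-agnostic), ties broken by p_corr ascending then probe id;
    ``signed=True`` ranks by ρ itself.
    """
    df = result.copy()
    key = df["rho_corr"] if signed else df["rho_corr"].abs()
    df["_key"] = key.fillna(-np.inf)
    df = df.sort_values(
        ["_key", "p_corr", "probe"], ascending=[False, True, True], kind="stable"
    ).drop(columns="_key").reset_index(drop=True)
    if top_k is not None:
        df = df.head(top_k)
    return df
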
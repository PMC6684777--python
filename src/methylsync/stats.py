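"""Longitudinal test statistics for small complete subject × time grids.

Two tests are provided for the time effect in a one-factor repeated-measures
design:

* :func:`rm_anova_pvalue` — the classical parametric F test with subject as
  a blocking factor, F = MS_time / MS_error on (t−1, (n−1)(t−1)) df.
* :func:`ats_pvalue` — the rank-based ANOVA-type statistic (ATS) for
  longitudinal data.  All N = n·t observations are mid-ranked jointly, each
  subject's rank profile is scaled to Y_i = R_i / N, and with
  T = I_t − J_t/t and V̂ the sample covariance of the Y_i,

      Q = n · p̂ᵀ T p̂ / tr(T V̂),      f̂ = tr(T V̂)² / tr(T V̂ T V̂),

  with p̂ the mean profile (the relative treatment effects).  Q is referred
  to F(f̂, ∞), i.e. p = P(χ²_f̂ > f̂·Q) — the Box-type approximation used for
  a single within-subject factor.

Both tests treat degenerate grids conservatively: a statistic that is
0/0 (no error variation, or identical flat rank profiles) yields p = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "LongitudinalTestResult",
    "mid_ranks",
    "rm_anova_pvalue",
    "ats_pvalue",
    "ats_pvalue_batch",
    "bh_fdr",
]

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class LongitudinalTestResult:
    """Outcome of one longitudinal test on a subject × time grid."""

    statistic: float
    df_num: float
    df_den: float | None
    p_value: float
    method: str  # "rm_anova" | "ats"


def _as_grid(data) -> np.ndarray:
    grid = np.asarray(data, dtype=float)
    if grid.ndim != 2:
        raise ValueError(f"expected a 2-D subjects × timepoints grid, got shape {grid.shape}")
    n, t = grid.shape
    if n < 2 or t < 2:
        raise ValueError(f"need ≥2 subjects and ≥2 timepoints, got {n}×{t}")
    if not np.all(np.isfinite(grid)):
        raise ValueError("grid contains non-finite values; complete cases are required")
    return grid


def mid_ranks(values) -> np.ndarray:
    """Mid-ranks of a flat vector; ties get the average of the ranks they span."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values cannot be ranked")
    return sps.rankdata(arr, method="average")


def rm_anova_pvalue(data) -> LongitudinalTestResult:
    """One-way repeated-measures ANOVA for the time effect.

    Subject is the blocking factor; no sphericity correction is applied by
    default (pass ``greenhouse_geisser=True`` via :func:`rm_anova_pvalue_gg`
    semantics below).  Grids with (numerically) zero error sum of squares
    cannot support an F ratio and return p = 1.
    """
    return _rm_anova(data, greenhouse_geisser=False)


def rm_anova_pvalue_gg(data) -> LongitudinalTestResult:
    """Repeated-measures ANOVA with the Greenhouse–Geisser df correction."""
    return _rm_anova(data, greenhouse_geisser=True)


def _rm_anova(data, greenhouse_geisser: bool) -> LongitudinalTestResult:
    grid = _as_grid(data)
    n, t = grid.shape
    gm = grid.mean()
    ss_time = n * np.sum((grid.mean(axis=0) - gm) ** 2)
    ss_subj = t * np.sum((grid.mean(axis=1) - gm) ** 2)
    ss_tot = np.sum((grid - gm) ** 2)
    ss_err = ss_tot - ss_time - ss_subj
    df_time = t - 1
    df_err = (n - 1) * (t - 1)
    scale = max(ss_tot, 1.0)
    if ss_err <= _DEGENERATE_TOL * scale:
        logger.info("rm_anova: zero error sum of squares; returning p=1 by convention")
        return LongitudinalTestResult(np.nan, df_time, df_err, 1.0, "rm_anova")
    f_stat = (ss_time / df_time) / (ss_err / df_err)
    if greenhouse_geisser:
        eps = _gg_epsilon(grid)
        p = float(sps.f.sf(f_stat, eps * df_time, eps * df_err))
        return LongitudinalTestResult(float(f_stat), eps * df_time, eps * df_err, p, "rm_anova")
    p = float(sps.f.sf(f_stat, df_time, df_err))
    return LongitudinalTestResult(float(f_stat), float(df_time), float(df_err), p, "rm_anova")


def _gg_epsilon(grid: np.ndarray) -> float:
    # Greenhouse-Geisser epsilon from the double-centred covariance matrix.
    t = grid.shape[1]
    s = np.cov(grid, rowvar=False, ddof=1)
    centred = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    num = np.trace(centred) ** 2
    den = (t - 1) * np.sum(centred**2)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (t - 1))))


def ats_pvalue(data) -> LongitudinalTestResult:
    """Rank-based ANOVA-type statistic for the time effect (see module docs)."""
    grid = _as_grid(data)
    stat, df, p = _ats_from_grids(grid[None, :, :])
    if np.isnan(stat[0]):
        logger.info("ats: degenerate rank covariance; returning p=1 by convention")
    return LongitudinalTestResult(float(stat[0]), float(df[0]), None, float(p[0]), "ats")


def ats_pvalue_batch(grids: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized ATS over a stack of grids, shape (batch, subjects, timepoints).

    Returns ``(statistic, df_num, p)`` arrays of length ``batch``.  Used by
    simulation-heavy callers; :func:`ats_pvalue` is the single-grid wrapper.
    """
    grids = np.asarray(grids, dtype=float)
    if grids.ndim != 3:
        raise ValueError("expected shape (batch, subjects, timepoints)")
    return _ats_from_grids(grids)


def _ats_from_grids(grids: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    b, n, t = grids.shape
    flat = grids.reshape(b, n * t)
    ranks = sps.rankdata(flat, method="average", axis=1).reshape(b, n, t)
    return _ats_from_ranks(ranks)


def _ats_from_ranks(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ATS from per-grid joint mid-ranks, shape (batch, n, t)."""
    b, n, t = ranks.shape
    y = ranks / (n * t)
    phat = y.mean(axis=1)  # (b, t)
    centred = y - phat[:, None, :]
    v = np.einsum("bit,biu->btu", centred, centred) / (n - 1)  # (b, t, t)
    # T = I - J/t; exploit TV traces: tr(TV) = tr(V) - sum(V)/t
    tr_v = np.einsum("btt->b", v)
    sum_v = v.sum(axis=(1, 2))
    tr_tv = tr_v - sum_v / t
    tv = v - v.mean(axis=1, keepdims=True)  # T @ V with T = I - J/t
    tr_tvtv = np.einsum("btu,but->b", tv, tv)
    # numerator p̂ᵀTp̂ = Σ(p̂_j − mean p̂)²
    quad = ((phat - phat.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    stat = np.full(b, np.nan)
    df = np.full(b, np.nan)
    p = np.ones(b)
    ok = tr_tv > _DEGENERATE_TOL
    ok_df = ok & (tr_tvtv > _DEGENERATE_TOL)
    stat[ok] = n * quad[ok] / tr_tv[ok]
    df[ok_df] = tr_tv[ok_df] ** 2 / tr_tvtv[ok_df]
    good = ok_df & np.isfinite(stat)
    p[good] = sps.chi2.sf(df[good] * stat[good], df[good])
    return stat, df, p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
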
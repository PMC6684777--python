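"""Mood-state scoring and the biochemical-indicator screen.

The Profile of Mood States (POMS) questionnaire yields six subscale
scores — Tension-Anxiety (TA), Depression-Dejection (DD), Anger-Hostility
(AH), Fatigue-Inertia (FI), Confusion-Bewilderment (CB) and
Vigor-Activity (VA).  Total Mood Disturbance is

    TMD = TA + DD + AH + FI + CB − VA

(raw subscale scores, no normative offset).

The indicator screen runs both longitudinal tests (repeated-measures ANOVA
and the rank-based ANOVA-type statistic) on each indicator's complete
subject × day grid and flags an indicator as significantly changed across
the mission when both raw p-values fall below α — no FDR, matching the
handful-of-indicators setting.  A disjunctive ("either test") rule is
available via ``rule="or"``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats import ats_pvalue, rm_anova_pvalue

__all__ = ["POMS_SUBSCALES", "tmd_score", "tmd_scores", "screen_indicators"]

#: The six POMS subscales; VA enters TMD with a negative sign.
POMS_SUBSCALES = ("TA", "DD", "AH", "FI", "CB", "VA")


def tmd_score(record) -> float:
    """Total Mood Disturbance from one record of the six POMS subscales.

    ``record`` is any mapping (dict, Series, DataFrame row) with keys
    TA, DD, AH, FI, CB, VA.  A missing subscale raises, naming it.
    """
    vals = {}
    for key in POMS_SUBSCALES:
        try:
            v = record[key]
        except (KeyError, IndexError):
            raise KeyError(f"POMS subscale {key!r} missing from record") from None
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise KeyError(f"POMS subscale {key!r} missing from record")
        vals[key] = float(v)
    return vals["TA"] + vals["DD"] + vals["AH"] + vals["FI"] + vals["CB"] - vals["VA"]


def tmd_scores(poms: pd.DataFrame) -> pd.DataFrame:
    """Append a ``tmd`` column to a POMS table (subject, day, subscales)."""
    out = poms.copy()
    out["tmd"] = [tmd_score(row) for _, row in poms.iterrows()]
    return out


def screen_indicators(
    pheno: pd.DataFrame,
    alpha: float = 0.05,
    rule: str = "and",
) -> pd.DataFrame:
    """Screen each indicator for significant change across sampling points.

    ``pheno`` is tidy: columns ``subject``, ``day``, then one column per
    indicator.  Indicators whose subject × day grid is incomplete are
    skipped with a warning.  Returns one row per tested indicator with
    ``p_anova``, ``p_ats`` and the ``significant`` flag.
    """
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    indicators = [c for c in pheno.columns if c not in ("subject", "day")]
    n_subj = pheno["subject"].nunique()
    n_days = pheno["day"].nunique()
    if n_subj < 2 or n_days < 2:
        raise ValueError("need ≥2 subjects and ≥2 sampling days")
    rows = []
    for ind in indicators:
        grid = pheno.pivot_table(index="subject", columns="day", values=ind, aggfunc="first")
        if grid.isna().any().any() or grid.shape != (n_subj, n_days):
            warnings.warn(f"indicator {ind!r} has an incomplete grid; skipped")
            continue
        values = grid.sort_index(axis=1).to_numpy(dtype=float)
        p_a = rm_anova_pvalue(values).p_value
        p_t = ats_pvalue(values).p_value
        sig = (p_a < alpha and p_t < alpha) if rule == "and" else (p_a < alpha or p_t < alpha)
        rows.append({"indicator": ind, "p_anova": p_a, "p_ats": p_t, "significant": sig})
    out = pd.DataFrame(rows, columns=["indicator", "p_anova", "p_ats", "significant"])
    out.attrs.update({"alpha": alpha, "rule": rule})
    return out
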
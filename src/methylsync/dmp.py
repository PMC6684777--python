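"""Differential-methylation calling and category enrichment.

A probe is a DMP (differentially methylated probe) when three conditions
hold: per-subject drift exceeds the stringency cutoff (sd_personal(β) >
``sd_cut``, default 0.02, in *every* subject), and both longitudinal tests
— the parametric repeated-measures ANOVA and the rank-based ANOVA-type
statistic — are significant after Benjamini–Hochberg correction (q < α in
each).  FDR is computed within the sd-filtered tested set, matching the
filter-then-test sequence.

Enrichment of a probe set over genomic-location categories (gene-feature
groups or CpG-island relations) uses observed/expected frequencies with
one-sided hypergeometric tail p-values in each direction.  CGI enrichment
is strictly per-probe; gene-feature enrichment counts (probe, feature)
pairs, because a multi-gene probe can sit in several feature groups at
once.  The same machinery serves user-supplied gene sets (GMT-style) in
place of external annotation-database queries.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import BetaMatrix, annotation_feature_lists
from .qc import VariabilityMetrics
from .stats import ats_pvalue, bh_fdr, rm_anova_pvalue

logger = logging.getLogger(__name__)

__all__ = [
    "call_dmps",
    "location_enrichment",
    "gene_set_enrichment",
    "collapse_cgi",
]


def call_dmps(
    beta: BetaMatrix,
    metrics: VariabilityMetrics,
    alpha: float = 0.05,
    sd_cut: float = 0.02,
) -> pd.DataFrame:
    """Dual-test DMP calling (see module docs).

    Returns a frame indexed by tested probe with columns ``p_anova``,
    ``q_anova``, ``p_ats``, ``q_ats``, ``min_sd_personal`` and ``dmp``;
    stage counts, ``alpha`` and ``sd_cut`` live in ``attrs``.  An empty
    tested set yields an empty frame with a warning, not an error.
    """
    core = beta.drop_replicates()
    sd = metrics.sd_personal.loc[core.probes]
    tested = core.probes[(sd > sd_cut).all(axis=1).to_numpy()]
    n_input = len(core.probes)
    if len(tested) == 0:
        warnings.warn("no probes exceed the sd_personal cutoff; empty DMP result")
        out = pd.DataFrame(
            columns=["p_anova", "q_anova", "p_ats", "q_ats", "min_sd_personal", "dmp"]
        )
        out.attrs.update(
            {"alpha": alpha, "sd_cut": sd_cut, "n_input": n_input, "n_tested": 0, "n_dmp": 0}
        )
        return out

    subjects = core.subjects
    grids = np.stack(
        [core.subject_series(s).loc[tested].to_numpy(dtype=float) for s in subjects],
        axis=1,
    )  # (probes, subjects, timepoints)
    if np.isnan(grids).any():
        bad = tested[np.isnan(grids).any(axis=(1, 2))]
        raise ValueError(
            f"{len(bad)} tested probes have missing values (e.g. {list(bad[:3])}); "
            "drop incomplete probes before DMP calling"
        )
    p_anova = np.empty(len(tested))
    p_ats = np.empty(len(tested))
    for k in range(len(tested)):
        p_anova[k] = rm_anova_pvalue(grids[k]).p_value
        p_ats[k] = ats_pvalue(grids[k]).p_value
    q_anova = bh_fdr(p_anova)
    q_ats = bh_fdr(p_ats)
    flag = (q_anova < alpha) & (q_ats < alpha)
    out = pd.DataFrame(
        {
            "p_anova": p_anova,
            "q_anova": q_anova,
            "p_ats": p_ats,
            "q_ats": q_ats,
            "min_sd_personal": sd.loc[tested].min(axis=1).to_numpy(),
            "dmp": flag,
        },
        index=tested,
    )
    out.index.name = "probe_id"
    out.attrs.update(
        {
            "alpha": alpha,
            "sd_cut": sd_cut,
            "n_input": n_input,
            "n_tested": int(len(tested)),
            "n_dmp": int(flag.sum()),
        }
    )
    return out


# ---------------------------------------------------------------------------
# enrichment

_CGI_COLLAPSE = {
    "N_Shore": "Shore",
    "S_Shore": "Shore",
    "N_Shelf": "Shelf",
    "S_Shelf": "Shelf",
    "": "OpenSea",
}


def collapse_cgi(relations: pd.Series, mapping: dict | None = None) -> pd.Series:
    """Collapse north/south island-relation variants to Shore/Shelf."""
    m = _CGI_COLLAPSE if mapping is None else mapping
    return relations.map(lambda r: m.get(r, r))


def _hypergeom_table(memberships: pd.DataFrame, draws_mask: np.ndarray) -> pd.DataFrame:
    """Enrichment table from a (unit, category) membership frame.

    ``memberships`` has one row per counted unit with a ``category``
    column; ``draws_mask`` marks the units belonging to the query set.
    """
    m_total = len(memberships)
    n_draws = int(draws_mask.sum())
    rows = []
    for cat, sub in memberships.groupby("category", sort=True):
        k_cat = len(sub)
        obs = int(draws_mask[sub.index].sum())
        expected = n_draws * k_cat / m_total if m_total else np.nan
        if obs == 0:
            log2_ratio = float(np.log2((obs + 0.5) / (expected + 0.5)))
        else:
            log2_ratio = float(np.log2(obs / expected))
        p_enrich = float(sps.hypergeom.sf(obs - 1, m_total, k_cat, n_draws))
        p_deplete = float(sps.hypergeom.cdf(obs, m_total, k_cat, n_draws))
        direction = "enriched" if obs > expected else ("depleted" if obs < expected else "none")
        rows.append(
            {
                "category": cat,
                "observed": obs,
                "expected": expected,
                "log2_obs_exp": log2_ratio,
                "p_enrich": p_enrich,
                "p_deplete": p_deplete,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


def location_enrichment(
    dmp_ids,
    universe,
    annot: pd.DataFrame,
    grouping: str = "cgi_relation",
) -> pd.DataFrame:
    """Observed/expected category frequencies of a probe set with
    hypergeometric tail p-values in both directions.

    ``grouping`` is ``"cgi_relation"`` (per-probe) or ``"gene_feature"``
    (per probe–feature pair; see module docs).
    """
    universe = pd.Index(universe)
    dmp_ids = pd.Index(dmp_ids)
    stray = dmp_ids.difference(universe)
    if len(stray):
        raise ValueError(f"query probes outside the universe, e.g. {list(stray)[:5]}")
    missing = universe.difference(annot.index)
    if len(missing):
        raise ValueError(f"universe probes missing annotation, e.g. {list(missing)[:5]}")
    if grouping == "cgi_relation":
        cats = collapse_cgi(annot.loc[universe, "cgi_relation"])
        memberships = pd.DataFrame({"category": cats.to_numpy()})
        mask = universe.isin(dmp_ids)
    elif grouping == "gene_feature":
        feats = annotation_feature_lists(annot.loc[universe])
        in_set = set(dmp_ids)
        records = []
        flags = []
        for probe, fl in feats.items():
            for f in sorted(set(fl)):
                records.append(f)
                flags.append(probe in in_set)
        memberships = pd.DataFrame({"category": records})
        mask = np.asarray(flags, dtype=bool)
    else:
        raise ValueError("grouping must be 'cgi_relation' or 'gene_feature'")
    out = _hypergeom_table(memberships, np.asarray(mask))
    out.attrs.update({"grouping": grouping, "n_universe": len(universe), "n_set": len(dmp_ids)})
    return out


def gene_set_enrichment(
    gene_list,
    gene_sets: dict[str, set],
    universe,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in named sets.

    Gene sets are intersected with the universe; the enrichment p-values
    are BH-adjusted across sets (column ``q_enrich``).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    genes = set(gene_list)
    stray = genes - universe
    if stray:
        raise ValueError(f"query genes outside the universe, e.g. {sorted(stray)[:5]}")
    m_total = len(universe)
    n_draws = len(genes)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        k_cat = len(members)
        obs = len(genes & members)
        expected = n_draws * k_cat / m_total
        if obs == 0:
            log2_ratio = float(np.log2((obs + 0.5) / (expected + 0.5))) if expected > 0 else np.nan
        else:
            log2_ratio = float(np.log2(obs / expected))
        rows.append(
            {
                "gene_set": name,
                "set_size": k_cat,
                "observed": obs,
                "expected": expected,
                "log2_obs_exp": log2_ratio,
                "p_enrich": float(sps.hypergeom.sf(obs - 1, m_total, k_cat, n_draws)),
                "p_deplete": float(sps.hypergeom.cdf(obs, m_total, k_cat, n_draws)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_enrich"] = bh_fdr(out["p_enrich"].to_numpy())
    out.attrs.update({"n_universe": m_total, "n_query": n_draws})
    return out
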
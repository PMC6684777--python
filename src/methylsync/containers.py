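"""In-memory containers shared by all pipeline stages.

The central object is :class:`BetaMatrix`: a probes × samples matrix of
methylation beta values (fraction methylated, in [0, 1]) together with a
sample design table assigning each sample column to a subject, a sampling
day, and a technical-replicate flag.  Probe metadata lives in a
manifest-style annotation table, phenotypes in a tidy subject × day table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "GENE_FEATURE_GROUPS",
    "CGI_RELATIONS",
    "PROBE_TYPES",
    "validate_annotation",
    "annotation_gene_lists",
]

#: Gene-model feature groups used by the HM450-style manifest; IGR marks
#: intergenic probes, which carry no gene symbols.
GENE_FEATURE_GROUPS = ("TSS200", "TSS1500", "5UTR", "1stExon", "Body", "3UTR", "IGR")

#: Position of a probe relative to the nearest CpG island.
CGI_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")

PROBE_TYPES = ("cg", "ch", "rs")

DESIGN_COLUMNS = ("subject", "day", "replicate")


@dataclass
class BetaMatrix:
    """Probes × samples beta-value matrix with its sample design.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample id.
        Entries are beta values in [0, 1]; missing values are NaN.
    design
        DataFrame indexed by sample id with columns ``subject`` (str),
        ``day`` (numeric sampling day) and ``replicate`` (bool; True marks
        the duplicate hybridization of a technical-replicate pair).
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        missing = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        undesigned = self.values.columns.difference(self.design.index)
        if len(undesigned):
            raise ValueError(f"samples without a design row: {list(undesigned)[:5]}")
        vals = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.nansum((vals < 0) | (vals > 1))
        if bad:
            raise ValueError(f"{int(bad)} beta values outside [0, 1]")
        self.design = self.design.loc[self.values.columns]
        self.design["replicate"] = self.design["replicate"].astype(bool)

    # -- accessors -----------------------------------------------------

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def subjects(self) -> list[str]:
        return sorted(self.design["subject"].unique())

    def subject_samples(self, subject: str) -> pd.DataFrame:
        """Design rows for one subject's non-replicate samples, sorted by day."""
        d = self.design
        rows = d[(d["subject"] == subject) & (~d["replicate"])]
        return rows.sort_values("day")

    def subject_series(self, subject: str) -> pd.DataFrame:
        """Probes × days matrix for one subject (replicate column excluded)."""
        rows = self.subject_samples(subject)
        out = self.values[rows.index]
        out.columns = rows["day"].to_numpy()
        return out

    def replicate_pair(self) -> tuple[str, str]:
        """The (original, duplicate) sample ids of the unique replicate pair.

        Raises ``ValueError`` unless exactly one sample is flagged as a
        replicate and its (subject, day) partner exists.
        """
        reps = self.design[self.design["replicate"]]
        if len(reps) != 1:
            raise ValueError(
                f"expected exactly one replicate sample in the design, found {len(reps)}"
            )
        rep_id = reps.index[0]
        subj, day = reps.iloc[0]["subject"], reps.iloc[0]["day"]
        partners = self.design[
            (self.design["subject"] == subj)
            & (self.design["day"] == day)
            & (~self.design["replicate"])
        ]
        if len(partners) != 1:
            raise ValueError(
                f"replicate sample {rep_id!r} has {len(partners)} (subject, day) partners"
            )
        return partners.index[0], rep_id

    def drop_replicates(self) -> "BetaMatrix":
        keep = self.design.index[~self.design["replicate"]]
        return BetaMatrix(self.values[keep].copy(), self.design.loc[keep].copy())

    def subset_probes(self, probes) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[probes].copy(), self.design.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"BetaMatrix({len(self.probes)} probes × {len(self.samples)} samples, "
            f"{len(self.subjects)} subjects)"
        )


def validate_annotation(annot: pd.DataFrame, probes: pd.Index | None = None) -> None:
    """Check a probe annotation table against the manifest conventions.

    Required columns: ``probe_type``, ``chrom``, ``genes`` (';'-joined
    symbols, empty for intergenic), ``feature_groups`` (';'-joined, parallel
    to genes, or the single value ``IGR``), ``cgi_relation``, ``snp_flag``,
    ``multimap_flag``, ``beadfail_frac``.
    """
    required = [
        "probe_type",
        "chrom",
        "genes",
        "feature_groups",
        "cgi_relation",
        "snp_flag",
        "multimap_flag",
        "beadfail_frac",
    ]
    missing = [c for c in required if c not in annot.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    if probes is not None:
        absent = probes.difference(annot.index)
        if len(absent):
            raise ValueError(
                f"{len(absent)} probes missing from annotation, e.g. {list(absent)[:5]}"
            )
    bf = annot["beadfail_frac"].to_numpy(dtype=float)
    if ((bf < 0) | (bf > 1)).any():
        raise ValueError("beadfail_frac outside [0, 1]")


def _split(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    return str(cell).split(";")


def annotation_gene_lists(annot: pd.DataFrame) -> pd.Series:
    """Per-probe list of gene symbols (empty list for intergenic probes)."""
    return annot["genes"].apply(_split)


def annotation_feature_lists(annot: pd.DataFrame) -> pd.Series:
    """Per-probe list of gene-feature groups parallel to the gene list.

    Intergenic probes yield ``["IGR"]`` so that feature-level bookkeeping
    still sees one entry per probe.
    """
    out = annot["feature_groups"].apply(_split)
    return out.where(out.str.len() > 0, other=pd.Series([["IGR"]] * len(annot), index=annot.index))
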
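"""TSV/JSON/YAML readers and writers for all pipeline tables.

All matrices and tables are plain TSV: diff-able, and at the cohort scale
this pipeline targets (a few ×10⁴–10⁵ probes, a few dozen samples) text
I/O is perfectly adequate.  Beta matrices travel as a probe × sample TSV
plus a design sidecar table; floats are written with ``repr`` precision so
a write→read round trip is bit-exact.  Missing cells are encoded as
``NA``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .containers import BetaMatrix, validate_annotation

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_annotation",
    "read_phenotypes",
    "write_phenotypes",
    "read_truth",
    "write_truth",
    "read_gmt",
    "write_json",
    "read_config",
    "write_config",
]

_NA = "NA"


def _check_unique(index: pd.Index, what: str, path) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} in {path}: {dups[:5]}")


def write_matrix(beta: BetaMatrix, path, design_path=None) -> None:
    """Write a beta matrix as TSV with its design sidecar
    (default ``<path>.design.tsv``)."""
    path = Path(path)
    design_path = Path(design_path) if design_path else path.with_suffix(".design.tsv")
    beta.values.to_csv(path, sep="\t", index_label="probe_id", na_rep=_NA)
    beta.design.to_csv(design_path, sep="\t", index_label="sample_id")


def read_matrix(path, design_path=None) -> BetaMatrix:
    """Read a beta matrix TSV and its design sidecar back into a BetaMatrix."""
    path = Path(path)
    design_path = Path(design_path) if design_path else path.with_suffix(".design.tsv")
    values = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[_NA], keep_default_na=False,
        float_precision="round_trip",
    )
    _check_unique(values.index, "probe ids", path)
    _check_unique(values.columns, "sample ids", path)
    non_numeric = values.columns[
        [values[c].dtype == object for c in values.columns]
    ]
    if len(non_numeric):
        raise ValueError(f"non-numeric beta columns in {path}: {list(non_numeric)[:5]}")
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    _check_unique(design.index, "sample ids", design_path)
    missing = values.columns.difference(design.index)
    if len(missing):
        raise ValueError(f"design table {design_path} missing samples: {list(missing)[:5]}")
    return BetaMatrix(values, design)


def write_annotation(annot: pd.DataFrame, path) -> None:
    annot.to_csv(path, sep="\t", index_label="probe_id", na_rep=_NA)


def read_annotation(path) -> pd.DataFrame:
    annot = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[_NA], keep_default_na=False,
        dtype={"genes": str, "feature_groups": str},
    )
    _check_unique(annot.index, "probe ids", path)
    annot["genes"] = annot["genes"].fillna("")
    annot["feature_groups"] = annot["feature_groups"].fillna("")
    for col in ("snp_flag", "multimap_flag"):
        if annot[col].dtype == object:
            annot[col] = annot[col].map({"True": True, "False": False}).astype(bool)
        else:
            annot[col] = annot[col].astype(bool)
    validate_annotation(annot)
    return annot


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_phenotypes(path) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False)
    for col in ("subject", "day"):
        if col not in pheno.columns:
            raise ValueError(f"phenotype table {path} missing column {col!r}")
    return pheno


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label="probe_id")


def read_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    _check_unique(truth.index, "probe ids", path)
    return truth


def read_gmt(path) -> dict[str, set]:
    """Read gene sets from GMT (name <tab> description <tab> genes...)."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, description, ≥1 gene")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate gene set {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
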
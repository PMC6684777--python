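"""Synthetic longitudinal methylome cohorts with planted signal.

Emulates the study design the pipeline is built for: a small cohort
(default 6 subjects) sampled at a handful of mission days (default 6
methylation timepoints over a ~520-day confinement), a manifest-style probe
annotation, phenotype trajectories (a 3-stage stepwise fasting-glucose rise
and a mood-disturbance curve with a mid-late-mission bump), one technical
replicate pair, and a ground-truth table recording every planted effect.

Probe baselines follow the bimodal beta-value distribution typical of
methylation arrays (a mixture of a low- and a high-methylation beta
component).  Noise is added on the beta scale and truncated to
[0.001, 0.999], which keeps the replicate-error and personal-dispersion
quantiles directly controllable.

Planted probe classes
---------------------
* ``dmp`` — a mid-mission step of size ``effect_dmp`` shared by all
  subjects (differential methylation across sampling points).  A step, not
  a ramp: the study's phenotypes move in stages, and a step of size e
  yields per-subject sd ≈ 0.548·e, comfortably detectable above the
  sd-based candidate filters.
* ``sync_<indicator>`` — beta tracks each subject's standardized phenotype
  trajectory with amplitude ``effect_sync`` and a per-probe random sign
  (both coupling directions occur in real data).
* ``null`` — baseline plus biological noise only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import BetaMatrix, GENE_FEATURE_GROUPS

__all__ = [
    "SimulationConfig",
    "calibrate_sigma_tech",
    "generate_phenotype_series",
    "generate_manifest",
    "generate_beta_matrix",
    "generate_replicate",
    "simulate_dataset",
]

#: Default methylation sampling days: one pre-mission draw and five
#: in-mission draws spread over the 520-day confinement.
DEFAULT_TIMEPOINTS = (-7.0, 60.0, 168.0, 250.0, 340.0, 418.0)

PHENO_KINDS = ("glucose", "tmd", "custom")

BETA_MIN, BETA_MAX = 0.001, 0.999


def calibrate_sigma_tech(error_quantile: float = 0.008, frac_below: float = 0.78) -> float:
    """Per-channel technical SD such that a fraction ``frac_below`` of
    replicate differences |N(0, 2σ²)| fall below ``error_quantile``.

    Closed form: σ = q / (√2 · Φ⁻¹((1 + frac_below)/2)).
    """
    if not 0 < frac_below < 1:
        raise ValueError("frac_below must be in (0, 1)")
    return float(error_quantile / (np.sqrt(2.0) * sps.norm.ppf((1 + frac_below) / 2)))


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Units: beta-scale quantities (effects, SDs) are methylation fractions;
    timepoints are mission days; glucose stages are mmol/L.
    """

    n_probes: int = 20000
    n_subjects: int = 6
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_extra_pheno_timepoints: int = 0
    frac_dmp: float = 0.01
    frac_sync: float = 0.01
    effect_dmp: float = 0.05
    effect_sync: float = 0.05
    sigma_bio: float = 0.015
    sigma_tech: float = field(default_factory=calibrate_sigma_tech)
    #: (low-mode (a, b), high-mode (a, b), weight of the low mode)
    beta_mixture: tuple = ((1.5, 8.0), (8.0, 1.5), 0.5)
    seed: int = 0
    # glucose trajectory: stage means/SDs in mmol/L; a day d belongs to
    # stage 0 if d <= boundaries[0], stage 1 if d <= boundaries[1], else 2.
    glucose_stage_means: tuple[float, float, float] = (4.5, 5.2, 6.0)
    glucose_stage_sds: tuple[float, float, float] = (0.34, 0.37, 0.37)
    glucose_stage_boundaries: tuple[float, float] = (168.0, 300.0)
    # mood-disturbance trajectory (arbitrary POMS-score units)
    tmd_baseline_mean: float = 20.0
    tmd_baseline_sd: float = 8.0
    tmd_bump_mean: float = 15.0
    tmd_bump_sd: float = 5.0
    tmd_bump_day: float = 390.0
    tmd_bump_width: float = 80.0
    tmd_noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.n_probes < 1 or self.n_subjects < 1:
            raise ValueError("n_probes and n_subjects must be positive")
        for name in ("frac_dmp", "frac_sync"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_dmp + self.frac_sync > 1:
            raise ValueError("frac_dmp + frac_sync must not exceed 1")
        if self.sigma_bio < 0 or self.sigma_tech < 0:
            raise ValueError("noise SDs must be non-negative")
        tp = np.asarray(self.timepoints, dtype=float)
        if len(tp) < 2 or not np.all(np.diff(tp) > 0):
            raise ValueError("timepoints must be ≥2 strictly increasing values")
        (a1, b1), (a2, b2), w = self.beta_mixture
        if not (a1 > 0 and b1 > 0 and a2 > 0 and b2 > 0 and 0 <= w <= 1):
            raise ValueError("invalid beta mixture parameters")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))

    @property
    def subjects(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    def pheno_days(self) -> np.ndarray:
        """Phenotype sampling days: the methylation days plus
        ``n_extra_pheno_timepoints`` extra days interleaved between them
        (phenotypes are sampled more densely than the methylome)."""
        days = list(map(float, self.timepoints))
        if self.n_extra_pheno_timepoints:
            lo, hi = min(days), max(days)
            candidates = np.linspace(lo, hi, self.n_extra_pheno_timepoints + 2)[1:-1]
            for c in candidates:
                d = float(round(c))
                while d in days:
                    d += 1.0
                days.append(d)
        return np.array(sorted(days))

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# phenotypes


def _glucose_stage_index(days: np.ndarray, boundaries) -> np.ndarray:
    return np.searchsorted(np.asarray(boundaries, dtype=float), days, side="left")


def generate_phenotype_series(kind: str, config: SimulationConfig) -> pd.DataFrame:
    """Per-subject phenotype trajectory, tidy: subject, day, <indicator>.

    Kinds: ``glucose`` — a 3-stage stepwise rise, values drawn per subject
    per day from Normal(stage mean, stage SD); ``tmd`` — per-subject
    baseline plus a Gaussian bump peaking in the latter part of the mission
    plus noise; ``custom`` — an iid standard-normal indicator (a null
    trajectory, useful for calibration runs).  Units are recorded in
    ``frame.attrs["units"]``.
    """
    if kind not in PHENO_KINDS:
        raise ValueError(f"unknown phenotype kind {kind!r}; valid kinds: {PHENO_KINDS}")
    rng = config.rng(salt=10 + PHENO_KINDS.index(kind))
    days = config.pheno_days()
    subjects = config.subjects
    rows = []
    if kind == "glucose":
        stage = _glucose_stage_index(days, config.glucose_stage_boundaries)
        means = np.asarray(config.glucose_stage_means)[stage]
        sds = np.asarray(config.glucose_stage_sds)[stage]
        for subj in subjects:
            vals = rng.normal(means, sds)
            rows.extend((subj, d, v) for d, v in zip(days, vals))
        unit = "mmol/L"
    elif kind == "tmd":
        for subj in subjects:
            base = rng.normal(config.tmd_baseline_mean, config.tmd_baseline_sd)
            bump = rng.normal(config.tmd_bump_mean, config.tmd_bump_sd)
            shape = np.exp(-0.5 * ((days - config.tmd_bump_day) / config.tmd_bump_width) ** 2)
            vals = base + bump * shape + rng.normal(0.0, config.tmd_noise_sd, size=len(days))
            rows.extend((subj, d, v) for d, v in zip(days, vals))
        unit = "POMS score"
    else:  # custom: null indicator
        for subj in subjects:
            vals = rng.standard_normal(len(days))
            rows.extend((subj, d, v) for d, v in zip(days, vals))
        unit = "a.u."
    out = pd.DataFrame(rows, columns=["subject", "day", kind])
    out.attrs["units"] = {kind: unit}
    return out


def merge_phenotypes(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Outer-merge tidy phenotype tables on (subject, day)."""
    out = tables[0]
    units = dict(out.attrs.get("units", {}))
    for t in tables[1:]:
        out = out.merge(t, on=["subject", "day"], how="outer")
        units.update(t.attrs.get("units", {}))
    out = out.sort_values(["subject", "day"]).reset_index(drop=True)
    out.attrs["units"] = units
    return out


# ---------------------------------------------------------------------------
# manifest

DEFAULT_CATEGORY_PROPS = {
    "gene_feature": {
        "TSS200": 0.07,
        "TSS1500": 0.10,
        "5UTR": 0.09,
        "1stExon": 0.04,
        "Body": 0.35,
        "3UTR": 0.04,
        "IGR": 0.31,
    },
    "cgi_relation": {"Island": 0.31, "Shore": 0.23, "Shelf": 0.10, "OpenSea": 0.36},
    "probe_type": {"cg": 0.97, "ch": 0.02, "rs": 0.01},
    "snp_frac": 0.01,
    "multimap_frac": 0.01,
    "beadfail_frac": 0.005,
}

_CHROMS = [str(c) for c in range(1, 23)] + ["X", "Y"]


def _largest_remainder_counts(n: int, props: dict[str, float]) -> dict[str, int]:
    """Deterministic apportionment of n items to categories: floor each
    share, then hand leftover items to the largest fractional remainders
    (ties broken by category order)."""
    keys = list(props)
    shares = np.array([props[k] * n for k in keys])
    base = np.floor(shares).astype(int)
    leftover = n - base.sum()
    order = np.argsort(-(shares - base), kind="stable")
    for i in range(leftover):
        base[order[i]] += 1
    return dict(zip(keys, base.tolist()))


def _check_props(props: dict[str, float], name: str) -> None:
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} proportions sum to {total}, expected 1")


def generate_manifest(
    config: SimulationConfig, category_props: dict | None = None
) -> pd.DataFrame:
    """Manifest-style probe annotation with configurable category mixes.

    Category counts follow the configured proportions exactly (largest-
    remainder rounding); assignment to probes is randomized by the config
    seed.  Intergenic (IGR) probes carry no gene symbols; other probes get
    1–3 symbols, each with its own feature group.
    """
    props = {**DEFAULT_CATEGORY_PROPS, **(category_props or {})}
    _check_props(props["gene_feature"], "gene_feature")
    _check_props(props["cgi_relation"], "cgi_relation")
    _check_props(props["probe_type"], "probe_type")
    n = config.n_probes
    rng = config.rng(salt=1)

    type_counts = _largest_remainder_counts(n, props["probe_type"])
    ptype = np.repeat(list(type_counts), list(type_counts.values()))
    rng.shuffle(ptype)
    probe_ids = np.array([f"{t}{i:08d}" for i, t in enumerate(ptype)])

    feat_counts = _largest_remainder_counts(n, props["gene_feature"])
    primary_feature = np.repeat(list(feat_counts), list(feat_counts.values()))
    rng.shuffle(primary_feature)

    cgi_counts = _largest_remainder_counts(n, props["cgi_relation"])
    cgi = np.repeat(list(cgi_counts), list(cgi_counts.values()))
    rng.shuffle(cgi)

    snp = np.zeros(n, dtype=bool)
    snp[rng.choice(n, _largest_remainder_counts(n, {"y": props["snp_frac"], "n": 1 - props["snp_frac"]})["y"], replace=False)] = True
    multimap = np.zeros(n, dtype=bool)
    multimap[rng.choice(n, _largest_remainder_counts(n, {"y": props["multimap_frac"], "n": 1 - props["multimap_frac"]})["y"], replace=False)] = True
    beadfail = np.zeros(n)
    n_bf = _largest_remainder_counts(n, {"y": props["beadfail_frac"], "n": 1 - props["beadfail_frac"]})["y"]
    bf_idx = rng.choice(n, n_bf, replace=False)
    beadfail[bf_idx] = rng.uniform(0.05, 0.5, size=n_bf)

    n_genes_pool = max(20, n // 10)
    gene_pool = np.array([f"GENE{i:05d}" for i in range(n_genes_pool)])
    non_igr_feats = [f for f in GENE_FEATURE_GROUPS if f != "IGR"]
    non_igr_props = np.array([props["gene_feature"][f] for f in non_igr_feats], dtype=float)
    non_igr_props /= non_igr_props.sum()

    genes_col = []
    feats_col = []
    extra_counts = rng.choice([1, 2, 3], size=n, p=[0.85, 0.12, 0.03])
    for i in range(n):
        if primary_feature[i] == "IGR":
            genes_col.append("")
            feats_col.append("IGR")
            continue
        k = int(extra_counts[i])
        syms = rng.choice(gene_pool, size=k, replace=False)
        feats = [primary_feature[i]] + list(
            rng.choice(non_igr_feats, size=k - 1, p=non_igr_props)
        )
        genes_col.append(";".join(syms))
        feats_col.append(";".join(feats))

    annot = pd.DataFrame(
        {
            "probe_type": ptype,
            "chrom": rng.choice(_CHROMS, size=n),
            "genes": genes_col,
            "feature_groups": feats_col,
            "cgi_relation": cgi,
            "snp_flag": snp,
            "multimap_flag": multimap,
            "beadfail_frac": beadfail,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return annot


# ---------------------------------------------------------------------------
# beta matrix


def _clean_mask(annot: pd.DataFrame, beadfail_threshold: float = 0.05) -> np.ndarray:
    return (
        (annot["probe_type"].to_numpy() == "cg")
        & (~annot["snp_flag"].to_numpy(dtype=bool))
        & (~annot["multimap_flag"].to_numpy(dtype=bool))
        & (annot["beadfail_frac"].to_numpy(dtype=float) < beadfail_threshold)
    )


def generate_beta_matrix(
    config: SimulationConfig,
    phenotypes: pd.DataFrame,
    manifest: pd.DataFrame,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Beta matrix with planted signal, plus its ground-truth table.

    Planted classes are assigned only among probes that survive the probe
    filter (clean cg probes), so the planted fractions are preserved
    end-to-end; flagged probes are always null.  Sync probes are split
    evenly across the indicator columns of ``phenotypes``; each couples to
    every subject's own standardized trajectory with a per-probe ±1 sign.

    Returns ``(beta, truth)`` where ``truth`` has columns ``class``
    (null / dmp / sync_<indicator>), ``effect`` (signed planted amplitude)
    and ``target`` (indicator name, empty otherwise).
    """
    n = config.n_probes
    if len(manifest) != n:
        raise ValueError("manifest size does not match config.n_probes")
    subjects = config.subjects
    days = np.asarray(config.timepoints, dtype=float)
    indicators = [c for c in phenotypes.columns if c not in ("subject", "day")]
    missing_subj = set(subjects) - set(phenotypes["subject"])
    if missing_subj:
        raise ValueError(f"phenotype table missing subjects: {sorted(missing_subj)}")

    # standardized per-subject phenotype at the methylation days
    z = {}  # (indicator, subject) -> length-t array
    for ind in indicators:
        for subj in subjects:
            sub = phenotypes[phenotypes["subject"] == subj].set_index("day")[ind]
            if not set(days).issubset(sub.index):
                raise ValueError(
                    f"phenotype {ind!r} for subject {subj} missing methylation days"
                )
            v = sub.loc[days].to_numpy(dtype=float)
            s = v.std(ddof=1)
            z[(ind, subj)] = (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    rng = config.rng(salt=2)
    n_dmp = int(round(config.frac_dmp * n))
    n_sync_total = int(round(config.frac_sync * n))
    clean_idx = np.flatnonzero(_clean_mask(manifest))
    if n_dmp + n_sync_total > len(clean_idx):
        raise ValueError("not enough clean probes to host the planted fractions")
    chosen = rng.choice(clean_idx, size=n_dmp + n_sync_total, replace=False)
    dmp_idx = chosen[:n_dmp]
    sync_idx = chosen[n_dmp:]

    classes = np.array(["null"] * n, dtype=object)
    effects = np.zeros(n)
    targets = np.array([""] * n, dtype=object)
    classes[dmp_idx] = "dmp"
    effects[dmp_idx] = config.effect_dmp
    # split sync probes evenly over indicators (first indicators get the
    # remainder), with a random coupling sign per probe
    per_ind = np.array_split(sync_idx, len(indicators)) if indicators else []
    sync_signs = {}
    for ind, idxs in zip(indicators, per_ind):
        classes[idxs] = f"sync_{ind}"
        targets[idxs] = ind
        signs = rng.choice([-1.0, 1.0], size=len(idxs))
        effects[idxs] = signs * config.effect_sync
        sync_signs[ind] = (idxs, signs)

    (a1, b1), (a2, b2), w_low = config.beta_mixture
    low = rng.random(n) < w_low
    baseline = np.where(low, rng.beta(a1, b1, size=n), rng.beta(a2, b2, size=n))

    t = len(days)
    step = (days > np.median(days)).astype(float)  # mid-mission step shape
    cols = {}
    design_rows = []
    for subj in subjects:
        block = np.repeat(baseline[:, None], t, axis=1)
        if config.sigma_bio > 0:
            block += rng.normal(0.0, config.sigma_bio, size=(n, t))
        block[dmp_idx] += config.effect_dmp * step[None, :]
        for ind, (idxs, signs) in sync_signs.items():
            block[idxs] += (signs * config.effect_sync)[:, None] * z[(ind, subj)][None, :]
        block = np.clip(block, BETA_MIN, BETA_MAX)
        for j, day in enumerate(days):
            sid = f"{subj}_T{j + 1:02d}"
            cols[sid] = block[:, j]
            design_rows.append((sid, subj, day, False))

    probe_ids = manifest.index
    values = pd.DataFrame(cols, index=probe_ids)
    design = pd.DataFrame(
        design_rows, columns=["sample_id", "subject", "day", "replicate"]
    ).set_index("sample_id")
    truth = pd.DataFrame(
        {"class": classes, "effect": effects, "target": targets}, index=probe_ids
    )
    truth.index.name = "probe_id"
    return BetaMatrix(values, design), truth


def generate_replicate(
    beta: BetaMatrix, sample_id: str, sigma_tech: float, seed: int = 0
) -> BetaMatrix:
    """Append a technical-replicate column for ``sample_id``.

    ``sigma_tech`` is the per-hybridization technical SD; since a replicate
    pair compares two noisy hybridizations, the duplicate column is the
    original plus N(0, 2·σ_tech²) noise, so that error(β) = |β₁ − β₂| is
    distributed |N(0, 2σ_tech²)| as the calibration closed form assumes.
    Values are truncated to [0.001, 0.999]; the design marks the pair.
    """
    if sample_id not in beta.samples:
        raise ValueError(f"unknown sample {sample_id!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    orig = beta.values[sample_id].to_numpy(dtype=float)
    rep = np.clip(
        orig + rng.normal(0.0, np.sqrt(2.0) * sigma_tech, size=orig.shape),
        BETA_MIN,
        BETA_MAX,
    )
    rep_id = f"{sample_id}_rep"
    values = beta.values.copy()
    values[rep_id] = rep
    row = beta.design.loc[sample_id]
    design = beta.design.copy()
    design.loc[rep_id] = {"subject": row["subject"], "day": row["day"], "replicate": True}
    return BetaMatrix(values, design)


# ---------------------------------------------------------------------------
# one-call cohort


@dataclass
class SyntheticCohort:
    beta: BetaMatrix
    manifest: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def simulate_dataset(
    config: SimulationConfig,
    pheno_kinds: tuple[str, ...] = ("glucose", "tmd"),
    category_props: dict | None = None,
) -> SyntheticCohort:
    """Full synthetic cohort: manifest, phenotypes, beta matrix with one
    replicate pair, and the ground-truth table."""
    manifest = generate_manifest(config, category_props)
    phenos = merge_phenotypes([generate_phenotype_series(k, config) for k in pheno_kinds])
    beta, truth = generate_beta_matrix(config, phenos, manifest)
    rep_target = beta.samples[0]
    beta = generate_replicate(beta, rep_target, config.sigma_tech, seed=config.seed)
    return SyntheticCohort(beta, manifest, phenos, truth, config)
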
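import numpy as np
import pandas as pd
import pytest

from methylsync.containers import BetaMatrix
from methylsync.synth import SimulationConfig, simulate_dataset


def make_beta(values, subjects, days, replicate_of=None, probe_ids=None):
    """Small BetaMatrix from an array (probes × samples) and parallel
    per-sample subject/day lists; ``replicate_of`` optionally names the
    sample index whose column is a technical replicate."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probe_ids = probe_ids or [f"cg{i:08d}" for i in range(n_probes)]
    sample_ids = [f"{s}_T{d}" if i != replicate_of else f"{s}_T{d}_rep"
                  for i, (s, d) in enumerate(zip(subjects, days))]
    frame = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    design = pd.DataFrame(
        {
            "subject": subjects,
            "day": days,
            "replicate": [i == replicate_of for i in range(n_samples)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return BetaMatrix(frame, design)


def clean_annotation(probe_ids, **overrides):
    """All-clean cg annotation for the given probes; columns overridable."""
    n = len(probe_ids)
    base = {
        "probe_type": ["cg"] * n,
        "chrom": ["1"] * n,
        "genes": [""] * n,
        "feature_groups": ["IGR"] * n,
        "cgi_relation": ["OpenSea"] * n,
        "snp_flag": [False] * n,
        "multimap_flag": [False] * n,
        "beadfail_frac": [0.0] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base, index=pd.Index(probe_ids, name="probe_id"))


@pytest.fixture(scope="session")
def small_cohort():
    """2,000-probe synthetic cohort with default planted fractions."""
    return simulate_dataset(SimulationConfig(n_probes=2000, seed=11))


@pytest.fixture(scope="session")
def clean_sync_cohort():
    """High-SNR sync-only cohort for recovery checks (effect/σ_bio = 10)."""
    cfg = SimulationConfig(
        n_probes=3000,
        frac_dmp=0.0,
        frac_sync=0.02,
        effect_sync=0.05,
        sigma_bio=0.005,
        seed=21,
    )
    return simulate_dataset(cfg)
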
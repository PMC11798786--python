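import numpy as np
import pandas as pd
import pytest

from mrmediate.sumstats import SUMSTAT_COLUMNS, HarmonizedSet


def make_sumstats(rows):
    """Build a summary-statistics frame from dicts with defaults filled in.

    Unless given explicitly, the p-value is derived from beta/se so the
    record passes the consistency check without warnings.
    """
    from scipy import stats

    defaults = {
        "chrom": "1",
        "pos": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.02,
        "n": 10_000,
    }
    out = []
    for i, row in enumerate(rows):
        rec = {"snp_id": f"rs{i + 1}", **defaults, **row}
        if "pvalue" not in rec:
            se = rec["se"] if rec["se"] > 0 else 1.0
            rec["pvalue"] = float(
                max(2.0 * stats.norm.sf(abs(rec["beta"] / se)), 1e-300)
            )
        out.append(rec)
    return pd.DataFrame(out)[SUMSTAT_COLUMNS]


@pytest.fixture
def sumstats_builder():
    return make_sumstats


def make_hset(gamma, big_gamma, se_gamma=0.01, se_big_gamma=0.01, **kwargs):
    return HarmonizedSet.from_arrays(
        gamma, se_gamma, big_gamma, se_big_gamma, **kwargs
    )


@pytest.fixture
def hset_builder():
    return make_hset


@pytest.fixture
def forward_study():
    """A strongly powered forward-causal simulated study."""
    from mrmediate.synthgwas import SimulationConfig, simulate_study

    cfg = SimulationConfig(
        n_snps=80,
        n_instruments=20,
        n_mediator_instruments=20,
        beta1_true=0.3,
        beta2_true=0.2,
        direct_true=0.34,
        seed=20240517,
    )
    return simulate_study(cfg)
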
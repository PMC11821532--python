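import numpy as np
import pandas as pd
import pytest

from mrscreen import InstrumentSet, LDPanel, TraitSummaryStats


def make_sumstats(
    trait_id,
    variant_ids,
    betas,
    ses,
    positions=None,
    chromosome="1",
    eafs=None,
    pvals=None,
    n=10000,
    trait_type="quantitative",
    effect_alleles=None,
    other_alleles=None,
):
    """Hand-build a small TraitSummaryStats table."""
    from scipy import stats

    k = len(variant_ids)
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    if positions is None:
        positions = (np.arange(k) + 1) * 1000
    if eafs is None:
        eafs = np.full(k, 0.3)
    if pvals is None:
        pvals = np.clip(2 * stats.norm.sf(np.abs(betas / ses)), 1e-300, 1.0)
    if effect_alleles is None:
        effect_alleles = ["A"] * k
    if other_alleles is None:
        other_alleles = ["G"] * k
    df = pd.DataFrame(
        {
            "chromosome": chromosome,
            "position": np.asarray(positions, dtype=np.int64),
            "effect_allele": effect_alleles,
            "other_allele": other_alleles,
            "beta": betas,
            "se": ses,
            "pval": pvals,
            "eaf": eafs,
            "n": n,
        },
        index=pd.Index(variant_ids, name="variant_id"),
    )
    return TraitSummaryStats(trait_id, trait_type, df, n)


def make_instruments(beta_exp, se_exp, beta_out, se_out, ids=None):
    """Hand-build an InstrumentSet from parallel arrays."""
    beta_exp = np.asarray(beta_exp, float)
    k = len(beta_exp)
    if ids is None:
        ids = [f"v{i}" for i in range(k)]
    df = pd.DataFrame(
        {
            "beta_exp": beta_exp,
            "se_exp": np.broadcast_to(np.asarray(se_exp, float), (k,)),
            "beta_out": np.asarray(beta_out, float),
            "se_out": np.broadcast_to(np.asarray(se_out, float), (k,)),
            "eaf": 0.3,
        },
        index=pd.Index(ids, name="variant_id"),
    )
    return InstrumentSet("exposure", "outcome", df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_instruments(rng):
    """A generic well-behaved 5-instrument set."""
    k = 5
    bx = rng.normal(0.1, 0.02, k)
    by = 0.5 * bx + rng.normal(0, 0.005, k)
    return make_instruments(bx, 0.005, by, 0.01)


@pytest.fixture
def identity_ld():
    def _make(ids):
        return LDPanel(list(ids), np.eye(len(ids)))

    return _make
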
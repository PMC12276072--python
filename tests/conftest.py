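import numpy as np
import pandas as pd
import pytest

from bpmr.sumstats import SummaryStats


def make_sumstats(rows, trait="SBP", unit="mmHg", n=1_000_000.0):
    """Build a SummaryStats from (chrom, pos, rsid, ea, oa, eaf, beta, se, p)
    tuples; sample size filled in uniformly."""
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "rsid", "effect_allele", "other_allele",
                 "eaf", "beta", "se", "pvalue"],
    )
    df["n"] = n
    return SummaryStats(trait, unit, df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_exposure():
    return make_sumstats([
        ("1", 1_000_000, "rs1", "A", "G", 0.30, 0.45, 0.05, 1e-19),
        ("1", 5_000_000, "rs2", "C", "T", 0.10, -0.60, 0.08, 1e-13),
        ("2", 2_000_000, "rs3", "G", "C", 0.25, 0.52, 0.06, 1e-17),
        ("3", 9_000_000, "rs4", "T", "A", 0.40, 0.38, 0.05, 1e-14),
    ])


def random_harmonized_frame(rng, J, theta=0.1, se_out_scale=0.05):
    """Random (beta_exp, se_exp, beta_out, se_out) instances for estimator
    oracle checks; betas exactly satisfy beta_out = theta*beta_exp + noise."""
    bx = rng.uniform(0.1, 1.0, J) * rng.choice([-1, 1], J)
    sx = rng.uniform(0.01, 0.05, J)
    sy = rng.uniform(0.5, 1.5, J) * se_out_scale
    by = theta * bx + rng.normal(0, sy)
    return pd.DataFrame({"beta_exp": bx, "se_exp": sx,
                         "beta_out": by, "se_out": sy})
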
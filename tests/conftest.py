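import numpy as np
import pandas as pd
import pytest

from lipidmr.gwas_io import CANONICAL_COLUMNS, SummaryDataset
from lipidmr.instruments import HARMONIZED_COLUMNS


def make_summary(
    snps, betas, ses, pvals=None, eafs=None, chroms=None, positions=None,
    ea=None, oa=None, n=8000, trait_id="trait", trait_type="quantitative",
):
    """Construct a small SummaryDataset from parallel lists."""
    J = len(snps)
    df = pd.DataFrame({
        "snp": snps,
        "chr": chroms if chroms is not None else ["1"] * J,
        "pos": positions if positions is not None else (np.arange(J) + 1) * 10_000,
        "effect_allele": ea if ea is not None else ["A"] * J,
        "other_allele": oa if oa is not None else ["G"] * J,
        "eaf": eafs if eafs is not None else [0.3] * J,
        "beta": betas,
        "se": ses,
        "pval": pvals if pvals is not None else [1e-8] * J,
        "n": [n] * J,
    })
    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    return SummaryDataset(trait_id, trait_type, df[CANONICAL_COLUMNS])


def make_harmonized(
    beta_exp, beta_out, se_exp=None, se_out=None, eaf_exp=None, eaf_out=None,
    n_exp=8000, n_out=100000, snps=None,
):
    """Construct a harmonized-instrument table from arrays."""
    x = np.asarray(beta_exp, float)
    J = len(x)
    return pd.DataFrame({
        "snp": snps if snps is not None else [f"rs{i}" for i in range(J)],
        "chr": ["1"] * J,
        "pos": (np.arange(J) + 1) * 10_000,
        "effect_allele": ["A"] * J,
        "other_allele": ["G"] * J,
        "beta_exp": x,
        "se_exp": np.asarray(se_exp, float) if se_exp is not None else np.full(J, 0.01),
        "eaf_exp": np.asarray(eaf_exp, float) if eaf_exp is not None else np.full(J, 0.3),
        "n_exp": np.full(J, n_exp, dtype=np.int64),
        "beta_out": np.asarray(beta_out, float),
        "se_out": np.asarray(se_out, float) if se_out is not None else np.full(J, 0.01),
        "eaf_out": np.asarray(eaf_out, float) if eaf_out is not None else np.full(J, 0.3),
        "n_out": np.full(J, n_out, dtype=np.int64),
        "harmonization_action": ["unchanged"] * J,
    })[HARMONIZED_COLUMNS]


@pytest.fixture
def rng():
    return np.random.default_rng(20240709)
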
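import numpy as np
import pandas as pd
import pytest

from mrchain.sumstats import GwasTable, HarmonizedInstrumentSet


def make_table(rows, trait_id="trait", trait_type="quantitative", **kw):
    """Build a GwasTable from a list of dicts with canonical column names."""
    defaults = {
        "CHR": "1", "POS": 1_000_000, "EA": "A", "OA": "G", "EAF": 0.3,
        "N": 30_000.0, "N_CASES": np.nan,
    }
    full = []
    for i, r in enumerate(rows):
        d = dict(defaults)
        d.setdefault("SNP", f"rs{i+1}")
        d.update(r)
        full.append(d)
    df = pd.DataFrame(full)[
        ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N", "N_CASES"]
    ]
    return GwasTable(trait_id=trait_id, trait_type=trait_type, df=df, **kw)


def make_hset(beta_exp, se_exp, beta_out, se_out, n_exp=30_000, n_out=700_000, **kw):
    j = len(beta_exp)
    return HarmonizedInstrumentSet(
        exposure_id=kw.pop("exposure_id", "exp"),
        outcome_id=kw.pop("outcome_id", "out"),
        snp_id=np.array([f"rs{i+1}" for i in range(j)], dtype=object),
        beta_exp=np.asarray(beta_exp, dtype=float),
        se_exp=np.asarray(se_exp, dtype=float),
        beta_out=np.asarray(beta_out, dtype=float),
        se_out=np.asarray(se_out, dtype=float),
        eaf=np.full(j, 0.3),
        n_exp=np.full(j, float(n_exp)),
        n_out=np.full(j, float(n_out)),
        **kw,
    )


@pytest.fixture
def worked_hset():
    """Three-instrument set with closed-form IVW beta 660/2900 and Q 52/29."""
    return make_hset(
        beta_exp=[0.1, 0.2, 0.15],
        se_exp=[0.01, 0.01, 0.01],
        beta_out=[0.02, 0.05, 0.03],
        se_out=[0.005, 0.005, 0.005],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
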
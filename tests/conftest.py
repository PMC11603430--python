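import numpy as np
import pandas as pd
import pytest

from mrmediation.harmonize import HARMONIZED_COLUMNS, HarmonizedSet
from mrmediation.sumstats import CANONICAL_COLUMNS, SumStatsTable


def make_harmonized(beta_exp, se_exp, beta_out, se_out,
                    exposure="X", outcome="Y") -> HarmonizedSet:
    """Build a harmonized instrument set directly from effect arrays."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    k = len(beta_exp)
    df = pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(k)],
        "effect_allele": "A", "other_allele": "G",
        "beta_exp": beta_exp,
        "se_exp": np.broadcast_to(np.asarray(se_exp, dtype=float), (k,)),
        "beta_out": np.asarray(beta_out, dtype=float),
        "se_out": np.broadcast_to(np.asarray(se_out, dtype=float), (k,)),
        "eaf_exp": 0.3, "eaf_out": 0.3, "status": "kept",
    })[HARMONIZED_COLUMNS]
    return HarmonizedSet(exposure, outcome, df)


def make_table(rows, trait_name="trait", trait_type="continuous") -> SumStatsTable:
    """Build a SumStatsTable from a list of row dicts, filling defaults."""
    defaults = {
        "chr": "1", "effect_allele": "A", "other_allele": "G",
        "eaf": 0.3, "beta": 0.1, "se": 0.02, "pval": 1e-9, "n": 10_000,
    }
    full = []
    for i, row in enumerate(rows):
        r = dict(defaults, pos=(i + 1) * 1_000_000, snp=f"rs{i + 1}")
        r.update(row)
        full.append(r)
    df = pd.DataFrame(full, columns=CANONICAL_COLUMNS)
    return SumStatsTable(trait_name, trait_type, df)


@pytest.fixture
def harmonized_20(rng=None) -> HarmonizedSet:
    """A 20-instrument harmonized set with heterogeneous ratio estimates."""
    rng = np.random.default_rng(7)
    be = rng.normal(0.05, 0.01, 20)
    se_e = np.full(20, 0.004)
    bo = 0.4 * be + rng.normal(0, 0.02, 20)
    se_o = rng.uniform(0.015, 0.03, 20)
    return make_harmonized(be, se_e, bo, se_o)
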
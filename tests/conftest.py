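import numpy as np
import pandas as pd
import pytest

from mrkit.harmonize import HarmonizedSet
from mrkit.tables import SUMSTAT_COLUMNS


def make_hset(beta_x, se_x, beta_y, se_y, eaf_x=0.3, eaf_y=0.3) -> HarmonizedSet:
    """Build a HarmonizedSet directly from effect vectors (scalars broadcast)."""
    beta_x = np.atleast_1d(np.asarray(beta_x, dtype=float))
    j = len(beta_x)

    def _vec(v):
        v = np.asarray(v, dtype=float)
        return np.full(j, v) if v.ndim == 0 else v

    data = pd.DataFrame(
        {
            "snp": [f"s{i + 1}" for i in range(j)],
            "beta_x": beta_x,
            "se_x": _vec(se_x),
            "beta_y": _vec(beta_y),
            "se_y": _vec(se_y),
            "eaf_x": _vec(eaf_x),
            "eaf_y": _vec(eaf_y),
        }
    )
    return HarmonizedSet(data=data)


def make_sumstats(rows) -> pd.DataFrame:
    """Build a summary-stat table from (snp, chr, pos, ea, oa, eaf, beta, se, pval, n) tuples."""
    return pd.DataFrame(rows, columns=SUMSTAT_COLUMNS)


@pytest.fixture
def simple_pair():
    """A 3-SNP exposure/outcome pair sharing allele coding."""
    exposure = make_sumstats(
        [
            ("rs1", 1, 1000, "A", "G", 0.30, 0.10, 0.010, 1e-20, 50_000),
            ("rs2", 2, 2000, "C", "T", 0.40, 0.08, 0.011, 1e-15, 50_000),
            ("rs3", 3, 3000, "G", "A", 0.20, 0.12, 0.012, 1e-22, 50_000),
        ]
    )
    outcome = make_sumstats(
        [
            ("rs1", 1, 1000, "A", "G", 0.30, 0.030, 0.015, 0.045, 60_000),
            ("rs2", 2, 2000, "C", "T", 0.40, 0.024, 0.016, 0.13, 60_000),
            ("rs3", 3, 3000, "G", "A", 0.20, 0.036, 0.014, 0.01, 60_000),
        ]
    )
    return exposure, outcome
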
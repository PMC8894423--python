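import numpy as np
import pandas as pd
import pytest

from mrdt.sumstats import AssociationTable, HarmonizedDataset


def make_table(rows, trait="X", sex="overall"):
    """rows: (rsid, ea, oa, beta, se[, pvalue, eaf, n]) tuples."""
    cols = ["rsid", "effect_allele", "other_allele", "beta", "se",
            "pvalue", "eaf", "n"]
    padded = [list(r) + [np.nan] * (8 - len(r)) for r in rows]
    return AssociationTable(
        trait=trait, sex=sex, df=pd.DataFrame(padded, columns=cols)
    )


def h_from_arrays(bx, sx, by, sy, bx2=None, sx2=None):
    k = len(bx)
    return HarmonizedDataset(
        rsids=tuple(f"rs{i + 1}" for i in range(k)),
        beta_exposure=np.asarray(bx, float),
        se_exposure=np.asarray(sx, float),
        beta_outcome=np.asarray(by, float),
        se_outcome=np.asarray(sy, float),
        beta_exposure2=None if bx2 is None else np.asarray(bx2, float),
        se_exposure2=None if sx2 is None else np.asarray(sx2, float),
    )


@pytest.fixture
def seeded_h():
    """Small harmonized dataset with heterogeneous SEs, k=5."""
    rng = np.random.default_rng(42)
    bx = rng.uniform(0.1, 0.3, 5)
    sx = rng.uniform(0.005, 0.02, 5)
    sy = rng.uniform(0.01, 0.04, 5)
    by = 0.5 * bx + rng.normal(0, sy)
    return h_from_arrays(bx, sx, by, sy)


@pytest.fixture(scope="session")
def paper_cfg():
    from mrdt.scenarios import paper_like_study

    config, truth = paper_like_study(11, bootstrap_iters=200)
    return config, truth
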
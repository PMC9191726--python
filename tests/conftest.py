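import numpy as np
import pandas as pd
import pytest

from sehet.config import RunConfig, SimConfig
from sehet.synthetic import simulate_atac, simulate_expression, simulate_foci


@pytest.fixture(scope="session")
def sim_expr_seed1():
    """Default-condition expression simulation, seed 1."""
    return simulate_expression(SimConfig(seed=1))


@pytest.fixture(scope="session")
def sim_atac_seed7():
    """Default-condition scATAC simulation, seed 7."""
    return simulate_atac(SimConfig(seed=7))


@pytest.fixture(scope="session")
def foci_seed3():
    """Default-condition foci table, seed 3."""
    return simulate_foci(SimConfig(seed=3))


@pytest.fixture(scope="session")
def normalized_seed1(sim_expr_seed1):
    from sehet import expression

    adata, truth = sim_expr_seed1
    cfg = SimConfig(seed=1)
    out = expression.qc_filter(adata, cfg.qc_min_total, cfg.qc_min_genes,
                               cfg.qc_max_mito)
    return expression.normalize(out), truth


def make_adata(counts, dose=None, markers=None):
    """Small AnnData with QC metadata derived from the counts."""
    import anndata as ad

    counts = np.asarray(counts)
    n, g = counts.shape
    obs = pd.DataFrame(index=pd.Index([f"c{i}" for i in range(n)],
                                      name="cell_id"))
    obs["dose"] = dose if dose is not None else 0.0
    obs["total_count"] = counts.sum(axis=1)
    obs["n_detected_genes"] = (counts > 0).sum(axis=1)
    obs["mito_ratio"] = 0.0
    var = pd.DataFrame(index=pd.Index([f"g{j}" for j in range(g)],
                                      name="gene"))
    var["is_marker"] = [j in (markers or []) for j in range(g)]
    var["is_mito"] = False
    return ad.AnnData(X=counts.astype(np.int64), obs=obs, var=var)
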
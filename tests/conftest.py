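import anndata as ad
import numpy as np
import pandas as pd
import pytest

from resistrace import lineage, preprocess as pp
from resistrace import simulate as sim


@pytest.fixture(scope="session")
def small_experiment():
    """A compact two-arm experiment with planted resistance/fitness programs."""
    cfg = sim.SimulationConfig(
        n_lineages=400,
        n_genes=500,
        heritability=0.6,
        n_resistance_genes=50,
        resistance_effect=0.5,
        n_fitness_genes=50,
        seed=7,
        mean_depth=5000,
    )
    return sim.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def normalized_pre(small_experiment):
    return pp.normalize_log(small_experiment.pre)


def make_adata(counts: np.ndarray, genes=None, cells=None) -> ad.AnnData:
    n, g = counts.shape
    adata = ad.AnnData(
        X=np.asarray(counts, dtype=np.int32),
        obs=pd.DataFrame(index=cells or [f"c{i}" for i in range(n)]),
        var=pd.DataFrame(index=genes or [f"g{j}" for j in range(g)]),
    )
    adata.layers["counts"] = np.asarray(adata.X).copy()
    return adata


def fate_groups(exp, arm):
    """Singleton-cell fate groups for one arm of a simulated experiment."""
    pre, post = exp.arms[arm]
    prn = pp.normalize_log(pre)
    cells = dict(zip(prn.obs_names, prn.obs["label"]))
    singles = lineage.singleton_cells(cells)
    fates = lineage.assign_fates(cells, set(post.obs["label"]), arm=arm)
    fates = fates[fates["cell_id"].isin(singles)]
    surviving, lost = lineage.ARM_FATES[arm]
    return (
        prn,
        fates.loc[fates["fate"] == surviving, "cell_id"].tolist(),
        fates.loc[fates["fate"] == lost, "cell_id"].tolist(),
    )
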
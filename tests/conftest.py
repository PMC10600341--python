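import numpy as np
import pandas as pd
import pytest

import anndata as ad

from germcycle.genesets import PHASES, PhaseGeneSets
from germcycle.simulate import SimDesign, simulate_counts


@pytest.fixture(scope="session")
def balanced_sim():
    """2,000 cells, balanced phases, the generator's default noise regime."""
    design = SimDesign(
        n_cells_per_group=2000,
        group_phase_proportions={"wt": (0.2, 0.2, 0.2, 0.2, 0.2)},
        seed=11,
    )
    return simulate_counts(design)


@pytest.fixture(scope="session")
def depleted_sim():
    """Control vs G1/S-depleted mutant, exact (stratified) phase counts."""
    design = SimDesign(n_cells_per_group=1000, stratified=True, seed=7)
    return simulate_counts(design)


@pytest.fixture
def tiny_genesets():
    return PhaseGeneSets({p: (f"{p}_a", f"{p}_b") for p in PHASES})


def make_adata(X, cell_ids=None, gene_ids=None, group=None):
    X = np.asarray(X)
    obs = pd.DataFrame(index=cell_ids or [f"c{i}" for i in range(X.shape[0])])
    if group is not None:
        obs["group"] = list(group)
    var = pd.DataFrame(index=gene_ids or [f"g{j}" for j in range(X.shape[1])])
    return ad.AnnData(X=X.astype(float), obs=obs, var=var)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
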
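import numpy as np
import pandas as pd
import pytest

from heatmaize import mixmod
from heatmaize.diversity import additive_kinship
from heatmaize.hsi import compute_hsi
from heatmaize.popsim import simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A scaled-down two-heat-level experiment shared across unit tests."""
    return simulate_study(
        seed=3, n_progeny=30, n_markers_dense=400, n_traits=2, n_qtl=20, n_blocks=8
    )


def hsi_pipeline(sim, traits):
    """Adjusted entry means -> HSI table and additive kinship for a study."""
    parts = []
    for t in traits:
        for cond in ("standard", "heat"):
            parts.append(mixmod.adjusted_entry_means(sim.phenotypes, cond, t))
    aem = mixmod.AEMTable(pd.concat(parts, ignore_index=True))
    pops_map = dict(
        sim.phenotypes.drop_duplicates("genotype").set_index("genotype")["population"]
    )
    tab = compute_hsi(aem, pops_map)
    imp = pd.DataFrame(
        sim.geno_dense.genotypes.astype(float),
        index=sim.geno_dense.markers,
        columns=sim.geno_dense.individuals,
    )
    ka = additive_kinship(imp)
    return tab, ka, imp


@pytest.fixture(scope="session")
def small_hsi(small_study):
    tab, ka, imp = hsi_pipeline(small_study, ["LL", "PH"])
    pops = tab.drop_duplicates("genotype").set_index("genotype")["population"]
    return tab, ka, imp, pops


def balanced_oneway(seed=0, n_g=20, r=3, s2g=4.0, s2e=1.0):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(s2g), n_g)
    y = g[:, None] + rng.normal(0, np.sqrt(s2e), (n_g, r))
    df = pd.DataFrame(
        {
            "genotype": np.repeat([f"G{i:02d}" for i in range(n_g)], r),
            "replicate": np.tile(np.arange(1, r + 1), n_g),
            "value": y.ravel(),
        }
    )
    return df, y
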
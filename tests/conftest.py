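import numpy as np
import pandas as pd
import pytest

from esstrans.datatypes import FeatureSchema, SpeciesDataset
from esstrans.simulate import PhyloTree, SimConfig, simulate_multispecies


@pytest.fixture(scope="session")
def small_corpus():
    """Five 300-gene species on a simulated tree, default drift."""
    cfg = SimConfig(n_species=5, n_genes_per_species=300, seed=11)
    datasets, divergence = simulate_multispecies(cfg)
    return datasets, divergence, cfg


@pytest.fixture(scope="session")
def toy_schema():
    return FeatureSchema(continuous=("x1", "x2"), categorical=("c1",))


def make_dataset(species_id, x, y, schema, categorical=None, species_col=None):
    """Small helper to assemble a SpeciesDataset from arrays."""
    x = np.asarray(x, dtype=float)
    idx = pd.Index([f"{species_id}_g{i}" for i in range(len(x))], name="gene_id")
    table = pd.DataFrame(x, columns=list(schema.continuous), index=idx)
    if categorical is not None:
        for name, vals in categorical.items():
            table[name] = vals
    table.insert(0, "species_id", species_col or species_id)
    return SpeciesDataset(
        species_id=species_id,
        features=table,
        labels=pd.Series(np.asarray(y, dtype=int), index=idx),
        schema=schema,
    )


def three_tip_tree(depth=4000.0, inner=2000.0):
    """Manual tree ((B,C),A): B and C equidistant from A, closer to each other."""
    parent = np.array([-1, 0, 0, 2, 2])
    time = np.array([0.0, depth, inner, depth, depth])
    return PhyloTree(parent, time, ["A", "B", "C"], np.array([1, 3, 4]))
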
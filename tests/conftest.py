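import numpy as np
import pytest

from fwbench import synthetic as syn
from fwbench.features import build_feature_table, default_features, LigandRecord


@pytest.fixture(scope="session")
def feature_defs():
    return default_features()


@pytest.fixture(scope="session")
def toy_ligands():
    return syn.gen_toy_ligands()


@pytest.fixture(scope="session")
def toy_records(toy_ligands):
    from rdkit import Chem

    return [LigandRecord(t.id, Chem.MolFromSmiles(t.smiles), "smiles")
            for t in toy_ligands]


@pytest.fixture(scope="session")
def toy_matrix(toy_records, feature_defs):
    return build_feature_table(toy_records, feature_defs)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_dataset():
    """Zero-SF-noise dataset for exact algebraic checks."""
    fm = syn.gen_feature_matrix(120, syn.default_feature_specs(), seed=7)
    truth = syn.SyntheticTruth(
        true_coefficients={"HP1": 0.6, "PIPI": 0.4, "F": 0.25},
        intercept=6.0,
        affinity_noise_sd=0.3,
        sf_slope=1.0,
        sf_offset=0.0,
        sf_biases={"HP1": -0.3},
        sf_noise_sd=0.0,
        seed=7,
    )
    pk_ref = syn.gen_affinities(fm, truth)
    pk_sf = syn.gen_sf_scores(fm, pk_ref, truth)
    return fm, truth, pk_ref, pk_sf
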
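import numpy as np
import pytest

from pnaqsar.chem import canonicalize_desalt, smiles_to_graph
from pnaqsar.synthetic import SyntheticSpec, generate_library


@pytest.fixture(scope="session")
def small_library():
    """A 120-compound 2-task library with salts, duplicates and cliffs."""
    spec = SyntheticSpec(
        n_compounds=120, targets=("T1", "T2"), noise_sd=0.25,
        cliff_fraction=0.08, salt_fraction=0.08, duplicate_fraction=0.08,
        seed=42,
    )
    records, truth = generate_library(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def clean_library():
    """A cliff-free, salt-free library for curation conservation checks."""
    spec = SyntheticSpec(n_compounds=100, targets=("T1", "T2"),
                         noise_sd=0.25, seed=7)
    records, truth = generate_library(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def fixture_graphs(small_library):
    _, _, truth = small_library
    smiles = truth.table["smiles"].tolist()
    return [smiles_to_graph(canonicalize_desalt(s)) for s in smiles[:40]]


@pytest.fixture(scope="session")
def tiny_trained_model():
    """A quickly trained 2-task model on 80 compounds, reused across tests."""
    from pnaqsar.model import PNAMultitaskRegressor

    spec = SyntheticSpec(n_compounds=80, targets=("T1", "T2"),
                         noise_sd=0.2, seed=5)
    _, truth = generate_library(spec)
    smiles = truth.table["smiles"].tolist()
    rng = np.random.default_rng(5)
    Y = truth.table[["true_T1", "true_T2"]].to_numpy() + rng.normal(0, 0.2, (len(smiles), 2))
    est = PNAMultitaskRegressor(targets=("T1", "T2"), seed=1, max_epochs=15,
                                hidden_dim=24, dnn_widths=(32,))
    est.fit(smiles, Y)
    return est, smiles, Y
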
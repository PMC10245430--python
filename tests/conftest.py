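import numpy as np
import pytest

from torconf import ModelConfig, TorsionPredictor, find_rotatable_bonds, read_molecule
from torconf.fixtures import FIXTURE_SMILES, embed_initial


def small_model_config(seed: int = 0, **overrides) -> ModelConfig:
    """Desk-scale architecture used throughout the tests."""
    base = dict(
        t_update_layers=1,
        n_encoder_layers=2,
        m_decoder_layers=2,
        n_heads=4,
        hidden=64,
        seed=seed,
    )
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture(scope="session")
def suite_graphs():
    return {name: read_molecule(smi) for name, smi in FIXTURE_SMILES.items()}


@pytest.fixture(scope="session")
def suite_embedded():
    """(graph, initial conformer, torsion specs) per flexible fixture molecule."""
    out = {}
    for name, smi in FIXTURE_SMILES.items():
        graph, conf = embed_initial(smi, seed=11)
        out[name] = (graph, conf, find_rotatable_bonds(graph))
    return out


@pytest.fixture(scope="session")
def untrained_model():
    return TorsionPredictor(small_model_config(seed=0))
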
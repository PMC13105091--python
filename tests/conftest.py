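import numpy as np
import pytest

from lorax.data_model import (
    Interaction,
    InteractionDataset,
    OdorantRecord,
    ReceptorRecord,
)
from lorax.lorax_core import EncoderConfig, FusionConfig


@pytest.fixture
def tiny_regression_dataset():
    """2 odorants x 2 receptors, full factorial, responses 1..4."""
    odorants = [OdorantRecord("o1", "CCO"), OdorantRecord("o2", "CC(=O)C")]
    receptors = [ReceptorRecord("r1", "MKTLLVAA"), ReceptorRecord("r2", "ACDEFGHIKL")]
    interactions = [
        Interaction("o1", "r1", response=1.0),
        Interaction("o1", "r2", response=2.0),
        Interaction("o2", "r1", response=3.0),
        Interaction("o2", "r2", response=4.0),
    ]
    return InteractionDataset(odorants, receptors, interactions, mode="regression")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


# small architecture used throughout the unit tests to keep forward passes cheap
TINY_ENCODER = EncoderConfig(dim=16, n_layers=1, n_heads=2, ff_dim=24, max_len=48)
TINY_FUSION = FusionConfig(model_dim=16, n_cross_attention_layers=1, n_heads=2,
                           feedforward_dim=24)


@pytest.fixture
def tiny_arch():
    return {"chem_encoder_cfg": TINY_ENCODER, "prot_encoder_cfg": TINY_ENCODER,
            "fusion": TINY_FUSION}
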
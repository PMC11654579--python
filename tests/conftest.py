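import numpy as np
import pytest

from captox.model_core import CAPTPModel, ModelConfig
from captox.sequence_io import AMINO_ACIDS, PeptideRecord


@pytest.fixture(scope="session")
def tiny_model():
    """Small randomly-initialised (untrained) model for contract tests."""
    return CAPTPModel(ModelConfig(d=8, n_heads=2, max_len=12, dropout=0.0, seed=9))


@pytest.fixture(scope="session")
def tiny_labelled_records():
    rng = np.random.default_rng(21)
    recs = []
    for i in range(12):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(5, 12)))
        recs.append(PeptideRecord(f"t{i}", seq, "toxic" if i % 3 == 0 else "non_toxic"))
    return recs
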
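import numpy as np
import pytest

from rxscreen.corpus import PrescriptionRecord, Vocabulary, encode_records
from rxscreen.model import Hyperparams, MVLDAModel


@pytest.fixture
def tiny_corpus():
    """Three prescriptions over small vocabularies, one labeled set."""
    records = [
        PrescriptionRecord("p1", ["hypertension"], ["amlodipine", "metoprolol"], label=0),
        PrescriptionRecord("p2", ["bronchitis", "pneumonia"], ["azithromycin"], label=0),
        PrescriptionRecord("p3", ["hypertension"], ["azithromycin"], label=1),
    ]
    return encode_records(records)


@pytest.fixture
def toy_model():
    """Hand-built K=3 model with block-structured topics.

    Topic 0 owns {hypertension; amlodipine, metoprolol}, topic 1 owns
    {bronchitis; azithromycin}, topic 2 owns {diabetes; metformin}.
    """
    vocab_A = Vocabulary("A", ["hypertension", "bronchitis", "diabetes"])
    vocab_B = Vocabulary("B", ["amlodipine", "metoprolol", "azithromycin", "metformin"])
    eps = 0.01
    phi_A = np.array(
        [
            [1 - 2 * eps, eps, eps],
            [eps, 1 - 2 * eps, eps],
            [eps, eps, 1 - 2 * eps],
        ]
    )
    phi_B = np.array(
        [
            [0.5 - eps, 0.5 - eps, eps, eps],
            [eps, eps, 1 - 4 * eps, 2 * eps],
            [eps, eps, 2 * eps, 1 - 4 * eps],
        ]
    )
    model = MVLDAModel(
        phi_A=phi_A,
        phi_B=phi_B,
        hyper=Hyperparams(K=3, alpha=0.5),
        vocab_A=vocab_A,
        vocab_B=vocab_B,
    )
    model.validate()
    return model
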
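"""Fold-in inference of topic proportions for held-out prescriptions.

Each view is treated as an independent topic model at inference time: the
topic-term distributions are frozen at their trained values and a short
single-document Gibbs chain estimates the view's topic proportions. Because
the two views are inferred separately, a disagreement between theta_A
(diagnoses) and theta_B (medications) is itself informative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .corpus import PrescriptionRecord
from .model import MVLDAModel

__all__ = ["ThetaEstimate", "infer_theta", "infer_record"]


@dataclass
class ThetaEstimate:
    """Per-view topic proportions for one prescription.

    A view with no usable (in-vocabulary) tokens gets the uniform vector and
    its ``uniform_*`` flag set; ``n_unseen_*`` counts skipped
    out-of-vocabulary tokens.
    """

    prescription_id: str
    theta_A: np.ndarray
    theta_B: np.ndarray
    n_unseen_A: int = 0
    n_unseen_B: int = 0
    uniform_A: bool = False
    uniform_B: bool = False


def infer_theta(
    model: MVLDAModel,
    record: PrescriptionRecord,
    view: str,
    n_sweeps: int = 200,
    burn_in: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, int, bool]:
    """Estimate one view's topic proportions by fold-in Gibbs sampling.

    Out-of-vocabulary tokens are skipped (counted, not smoothed). When the
    view has no usable tokens the uniform vector is returned with the flag
    set. Returns ``(theta, n_unseen, is_uniform_fallback)``.

    The chain samples p(z_n = k) ∝ phi[k, x_n] * (n_k^(−n) + alpha) with phi
    frozen, pooling document-topic counts over this view only, and averages
    the alpha-smoothed counts over post-burn-in sweeps.
    """
    if view == "A":
        vocab, phi, terms = model.vocab_A, model.phi_A, record.diagnoses
    elif view == "B":
        vocab, phi, terms = model.vocab_B, model.phi_B, record.medications
    else:
        raise ValueError("view must be 'A' or 'B'")
    if not (n_sweeps > burn_in >= 0):
        raise ValueError("need n_sweeps > burn_in >= 0")
    K = model.K
    ids = [vocab.get(t) for t in terms]
    tokens = np.asarray([i for i in ids if i is not None], dtype=np.int64)
    n_unseen = len(ids) - tokens.size
    if tokens.size == 0:
        return np.full(K, 1.0 / K), n_unseen, True
    theta = _kernels.fold_in_doc(
        tokens,
        np.ascontiguousarray(phi),
        model.hyper.alpha,
        int(n_sweeps),
        int(burn_in),
        int(seed) % (2**31),
    )
    return theta, n_unseen, False


def infer_record(
    model: MVLDAModel,
    record: PrescriptionRecord,
    n_sweeps: int = 200,
    burn_in: int = 100,
    seed: int = 0,
) -> ThetaEstimate:
    """Infer both views of one prescription (views are inferred separately)."""
    theta_A, unseen_A, uni_A = infer_theta(
        model, record, "A", n_sweeps, burn_in, seed
    )
    theta_B, unseen_B, uni_B = infer_theta(
        model, record, "B", n_sweeps, burn_in, (seed + 1) % (2**31)
    )
    return ThetaEstimate(
        prescription_id=record.prescription_id,
        theta_A=theta_A,
        theta_B=theta_B,
        n_unseen_A=unseen_A,
        n_unseen_B=unseen_B,
        uniform_A=uni_A,
        uniform_B=uni_B,
    )
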
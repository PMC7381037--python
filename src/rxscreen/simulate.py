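"""Synthetic prescription corpora with known ground truth.

The generator samples the model's own generative process: topic-term
distributions for diagnoses and medications drawn from symmetric Dirichlets,
a shared per-prescription topic distribution, and short documents (1-3
diagnoses, at most 5 medications, matching the source data's constraint).
Anomaly planting then emulates inappropriate prescriptions as
diagnosis-medication mismatches: a medication replaced by one drawn from the
topic least compatible with the prescription. Real inappropriate
prescriptions arise in many other ways (wrong dosage, route, duplication);
the planted labels are a synthetic construction, not a clinical gold
standard.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .corpus import EncodedCorpus, Vocabulary

__all__ = ["SyntheticSpec", "GroundTruth", "generate_corpus", "plant_anomalies"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters.

    Defaults describe an idealized coherent outpatient setting: a
    prescription is about one clinical condition, occasionally two
    (alpha_true = 0.02); 1-3 diagnoses and 1-5 medications each; and an
    anomaly prevalence of 9.8%, a realistic review-failure rate.

    ``topic_separation`` controls how exclusively each topic owns its terms.
    When set (default 0.98), each topic's Dirichlet prior is concentrated on
    its own block of ~V/K terms so that the block carries that expected
    share of the topic's mass — mirroring how real clinical topics own
    largely disjoint drug sets (antihypertensives vs. antibiotics). An
    exchangeable symmetric Dirichlet (``topic_separation=None``) leaves a
    sizable fraction of every topic's mass on terms dominated by other
    topics, so even perfectly generated prescriptions look partly
    mismatched; it remains available for studying that regime.
    """

    M: int = 5000
    K_true: int = 10
    V_A: int = 100
    V_B: int = 100
    alpha_true: float = 0.02
    beta_true_A: float = 0.1
    beta_true_B: float = 0.1
    topic_separation: float | None = 0.98
    n_A_range: tuple[int, int] = (1, 3)
    n_B_range: tuple[int, int] = (1, 5)
    anomaly_rate: float = 0.098
    anomaly_mode: str = "cross_topic_swap"  # or "random_replace"
    seed: int = 0

    def __post_init__(self):
        if min(self.M, self.K_true, self.V_A, self.V_B) < 1:
            raise ValueError("all sizes must be positive")
        if not (0 <= self.anomaly_rate <= 1):
            raise ValueError("anomaly_rate must be in [0, 1]")
        if self.anomaly_mode not in ("cross_topic_swap", "random_replace"):
            raise ValueError(f"unknown anomaly_mode {self.anomaly_mode!r}")
        for lo, hi in (self.n_A_range, self.n_B_range):
            if not (1 <= lo <= hi):
                raise ValueError("token-count ranges must satisfy 1 <= lo <= hi")
        if self.topic_separation is not None:
            n_b = min(self.V_A, self.V_B) // self.K_true
            if n_b < 1:
                raise ValueError("topic_separation needs V >= K_true in both views")
            if not (n_b / min(self.V_A, self.V_B) < self.topic_separation < 1):
                raise ValueError(
                    "topic_separation must lie strictly between the chance "
                    "block share (V/K)/V and 1"
                )


@dataclass
class GroundTruth:
    """Everything the generator knows: true parameters, per-token topics,
    and anomaly labels (all zero until planting)."""

    phi_A: np.ndarray
    phi_B: np.ndarray
    theta: np.ndarray
    z_A: np.ndarray
    z_B: np.ndarray
    labels: np.ndarray


def _sample_tokens(rng, theta_rows, lengths, phi):
    """Draw per-token topics from each document's theta and tokens from phi."""
    doc_of = np.repeat(np.arange(len(lengths)), lengths)
    u = rng.random(doc_of.size)
    z = (theta_rows[doc_of].cumsum(axis=1) > u[:, None]).argmax(axis=1)
    u2 = rng.random(doc_of.size)
    x = (phi[z].cumsum(axis=1) > u2[:, None]).argmax(axis=1)
    return z.astype(np.int32), x.astype(np.int32)


def _sample_phi(rng, K: int, V: int, beta: float, separation: float | None) -> np.ndarray:
    """Topic-term rows from a Dirichlet prior; with separation s, topic k's
    prior is boosted on its own block of V//K terms so the block's expected
    mass is s. Leftover terms (when K does not divide V) stay background."""
    if separation is None:
        return rng.dirichlet(np.full(V, beta), size=K)
    n_b = V // K
    # choose the boost so that E[own-block mass] = s
    boost = beta * (separation * V - n_b) / (n_b * (1 - separation))
    rows = np.empty((K, V))
    for k in range(K):
        conc = np.full(V, beta)
        conc[k * n_b : (k + 1) * n_b] += boost
        rows[k] = rng.dirichlet(conc)
    return rows


def generate_corpus(spec: SyntheticSpec) -> tuple[EncodedCorpus, GroundTruth]:
    """Exact sampling of the two-view generative process; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    K = spec.K_true
    phi_A = _sample_phi(rng, K, spec.V_A, spec.beta_true_A, spec.topic_separation)
    phi_B = _sample_phi(rng, K, spec.V_B, spec.beta_true_B, spec.topic_separation)
    theta = rng.dirichlet(np.full(K, spec.alpha_true), size=spec.M)
    n_A = rng.integers(spec.n_A_range[0], spec.n_A_range[1] + 1, size=spec.M)
    n_B = rng.integers(spec.n_B_range[0], spec.n_B_range[1] + 1, size=spec.M)
    z_A, x_A = _sample_tokens(rng, theta, n_A, phi_A)
    z_B, x_B = _sample_tokens(rng, theta, n_B, phi_B)
    width_A = len(str(spec.V_A - 1))
    width_B = len(str(spec.V_B - 1))
    corpus = EncodedCorpus(
        ids=[f"rx{m:06d}" for m in range(spec.M)],
        tokens_A=x_A,
        offsets_A=np.concatenate([[0], np.cumsum(n_A)]).astype(np.int64),
        tokens_B=x_B,
        offsets_B=np.concatenate([[0], np.cumsum(n_B)]).astype(np.int64),
        vocab_A=Vocabulary("A", [f"diag_{v:0{width_A}d}" for v in range(spec.V_A)]),
        vocab_B=Vocabulary("B", [f"med_{v:0{width_B}d}" for v in range(spec.V_B)]),
        labels=np.zeros(spec.M, dtype=np.int8),
    )
    truth = GroundTruth(
        phi_A=phi_A,
        phi_B=phi_B,
        theta=theta,
        z_A=z_A,
        z_B=z_B,
        labels=np.zeros(spec.M, dtype=np.int8),
    )
    return corpus, truth


def plant_anomalies(
    corpus: EncodedCorpus, truth: GroundTruth, spec: SyntheticSpec
) -> tuple[EncodedCorpus, GroundTruth]:
    """Plant round(anomaly_rate * M) mismatches; returns modified copies.

    ``cross_topic_swap`` replaces one medication (uniformly chosen) of each
    selected prescription with a medication drawn from the topic with minimal
    weight under the prescription's true theta — a drug the diagnoses do not
    explain. ``random_replace`` draws a uniform random different medication.
    Exactly one medication token changes per planted prescription.
    """
    n_anom = int(round(spec.anomaly_rate * corpus.M))
    if spec.anomaly_mode == "cross_topic_swap" and spec.K_true == 1:
        raise ValueError(
            "cross_topic_swap needs K_true >= 2; use anomaly_mode='random_replace'"
        )
    tokens_B = corpus.tokens_B.copy()
    labels = np.zeros(corpus.M, dtype=np.int8)
    z_B = truth.z_B.copy()
    if n_anom > 0:
        rng = np.random.default_rng([int(spec.seed), 0x5EED])
        n_meds = np.diff(corpus.offsets_B)
        eligible = np.flatnonzero(n_meds > 0)
        if eligible.size < n_anom:
            raise ValueError(
                f"only {eligible.size} prescriptions have a medication to swap"
            )
        chosen = rng.choice(eligible, size=n_anom, replace=False)
        for m in chosen:
            pos = corpus.offsets_B[m] + rng.integers(n_meds[m])
            old = tokens_B[pos]
            if spec.anomaly_mode == "cross_topic_swap":
                k_min = int(truth.theta[m].argmin())
                weights = truth.phi_B[k_min].copy()
                weights[old] = 0.0
                weights /= weights.sum()
                new = int(rng.choice(len(weights), p=weights))
                z_B[pos] = k_min
            else:
                # uniform over the V_B - 1 medications other than the original
                new = int(rng.integers(truth.phi_B.shape[1] - 1))
                if new >= old:
                    new += 1
            tokens_B[pos] = new
            labels[m] = 1
    new_corpus = replace(corpus, tokens_B=tokens_B, labels=labels)
    new_truth = GroundTruth(
        phi_A=truth.phi_A,
        phi_B=truth.phi_B,
        theta=truth.theta,
        z_A=truth.z_A,
        z_B=z_B,
        labels=labels,
    )
    return new_corpus, new_truth
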
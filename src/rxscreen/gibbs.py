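"""Collapsed Gibbs training of the multiview topic model.

Both views of a prescription — diagnoses (A) and medications (B) — share one
per-prescription topic distribution theta. With theta and the topic-term
distributions phi integrated out, each token's topic is resampled from

    p(z = k | rest) ∝ (n_kv + beta) / (n_k + V*beta)
                      * (n_mk + alpha) / (n_m - 1 + K*alpha)

where the first factor uses only the token's own view while the
document-topic counts n_mk pool tokens of BOTH views — this pooling is the
multiview coupling. After sampling, phi is read off the counts as
(n_kv + beta) / (n_k + V*beta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .corpus import EncodedCorpus
from .model import Hyperparams, MVLDAModel

__all__ = [
    "GibbsState",
    "CountConsistencyError",
    "gibbs_conditional",
    "gibbs_sweep",
    "estimate_phi",
    "train",
    "train_topic_grid",
    "DEFAULT_TOPIC_GRID",
]

# default grid for the topic-number sweep helper
DEFAULT_TOPIC_GRID = (15, 20, 25, 30, 35, 40, 45, 50)


class CountConsistencyError(RuntimeError):
    """A sufficient-count invariant was violated (negative or inconsistent)."""


@dataclass
class GibbsState:
    """Token-topic assignments and all sufficient counts of the sampler.

    ``ntt_*[k, v]``: times term v carries topic k (per view);
    ``nt_*[k]``: tokens of that view in topic k;
    ``ndk[m, k]``: tokens of prescription m — both views pooled — in topic k;
    ``nd[m]``: total tokens of prescription m (N_A + N_B).
    """

    corpus: EncodedCorpus
    z_A: np.ndarray
    z_B: np.ndarray
    ntt_A: np.ndarray
    nt_A: np.ndarray
    ntt_B: np.ndarray
    nt_B: np.ndarray
    ndk: np.ndarray
    nd: np.ndarray
    seed: int
    sweeps_done: int = 0

    @classmethod
    def random_init(cls, corpus: EncodedCorpus, hyper: Hyperparams, seed: int) -> "GibbsState":
        """Assign every token a uniform-random topic and build the counts."""
        K = hyper.K
        rng = np.random.default_rng(seed)
        M = corpus.M
        V_A, V_B = len(corpus.vocab_A), len(corpus.vocab_B)
        z_A = rng.integers(0, K, size=corpus.tokens_A.size).astype(np.int32)
        z_B = rng.integers(0, K, size=corpus.tokens_B.size).astype(np.int32)
        ntt_A = np.zeros((K, V_A), dtype=np.int64)
        ntt_B = np.zeros((K, V_B), dtype=np.int64)
        np.add.at(ntt_A, (z_A, corpus.tokens_A), 1)
        np.add.at(ntt_B, (z_B, corpus.tokens_B), 1)
        ndk = np.zeros((M, K), dtype=np.int64)
        doc_A = np.repeat(np.arange(M), np.diff(corpus.offsets_A))
        doc_B = np.repeat(np.arange(M), np.diff(corpus.offsets_B))
        np.add.at(ndk, (doc_A, z_A), 1)
        np.add.at(ndk, (doc_B, z_B), 1)
        nd = (np.diff(corpus.offsets_A) + np.diff(corpus.offsets_B)).astype(np.int64)
        return cls(
            corpus=corpus,
            z_A=z_A,
            z_B=z_B,
            ntt_A=ntt_A,
            nt_A=ntt_A.sum(axis=1),
            ntt_B=ntt_B,
            nt_B=ntt_B.sum(axis=1),
            ndk=ndk,
            nd=nd,
            seed=int(seed),
        )

    def check_invariants(self) -> None:
        """Verify all count identities; raise CountConsistencyError on breach."""
        if (
            (self.ntt_A < 0).any()
            or (self.ntt_B < 0).any()
            or (self.ndk < 0).any()
            or (self.nt_A < 0).any()
            or (self.nt_B < 0).any()
        ):
            raise CountConsistencyError("negative count encountered")
        if not np.array_equal(self.ntt_A.sum(axis=1), self.nt_A):
            raise CountConsistencyError("view-A topic totals inconsistent")
        if not np.array_equal(self.ntt_B.sum(axis=1), self.nt_B):
            raise CountConsistencyError("view-B topic totals inconsistent")
        if not np.array_equal(self.ndk.sum(axis=1), self.nd):
            raise CountConsistencyError("document-topic totals inconsistent")
        expected_nd = np.diff(self.corpus.offsets_A) + np.diff(self.corpus.offsets_B)
        if not np.array_equal(self.nd, expected_nd):
            raise CountConsistencyError("nd inconsistent with corpus lengths")
        if self.nt_A.sum() != self.corpus.tokens_A.size:
            raise CountConsistencyError("view-A token total inconsistent")
        if self.nt_B.sum() != self.corpus.tokens_B.size:
            raise CountConsistencyError("view-B token total inconsistent")


def _token_id(state: GibbsState, m: int, pos: int, view: str) -> int:
    c = state.corpus
    if view == "A":
        return int(c.tokens_A[c.offsets_A[m] + pos])
    return int(c.tokens_B[c.offsets_B[m] + pos])


def gibbs_conditional(
    state: GibbsState, hyper: Hyperparams, m: int, pos: int, view: str
) -> np.ndarray:
    """Collapsed conditional p(z = k | everything else) for one token.

    Precondition: the token's current assignment has already been removed
    from all counts (standard exclusion of the token being resampled).
    Returns a normalized length-K vector.
    """
    if view not in ("A", "B"):
        raise ValueError("view must be 'A' or 'B'")
    x = _token_id(state, m, pos, view)
    if view == "A":
        ntt, nt, beta, V = state.ntt_A, state.nt_A, hyper.beta_A, len(state.corpus.vocab_A)
    else:
        ntt, nt, beta, V = state.ntt_B, state.nt_B, hyper.beta_B, len(state.corpus.vocab_B)
    if (ntt[:, x] < 0).any() or (state.ndk[m] < 0).any():
        raise CountConsistencyError("negative count in conditional")
    term_factor = (ntt[:, x] + beta) / (nt + V * beta)
    doc_factor = (state.ndk[m] + hyper.alpha) / (
        state.nd[m] - 1 + hyper.K * hyper.alpha
    )
    p = term_factor * doc_factor
    return p / p.sum()


def gibbs_sweep(
    state: GibbsState,
    corpus: EncodedCorpus,
    hyper: Hyperparams,
    seed: int | None = None,
) -> GibbsState:
    """Resample every token of both views exactly once, in place."""
    if seed is None:
        seed = (state.seed + 1_000_003 * (state.sweeps_done + 1)) % (2**31)
    ll = np.empty(1, dtype=np.float64)
    empty = np.zeros((0, 0), dtype=np.float64)
    _kernels.run_gibbs(
        corpus.tokens_A,
        corpus.offsets_A,
        corpus.tokens_B,
        corpus.offsets_B,
        state.z_A,
        state.z_B,
        state.ntt_A,
        state.nt_A,
        state.ntt_B,
        state.nt_B,
        state.ndk,
        state.nd,
        hyper.alpha,
        hyper.beta_A,
        hyper.beta_B,
        1,
        int(seed) % (2**31),
        ll,
        empty,
        empty,
        -1,
    )
    state.sweeps_done += 1
    return state


def estimate_phi(state: GibbsState, hyper: Hyperparams, view: str) -> np.ndarray:
    """Beta-smoothed topic-term estimate phi[k, v] = (n_kv + beta) / (n_k + V*beta)."""
    if view == "A":
        ntt, nt, beta = state.ntt_A, state.nt_A, hyper.beta_A
    elif view == "B":
        ntt, nt, beta = state.ntt_B, state.nt_B, hyper.beta_B
    else:
        raise ValueError("view must be 'A' or 'B'")
    V = ntt.shape[1]
    return (ntt + beta) / (nt + V * beta)[:, None]


def collapsed_loglik(state: GibbsState, hyper: Hyperparams) -> float:
    """Joint log p(x, z) with theta and phi integrated out."""
    return float(
        _kernels._collapsed_loglik(
            state.ntt_A,
            state.nt_A,
            state.ntt_B,
            state.nt_B,
            state.ndk,
            state.nd,
            hyper.alpha,
            hyper.beta_A,
            hyper.beta_B,
        )
    )


def train(
    corpus: EncodedCorpus,
    hyper: Hyperparams,
    n_iter: int = 1000,
    burn_in: int = 0,
    *,
    seed: int,
    average_phi: bool = False,
) -> MVLDAModel:
    """Fit the model: random initialization, then ``n_iter`` Gibbs sweeps.

    phi is estimated from the final state by default, or averaged over
    post-burn-in sweeps when ``average_phi`` is set. The training log records
    the collapsed joint log-likelihood after every sweep. Deterministic for a
    fixed seed.
    """
    if corpus.M == 0:
        raise ValueError("cannot train on an empty corpus")
    if not (n_iter > burn_in >= 0):
        raise ValueError("need n_iter > burn_in >= 0")
    n_terms = len(corpus.vocab_A) + len(corpus.vocab_B)
    if hyper.K > n_terms:
        warnings.warn(
            f"K={hyper.K} exceeds the {n_terms} distinct terms across both views",
            stacklevel=2,
        )
    state = GibbsState.random_init(corpus, hyper, seed)
    ll = np.empty(n_iter, dtype=np.float64)
    K = hyper.K
    if average_phi:
        acc_A = np.zeros((K, len(corpus.vocab_A)), dtype=np.float64)
        acc_B = np.zeros((K, len(corpus.vocab_B)), dtype=np.float64)
        accumulate_from = burn_in
    else:
        acc_A = np.zeros((0, 0), dtype=np.float64)
        acc_B = np.zeros((0, 0), dtype=np.float64)
        accumulate_from = -1
    kernel_seed = (int(seed) + 777_767_777) % (2**31)
    n_acc = _kernels.run_gibbs(
        corpus.tokens_A,
        corpus.offsets_A,
        corpus.tokens_B,
        corpus.offsets_B,
        state.z_A,
        state.z_B,
        state.ntt_A,
        state.nt_A,
        state.ntt_B,
        state.nt_B,
        state.ndk,
        state.nd,
        hyper.alpha,
        hyper.beta_A,
        hyper.beta_B,
        n_iter,
        kernel_seed,
        ll,
        acc_A,
        acc_B,
        accumulate_from,
    )
    state.sweeps_done = n_iter
    state.check_invariants()
    if average_phi:
        phi_A = acc_A / n_acc
        phi_B = acc_B / n_acc
    else:
        phi_A = estimate_phi(state, hyper, "A")
        phi_B = estimate_phi(state, hyper, "B")
    model = MVLDAModel(
        phi_A=phi_A,
        phi_B=phi_B,
        hyper=hyper,
        vocab_A=corpus.vocab_A,
        vocab_B=corpus.vocab_B,
        training_log={
            "n_iter": n_iter,
            "burn_in": burn_in,
            "seed": int(seed),
            "average_phi": average_phi,
            "loglik": ll.tolist(),
        },
    )
    model.validate()
    return model


def train_topic_grid(
    corpus: EncodedCorpus,
    topic_numbers=DEFAULT_TOPIC_GRID,
    *,
    seed: int,
    alpha: float | None = None,
    beta_A: float = 0.01,
    beta_B: float = 0.01,
    **train_kwargs,
) -> dict[int, MVLDAModel]:
    """Fit one model per topic number (default grid 15..50 in steps of 5)."""
    return {
        K: train(
            corpus,
            Hyperparams(K=K, alpha=alpha, beta_A=beta_A, beta_B=beta_B),
            seed=seed,
            **train_kwargs,
        )
        for K in topic_numbers
    }
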
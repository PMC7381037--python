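"""Independent oracles used by the test suite.

Everything here is computed from first principles (closed forms, exhaustive
enumeration, brute-force pairwise counts) and never calls the code paths it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import gammaln

from rxscreen.corpus import EncodedCorpus
from rxscreen.gibbs import GibbsState
from rxscreen.model import Hyperparams


def build_state(corpus: EncodedCorpus, z_A, z_B, hyper: Hyperparams, seed: int = 0) -> GibbsState:
    """Build a GibbsState with given assignments, counting from scratch."""
    K = hyper.K
    z_A = np.asarray(z_A, dtype=np.int32)
    z_B = np.asarray(z_B, dtype=np.int32)
    V_A, V_B = len(corpus.vocab_A), len(corpus.vocab_B)
    M = corpus.M
    ntt_A = np.zeros((K, V_A), dtype=np.int64)
    ntt_B = np.zeros((K, V_B), dtype=np.int64)
    ndk = np.zeros((M, K), dtype=np.int64)
    for m in range(M):
        for i in range(corpus.offsets_A[m], corpus.offsets_A[m + 1]):
            ntt_A[z_A[i], corpus.tokens_A[i]] += 1
            ndk[m, z_A[i]] += 1
        for i in range(corpus.offsets_B[m], corpus.offsets_B[m + 1]):
            ntt_B[z_B[i], corpus.tokens_B[i]] += 1
            ndk[m, z_B[i]] += 1
    nd = (np.diff(corpus.offsets_A) + np.diff(corpus.offsets_B)).astype(np.int64)
    return GibbsState(
        corpus=corpus,
        z_A=z_A,
        z_B=z_B,
        ntt_A=ntt_A,
        nt_A=ntt_A.sum(axis=1),
        ntt_B=ntt_B,
        nt_B=ntt_B.sum(axis=1),
        ndk=ndk,
        nd=nd,
        seed=seed,
    )


def collapsed_logjoint(corpus: EncodedCorpus, z_A, z_B, hyper: Hyperparams) -> float:
    """log p(x, z) of the collapsed two-view model, from the
    Dirichlet-multinomial closed form (independent of the sampler code)."""
    K, alpha = hyper.K, hyper.alpha
    ll = 0.0
    for tokens, offsets, z, V, beta in (
        (corpus.tokens_A, corpus.offsets_A, np.asarray(z_A), len(corpus.vocab_A), hyper.beta_A),
        (corpus.tokens_B, corpus.offsets_B, np.asarray(z_B), len(corpus.vocab_B), hyper.beta_B),
    ):
        if V == 0:  # view absent from this corpus
            continue
        ntt = np.zeros((K, V))
        for i, v in enumerate(tokens):
            ntt[z[i], v] += 1
        for k in range(K):
            ll += gammaln(V * beta) - gammaln(ntt[k].sum() + V * beta)
            ll += (gammaln(ntt[k] + beta) - gammaln(beta)).sum()
    M = corpus.M
    for m in range(M):
        ndk = np.zeros(K)
        for i in range(corpus.offsets_A[m], corpus.offsets_A[m + 1]):
            ndk[np.asarray(z_A)[i]] += 1
        for i in range(corpus.offsets_B[m], corpus.offsets_B[m + 1]):
            ndk[np.asarray(z_B)[i]] += 1
        ll += gammaln(K * alpha) - gammaln(ndk.sum() + K * alpha)
        ll += (gammaln(ndk + alpha) - gammaln(alpha)).sum()
    return float(ll)


def enumerate_conditional(
    corpus: EncodedCorpus, z_A, z_B, hyper: Hyperparams, view: str, flat_index: int
) -> np.ndarray:
    """p(z = k | all other assignments, x) by exhaustively evaluating the
    collapsed joint at each of the K values of that token's topic."""
    z_A = np.asarray(z_A, dtype=np.int32).copy()
    z_B = np.asarray(z_B, dtype=np.int32).copy()
    logp = np.empty(hyper.K)
    for k in range(hyper.K):
        if view == "A":
            z_A[flat_index] = k
        else:
            z_B[flat_index] = k
        logp[k] = collapsed_logjoint(corpus, z_A, z_B, hyper)
    p = np.exp(logp - logp.max())
    return p / p.sum()


def enumerate_posterior_over_configs(corpus: EncodedCorpus, hyper: Hyperparams):
    """Posterior over all K^(n_tokens) joint assignment configurations."""
    n_A = corpus.tokens_A.size
    n_B = corpus.tokens_B.size
    configs = list(itertools.product(range(hyper.K), repeat=n_A + n_B))
    logp = np.array(
        [
            collapsed_logjoint(corpus, cfg[:n_A], cfg[n_A:], hyper)
            for cfg in configs
        ]
    )
    p = np.exp(logp - logp.max())
    return configs, p / p.sum()


def exact_foldin_mean(phi: np.ndarray, tokens, alpha: float) -> np.ndarray:
    """Exact posterior-mean topic proportions of a single document with phi
    frozen, by enumerating all K^N topic assignments."""
    K = phi.shape[0]
    tokens = list(tokens)
    N = len(tokens)
    theta = np.zeros(K)
    total = 0.0
    for cfg in itertools.product(range(K), repeat=N):
        counts = np.bincount(cfg, minlength=K)
        w = np.prod([phi[z, x] for z, x in zip(cfg, tokens)])
        w *= np.exp(
            gammaln(K * alpha)
            - gammaln(N + K * alpha)
            + (gammaln(counts + alpha) - gammaln(alpha)).sum()
        )
        theta += w * (counts + alpha) / (N + K * alpha)
        total += w
    return theta / total


def concordance_auroc(labels, scores) -> float:
    """Brute-force pairwise concordance with ties counted 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for s_pos in pos:
        for s_neg in neg:
            if s_pos > s_neg:
                total += 1.0
            elif s_pos == s_neg:
                total += 0.5
    return total / (len(pos) * len(neg))


def matched_mean_tv(model, truth) -> float:
    """Mean total-variation distance between true and estimated topic rows
    after maximum-weight bipartite matching on the pooled two-view rows."""
    from scipy.optimize import linear_sum_assignment

    K = truth.phi_A.shape[0]
    tv_A = np.array(
        [
            [0.5 * np.abs(model.phi_A[i] - truth.phi_A[j]).sum() for j in range(K)]
            for i in range(K)
        ]
    )
    tv_B = np.array(
        [
            [0.5 * np.abs(model.phi_B[i] - truth.phi_B[j]).sum() for j in range(K)]
            for i in range(K)
        ]
    )
    rows, cols = linear_sum_assignment((tv_A + tv_B) / 2)
    return float(((tv_A[rows, cols] + tv_B[rows, cols]) / 2).mean())
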
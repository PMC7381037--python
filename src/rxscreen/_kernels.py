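"""Numba inner loops for the collapsed Gibbs sampler and fold-in inference.

These kernels mutate count arrays in place and use numba's global RNG,
seeded explicitly at entry, so a given (state, seed) pair is reproducible.
The pure-Python conditional in :mod:`rxscreen.gibbs` is the readable
reference for the same arithmetic.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=False)
def _collapsed_loglik(ntt_A, nt_A, ntt_B, nt_B, ndk, nd, alpha, beta_A, beta_B):
    K, V_A = ntt_A.shape
    V_B = ntt_B.shape[1]
    M = ndk.shape[0]
    ll = 0.0
    for k in range(K):
        ll += math.lgamma(V_A * beta_A) - math.lgamma(nt_A[k] + V_A * beta_A)
        for v in range(V_A):
            if ntt_A[k, v] > 0:
                ll += math.lgamma(ntt_A[k, v] + beta_A) - math.lgamma(beta_A)
        ll += math.lgamma(V_B * beta_B) - math.lgamma(nt_B[k] + V_B * beta_B)
        for v in range(V_B):
            if ntt_B[k, v] > 0:
                ll += math.lgamma(ntt_B[k, v] + beta_B) - math.lgamma(beta_B)
    for m in range(M):
        ll += math.lgamma(K * alpha) - math.lgamma(nd[m] + K * alpha)
        for k in range(K):
            if ndk[m, k] > 0:
                ll += math.lgamma(ndk[m, k] + alpha) - math.lgamma(alpha)
    return ll


@njit(cache=False)
def run_gibbs(
    tokens_A,
    off_A,
    tokens_B,
    off_B,
    z_A,
    z_B,
    ntt_A,
    nt_A,
    ntt_B,
    nt_B,
    ndk,
    nd,
    alpha,
    beta_A,
    beta_B,
    n_sweeps,
    seed,
    ll_out,
    acc_A,
    acc_B,
    accumulate_from,
):
    """Run ``n_sweeps`` full sweeps over both views.

    Each token's topic is resampled from the collapsed conditional: the
    view-specific topic-term factor times the prescription-topic factor
    pooled over BOTH views. If ``accumulate_from`` >= 0, the beta-smoothed
    phi estimates are accumulated into ``acc_A``/``acc_B`` for every sweep
    index >= accumulate_from; returns the number of accumulated sweeps.
    """
    np.random.seed(seed)
    K, V_A = ntt_A.shape
    V_B = ntt_B.shape[1]
    M = off_A.shape[0] - 1
    p = np.empty(K, dtype=np.float64)
    n_acc = 0
    for s in range(n_sweeps):
        for m in range(M):
            # the doc factor's denominator (nd[m]-1+K*alpha) is constant over
            # k, so it is dropped from the unnormalized weights
            for i in range(off_A[m], off_A[m + 1]):
                v = tokens_A[i]
                k_old = z_A[i]
                ntt_A[k_old, v] -= 1
                nt_A[k_old] -= 1
                ndk[m, k_old] -= 1
                tot = 0.0
                for k in range(K):
                    p[k] = (
                        (ntt_A[k, v] + beta_A)
                        / (nt_A[k] + V_A * beta_A)
                        * (ndk[m, k] + alpha)
                    )
                    tot += p[k]
                u = np.random.random() * tot
                k_new = 0
                acc = p[0]
                while acc < u and k_new < K - 1:
                    k_new += 1
                    acc += p[k_new]
                z_A[i] = k_new
                ntt_A[k_new, v] += 1
                nt_A[k_new] += 1
                ndk[m, k_new] += 1
            for i in range(off_B[m], off_B[m + 1]):
                v = tokens_B[i]
                k_old = z_B[i]
                ntt_B[k_old, v] -= 1
                nt_B[k_old] -= 1
                ndk[m, k_old] -= 1
                tot = 0.0
                for k in range(K):
                    p[k] = (
                        (ntt_B[k, v] + beta_B)
                        / (nt_B[k] + V_B * beta_B)
                        * (ndk[m, k] + alpha)
                    )
                    tot += p[k]
                u = np.random.random() * tot
                k_new = 0
                acc = p[0]
                while acc < u and k_new < K - 1:
                    k_new += 1
                    acc += p[k_new]
                z_B[i] = k_new
                ntt_B[k_new, v] += 1
                nt_B[k_new] += 1
                ndk[m, k_new] += 1
        ll_out[s] = _collapsed_loglik(
            ntt_A, nt_A, ntt_B, nt_B, ndk, nd, alpha, beta_A, beta_B
        )
        if accumulate_from >= 0 and s >= accumulate_from:
            for k in range(K):
                denom_A = nt_A[k] + V_A * beta_A
                for v in range(V_A):
                    acc_A[k, v] += (ntt_A[k, v] + beta_A) / denom_A
                denom_B = nt_B[k] + V_B * beta_B
                for v in range(V_B):
                    acc_B[k, v] += (ntt_B[k, v] + beta_B) / denom_B
            n_acc += 1
    return n_acc


@njit(cache=False)
def fold_in_doc(tokens, phi, alpha, n_sweeps, burn_in, seed):
    """Single-document Gibbs with phi frozen, one view only.

    Returns the alpha-smoothed posterior-mean topic proportions averaged
    over post-burn-in sweeps.
    """
    np.random.seed(seed)
    K = phi.shape[0]
    N = tokens.shape[0]
    dk = np.zeros(K, dtype=np.int64)
    z = np.empty(N, dtype=np.int64)
    for n in range(N):
        z[n] = np.random.randint(0, K)
        dk[z[n]] += 1
    p = np.empty(K, dtype=np.float64)
    acc = np.zeros(K, dtype=np.float64)
    n_acc = 0
    for s in range(n_sweeps):
        for n in range(N):
            k_old = z[n]
            dk[k_old] -= 1
            tot = 0.0
            for k in range(K):
                p[k] = phi[k, tokens[n]] * (dk[k] + alpha)
                tot += p[k]
            u = np.random.random() * tot
            k_new = 0
            a = p[0]
            while a < u and k_new < K - 1:
                k_new += 1
                a += p[k_new]
            z[n] = k_new
            dk[k_new] += 1
        if s >= burn_in:
            for k in range(K):
                acc[k] += dk[k]
            n_acc += 1
    theta = np.empty(K, dtype=np.float64)
    denom = N + K * alpha
    for k in range(K):
        theta[k] = (acc[k] / n_acc + alpha) / denom
    return theta
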
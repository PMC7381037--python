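import numpy as np
import pytest
from scipy import stats as sps

from helpers import build_state, enumerate_conditional, matched_mean_tv
from rxscreen.corpus import PrescriptionRecord, encode_records
from rxscreen.gibbs import (
    CountConsistencyError,
    GibbsState,
    estimate_phi,
    gibbs_conditional,
    gibbs_sweep,
    train,
)
from rxscreen.model import Hyperparams
from rxscreen.simulate import SyntheticSpec, generate_corpus


def _random_corpus(rng, M=6, V_A=5, V_B=6, max_A=3, max_B=5):
    records = []
    for m in range(M):
        n_a = int(rng.integers(0, max_A + 1))
        n_b = int(rng.integers(0, max_B + 1))
        if n_a + n_b == 0:
            n_a = 1
        records.append(
            PrescriptionRecord(
                f"p{m}",
                [f"d{rng.integers(V_A)}" for _ in range(n_a)],
                [f"m{rng.integers(V_B)}" for _ in range(n_b)],
            )
        )
    return encode_records(records)


class TestConditional:
    def test_uniform_when_all_counts_zero(self):
        corpus = encode_records([PrescriptionRecord("p", ["d0"], [])])
        hyper = Hyperparams(K=3, alpha=0.5, beta_A=0.1)
        state = build_state(corpus, [0], [], hyper)
        # remove the single token: empty state
        state.ntt_A[0, 0] -= 1
        state.nt_A[0] -= 1
        state.ndk[0, 0] -= 1
        p = gibbs_conditional(state, hyper, 0, 0, "A")
        assert np.allclose(p, 1 / 3)

    def test_two_factor_formula_hand_example(self):
        """K=2 example checked against scalar arithmetic done independently."""
        corpus = encode_records([PrescriptionRecord("p", ["d0", "d1"], [])])
        hyper = Hyperparams(K=2, alpha=0.5, beta_A=0.1)
        state = build_state(corpus, [0, 0], [], hyper)
        # overwrite counts with the scenario (token already excluded):
        state.ntt_A = np.array([[3, 0], [0, 2]], dtype=np.int64)
        state.nt_A = np.array([3, 2], dtype=np.int64)
        state.ndk = np.array([[1, 1]], dtype=np.int64)
        state.nd = np.array([3], dtype=np.int64)  # nd - 1 = 2
        p = gibbs_conditional(state, hyper, 0, 0, "A")
        u0 = (3 + 0.1) / (3 + 2 * 0.1) * (1 + 0.5) / (2 + 2 * 0.5)
        u1 = (0 + 0.1) / (2 + 2 * 0.1) * (1 + 0.5) / (2 + 2 * 0.5)
        assert np.allclose(p, np.array([u0, u1]) / (u0 + u1), atol=1e-15)

    def test_negative_count_raises(self):
        corpus = encode_records([PrescriptionRecord("p", ["d0"], [])])
        hyper = Hyperparams(K=2, alpha=0.5)
        state = build_state(corpus, [0], [], hyper)
        state.ntt_A[0, 0] = -1
        with pytest.raises(CountConsistencyError):
            gibbs_conditional(state, hyper, 0, 0, "A")

    @pytest.mark.parametrize("seed", range(10))
    def test_sums_to_one_on_fuzzed_states(self, seed):
        rng = np.random.default_rng(seed)
        corpus = _random_corpus(rng)
        hyper = Hyperparams(
            K=int(rng.integers(2, 6)),
            alpha=float(rng.uniform(0.05, 2)),
            beta_A=float(rng.uniform(0.01, 1)),
            beta_B=float(rng.uniform(0.01, 1)),
        )
        state = GibbsState.random_init(corpus, hyper, seed)
        for _ in range(100):
            m = int(rng.integers(corpus.M))
            view = "A" if rng.random() < 0.5 else "B"
            n = len(corpus.doc_A(m) if view == "A" else corpus.doc_B(m))
            if n == 0:
                continue
            pos = int(rng.integers(n))
            p = gibbs_conditional(state, hyper, m, pos, view)
            assert p.shape == (hyper.K,)
            assert (p >= 0).all()
            assert np.isclose(p.sum(), 1.0, atol=1e-12)

    @pytest.mark.parametrize(
        "diagnoses,medications,K",
        [
            (["d0"], ["m0"], 2),
            (["d0", "d1"], [], 3),
            ([], ["m0", "m0"], 2),
            (["d0"], ["m1"], 3),
        ],
    )
    def test_matches_exhaustive_enumeration_of_collapsed_posterior(
        self, diagnoses, medications, K
    ):
        """On <=2-token corpora the sampler conditional must equal the exact
        conditional derived by enumerating the collapsed joint."""
        corpus = encode_records(
            [PrescriptionRecord("p", diagnoses, medications)],
        )
        hyper = Hyperparams(K=K, alpha=0.3, beta_A=0.2, beta_B=0.4)
        n_A, n_B = corpus.tokens_A.size, corpus.tokens_B.size
        rng = np.random.default_rng(5)
        z_A = rng.integers(0, K, n_A)
        z_B = rng.integers(0, K, n_B)
        for view, n in (("A", n_A), ("B", n_B)):
            for i in range(n):
                expected = enumerate_conditional(corpus, z_A, z_B, hyper, view, i)
                state = build_state(corpus, z_A, z_B, hyper)
                z = z_A if view == "A" else z_B
                x = corpus.tokens_A[i] if view == "A" else corpus.tokens_B[i]
                ntt = state.ntt_A if view == "A" else state.ntt_B
                nt = state.nt_A if view == "A" else state.nt_B
                ntt[z[i], x] -= 1
                nt[z[i]] -= 1
                state.ndk[0, z[i]] -= 1
                got = gibbs_conditional(state, hyper, 0, i, view)
                assert np.abs(got - expected).max() < 1e-12


class TestSweep:
    def test_single_token_corpus_conserves_counts(self):
        corpus = encode_records([PrescriptionRecord("p", ["d0"], [])])
        hyper = Hyperparams(K=2, alpha=0.5)
        state = GibbsState.random_init(corpus, hyper, 0)
        gibbs_sweep(state, corpus, hyper)
        assert state.nd.tolist() == [1]
        assert state.ndk.sum() == 1
        state.check_invariants()

    @pytest.mark.parametrize("seed", range(8))
    def test_invariants_hold_after_sweeps_on_fuzzed_corpora(self, seed):
        rng = np.random.default_rng(100 + seed)
        corpus = _random_corpus(rng, M=int(rng.integers(2, 10)))
        hyper = Hyperparams(K=int(rng.integers(2, 5)), alpha=0.5, beta_A=0.1, beta_B=0.1)
        state = GibbsState.random_init(corpus, hyper, seed)
        for _ in range(3):
            gibbs_sweep(state, corpus, hyper)
            state.check_invariants()

    def test_flat_priors_give_uniform_assignments(self):
        """With alpha, beta very large the conditional is ~uniform; empirical
        topic frequencies over repeated sweeps must pass a chi-square test."""
        corpus = encode_records(
            [PrescriptionRecord(f"p{m}", ["d0", "d1"], ["m0"]) for m in range(10)]
        )
        K = 3
        hyper = Hyperparams(K=K, alpha=1e4, beta_A=1e4, beta_B=1e4)
        state = GibbsState.random_init(corpus, hyper, 0)
        counts = np.zeros(K)
        n_sweeps = 400  # 30 tokens per sweep -> 12,000 samples
        for s in range(n_sweeps):
            gibbs_sweep(state, corpus, hyper, seed=s)
            counts += np.bincount(state.z_A, minlength=K)
        _, p_value = sps.chisquare(counts)
        assert p_value > 0.001


class TestEstimatePhi:
    def test_zero_counts_give_uniform_rows(self):
        corpus = encode_records([PrescriptionRecord("p", ["d0", "d1", "d2"], [])])
        hyper = Hyperparams(K=2, alpha=0.5, beta_A=0.3)
        state = build_state(corpus, [0, 0, 0], [], hyper)
        state.ntt_A[:] = 0
        state.nt_A[:] = 0
        phi = estimate_phi(state, hyper, "A")
        assert np.allclose(phi, 1 / 3)

    def test_direct_formula(self):
        corpus = encode_records([PrescriptionRecord("p", ["d0", "d1"], [])])
        hyper = Hyperparams(K=2, alpha=0.5, beta_A=1.0)
        state = build_state(corpus, [0, 0], [], hyper)
        state.ntt_A = np.array([[9, 1], [0, 0]], dtype=np.int64)
        state.nt_A = np.array([10, 0], dtype=np.int64)
        phi = estimate_phi(state, hyper, "A")
        assert np.allclose(phi[0], [10 / 12, 2 / 12])
        assert np.allclose(phi.sum(axis=1), 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_sum_to_one_for_fuzzed_counts(self, seed):
        rng = np.random.default_rng(seed)
        corpus = _random_corpus(rng)
        hyper = Hyperparams(K=4, alpha=0.5, beta_A=0.05, beta_B=0.05)
        state = GibbsState.random_init(corpus, hyper, seed)
        for view in "AB":
            assert np.allclose(estimate_phi(state, hyper, view).sum(axis=1), 1.0)


class TestTrain:
    def test_two_prescription_corpus_separates_topics(self):
        """Two disjoint diagnosis-medication pairs should occupy different
        topics, with each topic's mass concentrated on its pair."""
        corpus = encode_records(
            [
                PrescriptionRecord("p1", ["dA1"], ["mB1"]),
                PrescriptionRecord("p2", ["dA2"], ["mB2"]),
            ]
        )
        model = train(corpus, Hyperparams(K=2), n_iter=200, seed=0)
        k1 = int(model.phi_A[:, 0].argmax())
        k2 = int(model.phi_A[:, 1].argmax())
        assert k1 != k2
        assert model.phi_A[k1, 0] > 0.8 and model.phi_A[k2, 1] > 0.8
        assert model.phi_B[k1, 0] > 0.8 and model.phi_B[k2, 1] > 0.8

    def test_identical_seeds_give_bit_identical_phi(self):
        rng = np.random.default_rng(0)
        corpus = _random_corpus(rng, M=20)
        hyper = Hyperparams(K=3)
        m1 = train(corpus, hyper, n_iter=30, seed=42)
        m2 = train(corpus, hyper, n_iter=30, seed=42)
        assert np.array_equal(m1.phi_A, m2.phi_A)
        assert np.array_equal(m1.phi_B, m2.phi_B)

    def test_empty_corpus_rejected(self):
        corpus = encode_records([])
        with pytest.raises(ValueError):
            train(corpus, Hyperparams(K=2), n_iter=5, seed=0)

    def test_k_beyond_vocabulary_warns(self):
        corpus = encode_records([PrescriptionRecord("p", ["d0"], ["m0"])])
        with pytest.warns(UserWarning, match="distinct terms"):
            train(corpus, Hyperparams(K=5), n_iter=5, seed=0)

    def test_loglik_trace_trends_upward(self):
        """Median log-likelihood gain from sweep 1 to sweep 100 over 10 seeds
        is positive on synthetic data."""
        spec = SyntheticSpec(M=100, K_true=4, V_A=30, V_B=30, seed=9)
        corpus, _ = generate_corpus(spec)
        gains = []
        for seed in range(10):
            model = train(corpus, Hyperparams(K=4), n_iter=100, seed=seed)
            ll = model.training_log["loglik"]
            gains.append(ll[99] - ll[0])
        assert np.median(gains) > 0

    def test_recovery_improves_with_corpus_size(self):
        """Total-variation distance to the true topics shrinks as M grows."""
        tvs = {}
        for M in (200, 2000):
            spec = SyntheticSpec(M=M, K_true=5, V_A=50, V_B=50, seed=21)
            corpus, truth = generate_corpus(spec)
            model = train(corpus, Hyperparams(K=5), n_iter=300, seed=21)
            tvs[M] = matched_mean_tv(model, truth)
        assert tvs[2000] < tvs[200]

    def test_average_phi_is_row_stochastic_and_valid(self):
        rng = np.random.default_rng(3)
        corpus = _random_corpus(rng, M=30)
        model = train(
            corpus, Hyperparams(K=3), n_iter=40, burn_in=20, seed=1, average_phi=True
        )
        model.validate()
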
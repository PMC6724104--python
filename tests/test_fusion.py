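"""Structured Hinge loss, the fusion objective and the mini-batch
subgradient learner."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iokr import (
    CandidateSets,
    DeltaTable,
    FingerprintTable,
    QueryScores,
    ScoreTensor,
    build_delta_table,
    fuse_scores,
    hamming_delta,
    hinge_loss,
    objective,
    train_sgd,
)


def toy_tensor(rng, n_queries=5, n_c=4, K=3):
    queries, deltas = {}, {}
    for i in range(n_queries):
        q = f"q{i}"
        S = rng.normal(size=(n_c, K))
        d = rng.uniform(0.1, 1.0, size=n_c)
        d[0] = 0.0
        queries[q] = QueryScores([f"c{j}" for j in range(n_c)], S, 0)
        deltas[q] = d
    names = [f"model{k}" for k in range(K)]
    return ScoreTensor(names, queries), DeltaTable(deltas)


class TestHammingDelta:
    def test_identical_is_zero(self):
        assert hamming_delta(np.array([1, 0, 1]), np.array([1, 0, 1])) == 0.0

    def test_complementary_is_one(self):
        assert hamming_delta(np.array([1, 0]), np.array([0, 1])) == 1.0

    def test_half_differing(self):
        assert hamming_delta(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0])) == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hamming_delta(np.array([1, 0]), np.array([1, 0, 1]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=20),
           st.lists(st.integers(0, 1), min_size=1, max_size=20))
    def test_symmetric_and_bounded(self, a, b):
        n = min(len(a), len(b))
        va, vb = np.array(a[:n]), np.array(b[:n])
        d = hamming_delta(va, vb)
        assert 0.0 <= d <= 1.0
        assert d == hamming_delta(vb, va)


class TestDeltaTable:
    def _cands(self):
        fps = FingerprintTable(
            ["t", "a", "b"], 4,
            {"t": np.array([1, 1, 0, 0], dtype=np.uint8),
             "a": np.array([1, 0, 1, 0], dtype=np.uint8),
             "b": np.array([0, 0, 1, 1], dtype=np.uint8)},
        )
        cands = CandidateSets({"q": ["t", "a", "b"]}, {"q": "t"})
        return cands, fps

    def test_matches_elementwise_oracle(self):
        cands, fps = self._cands()
        table = build_delta_table(cands, fps)
        expected = [hamming_delta(fps.bits["t"], fps.bits[c]) for c in ["t", "a", "b"]]
        np.testing.assert_allclose(table.deltas["q"], expected)
        assert table.deltas["q"][0] == 0.0

    def test_missing_fingerprint_names_id(self):
        cands, fps = self._cands()
        cands.candidates["q"].append("ghost")
        with pytest.raises(ValueError, match="ghost"):
            build_delta_table(cands, fps)


class TestHingeLoss:
    def test_zero_weights_give_max_delta(self):
        S = np.zeros((3, 2))
        delta = np.array([0.0, 0.4, 0.9])
        loss, j = hinge_loss(np.zeros(2), S, delta, 0)
        assert loss == 0.9 and j == 2

    def test_single_true_candidate_gives_zero(self):
        loss, j = hinge_loss(np.array([1.0]), np.array([[0.7]]), np.array([0.0]), 0)
        assert loss == 0.0 and j == 0

    def test_matches_brute_force_max(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            S = rng.normal(size=(5, 1))
            delta = rng.uniform(0, 1, 5)
            delta[2] = 0.0
            w = rng.normal(size=1)
            loss, j = hinge_loss(w, S, delta, 2)
            v = S @ w
            margins = delta - (v[2] - v)
            assert loss == pytest.approx(margins.max(), abs=1e-12)
            assert j == int(np.argmax(margins))

    def test_nonnegative_because_truth_included(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            S = rng.normal(size=(6, 3))
            delta = rng.uniform(0, 1, 6)
            delta[0] = 0.0
            loss, _ = hinge_loss(rng.normal(size=3), S, delta, 0)
            assert loss >= 0.0


class TestObjective:
    def test_zero_weights_value(self):
        rng = np.random.default_rng(9)
        tensor, deltas = toy_tensor(rng)
        expected = np.mean([d.max() for d in deltas.deltas.values()])
        assert objective(np.zeros(3), tensor, deltas, 1.0) == pytest.approx(expected)

    def test_all_zero_deltas_and_weights(self):
        rng = np.random.default_rng(10)
        tensor, deltas = toy_tensor(rng)
        for q in deltas.deltas:
            deltas.deltas[q] = np.zeros_like(deltas.deltas[q])
        assert objective(np.zeros(3), tensor, deltas, 1.0) == 0.0

    def test_direct_summation_oracle(self):
        rng = np.random.default_rng(11)
        tensor, deltas = toy_tensor(rng, n_queries=5)
        w = rng.normal(size=3)
        lam = 0.3
        direct = 0.5 * lam * w @ w + np.mean(
            [hinge_loss(w, tensor.queries[q].scores, deltas.deltas[q],
                        tensor.queries[q].true_idx)[0] for q in tensor.query_ids]
        )
        assert objective(w, tensor, deltas, lam) == pytest.approx(direct, abs=1e-12)

    def test_convexity_spot_check(self):
        rng = np.random.default_rng(12)
        tensor, deltas = toy_tensor(rng, n_queries=8)
        for _ in range(20):
            w1, w2 = rng.normal(size=3), rng.normal(size=3)
            t = rng.uniform()
            lhs = objective(t * w1 + (1 - t) * w2, tensor, deltas, 0.5)
            rhs = t * objective(w1, tensor, deltas, 0.5) + (1 - t) * objective(
                w2, tensor, deltas, 0.5)
            assert lhs <= rhs + 1e-10


class TestTrainSGD:
    def test_bit_identical_under_same_seed(self):
        rng = np.random.default_rng(13)
        tensor, deltas = toy_tensor(rng, n_queries=10)
        m1 = train_sgd(tensor, deltas, 0.1, m=3, epochs=10, seed=7)
        m2 = train_sgd(tensor, deltas, 0.1, m=3, epochs=10, seed=7)
        assert np.array_equal(m1.w, m2.w)
        assert m1.training_objective_trace == m2.training_objective_trace

    def test_objective_never_ends_above_start(self):
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            tensor, deltas = toy_tensor(rng, n_queries=12)
            model = train_sgd(tensor, deltas, 0.5, m=4, epochs=30, seed=seed)
            j0 = objective(np.zeros(3), tensor, deltas, 0.5)
            assert model.training_objective_trace[-1] <= j0 + 1e-12

    def test_loss_free_problem_keeps_weights_at_zero(self):
        # single query, single (true) candidate: hinge identically 0, only the
        # regularization pull acts on w = 0, which it fixes
        tensor = ScoreTensor(["m"], {"q": QueryScores(["c"], np.array([[0.3]]), 0)})
        deltas = DeltaTable({"q": np.array([0.0])})
        model = train_sgd(tensor, deltas, 0.5, m=1, epochs=30, seed=0)
        assert np.linalg.norm(model.w) <= 1e-8

    def test_informative_model_outweighs_noise(self):
        """K=2: scores of model 1 single out the truth with a clean margin;
        model 2 is i.i.d. noise. The learned weights must prefer model 1 in
        every run."""
        n_q, n_c = 20, 6
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            queries, dd = {}, {}
            for i in range(n_q):
                informative = np.zeros(n_c)
                informative[0] = 1.0
                noise = rng.normal(size=n_c)
                d = rng.uniform(0.2, 0.8, n_c)
                d[0] = 0.0
                queries[f"q{i}"] = QueryScores(
                    [f"c{j}" for j in range(n_c)],
                    np.column_stack([informative, noise]), 0)
                dd[f"q{i}"] = d
            model = train_sgd(ScoreTensor(["inf", "noise"], queries),
                              DeltaTable(dd), 0.1, m=5, epochs=30, seed=seed)
            assert model.w[0] > model.w[1]

    def test_invalid_hyperparameters_rejected(self):
        rng = np.random.default_rng(14)
        tensor, deltas = toy_tensor(rng)
        with pytest.raises(ValueError):
            train_sgd(tensor, deltas, 0.0, m=2, epochs=1, seed=0)
        with pytest.raises(ValueError):
            train_sgd(tensor, deltas, 0.1, m=0, epochs=1, seed=0)


class TestFuseScores:
    def test_unit_weight_projects_single_model(self):
        rng = np.random.default_rng(15)
        tensor, deltas = toy_tensor(rng, K=3)
        model = train_sgd(tensor, deltas, 0.1, m=2, epochs=1, seed=0)
        model.w = np.array([0.0, 1.0, 0.0])
        fused = fuse_scores(model, tensor)
        for q, qs in tensor.queries.items():
            np.testing.assert_allclose(fused[q], qs.scores[:, 1])

    def test_zero_weights_zero_scores(self):
        rng = np.random.default_rng(16)
        tensor, deltas = toy_tensor(rng)
        model = train_sgd(tensor, deltas, 0.1, m=2, epochs=1, seed=0)
        model.w = np.zeros(3)
        assert all(np.all(v == 0) for v in fuse_scores(model, tensor).values())

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(17)
        tensor, deltas = toy_tensor(rng, n_c=4, K=3)
        model = train_sgd(tensor, deltas, 0.1, m=2, epochs=1, seed=0)
        model.w = rng.normal(size=3)
        fused = fuse_scores(model, tensor)
        for q, qs in tensor.queries.items():
            expected = [qs.scores[j] @ model.w for j in range(4)]
            np.testing.assert_allclose(fused[q], expected, atol=1e-12)
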
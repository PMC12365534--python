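"""MIL network: per-instance maps, attention pooling, invariances."""

import unittest.mock as mock

import numpy as np
import pytest

from gastromil.errors import ContractViolationError, FormatError, InvalidInputError
from gastromil.features import FeatureBag
from gastromil.model import (
    AttentionMap,
    GradingScheme,
    MILModel,
    ModelConfig,
    _backward,
    _forward_cache,
    attention_scores,
    classify,
    embed,
    init_params,
    pool,
    softmax,
)


class TestGradingScheme:
    def test_ternary_and_quaternary(self):
        assert GradingScheme.for_task(1).n_classes == 3
        assert GradingScheme.for_task(2).n_classes == 3
        assert GradingScheme.for_task(3).n_classes == 4
        assert GradingScheme.for_task(4).n_classes == 4

    def test_wrong_class_count_rejected(self):
        with pytest.raises(InvalidInputError):
            GradingScheme(1, ("a", "b", "c", "d"))


class TestEmbed:
    def test_per_instance_map(self, small_model, rng):
        X = rng.standard_normal((6, 32)).astype(np.float32)
        H = embed(X, small_model.params, small_model.config)
        perm = rng.permutation(6)
        H_perm = embed(X[perm], small_model.params, small_model.config)
        assert np.array_equal(H[perm], H_perm)

    def test_identical_rows_identical_outputs(self, small_model):
        X = np.ones((4, 32), np.float32)
        H = embed(X, small_model.params, small_model.config)
        assert np.allclose(H, H[0])

    def test_single_instance(self, small_model, rng):
        H = embed(rng.standard_normal((1, 32)), small_model.params, small_model.config)
        assert H.shape == (1, 24)

    def test_dim_mismatch(self, small_model, rng):
        with pytest.raises(ContractViolationError):
            embed(rng.standard_normal((4, 16)), small_model.params, small_model.config)


class TestAttention:
    def test_single_instance_weight_one(self, small_model, rng):
        H = rng.standard_normal((1, 24)).astype(np.float32)
        attn = attention_scores(H, small_model.params, small_model.config)
        assert attn.weights == pytest.approx([1.0])

    def test_identical_instances_uniform(self, small_model):
        H = np.tile(np.linspace(-1, 1, 24, dtype=np.float32), (5, 1))
        attn = attention_scores(H, small_model.params, small_model.config)
        assert attn.weights == pytest.approx(np.full(5, 0.2), abs=1e-9)

    def test_normalization(self, small_model, rng):
        for _ in range(20):
            H = rng.standard_normal((int(rng.integers(2, 40)), 24)).astype(np.float32)
            attn = attention_scores(H, small_model.params, small_model.config)
            assert attn.weights.sum() == pytest.approx(1.0, abs=1e-6)
            assert (attn.weights >= 0).all()


class TestPool:
    def test_uniform_attention_is_mean(self, rng):
        H = rng.standard_normal((8, 16)).astype(np.float32)
        attn = AttentionMap("s", np.full(8, 1 / 8), np.zeros(8), np.zeros((8, 2)))
        assert pool(H, attn) == pytest.approx(H.mean(axis=0), abs=1e-6)

    def test_one_hot_attention_selects_row(self, rng):
        H = rng.standard_normal((5, 16)).astype(np.float32)
        w = np.zeros(5)
        w[3] = 1.0
        attn = AttentionMap("s", w, np.zeros(5), np.zeros((5, 2)))
        assert pool(H, attn) == pytest.approx(H[3], abs=1e-7)

    def test_duplication_invariance(self, small_model, rng):
        """Duplicating every instance halves the weights but preserves z."""
        H = rng.standard_normal((7, 24)).astype(np.float32)
        attn = attention_scores(H, small_model.params, small_model.config)
        z = pool(H, attn)
        H2 = np.vstack([H, H])
        attn2 = attention_scores(H2, small_model.params, small_model.config)
        z2 = pool(H2, attn2)
        # direct recomputation oracle
        z_oracle = attn2.weights.astype(np.float32) @ H2
        assert z2 == pytest.approx(z, abs=1e-5)
        assert z2 == pytest.approx(z_oracle, abs=1e-7)

    def test_length_mismatch(self, rng):
        H = rng.standard_normal((4, 16)).astype(np.float32)
        attn = AttentionMap("s", np.full(3, 1 / 3), np.zeros(3), np.zeros((3, 2)))
        with pytest.raises(ContractViolationError):
            pool(H, attn)


class TestClassify:
    @pytest.mark.parametrize("task,k", [(1, 3), (3, 4)])
    def test_probability_vector_length(self, task, k, rng):
        cfg = ModelConfig(input_dim=32, embed_dim=24, attn_dim=12, hidden_dim=8,
                          n_classes=k, seed=1)
        params = init_params(cfg)
        pred = classify(rng.standard_normal(24).astype(np.float32), params, cfg, task_id=task)
        assert len(pred.probabilities) == k
        assert pred.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_tie_breaks_to_lowest_rank(self, small_model):
        params = {k: np.zeros_like(v) for k, v in small_model.params.items()}
        pred = classify(np.zeros(24, np.float32), params, small_model.config)
        assert pred.probabilities == pytest.approx(np.full(4, 0.25))
        assert pred.predicted_rank == 0


class TestForward:
    def test_permutation_invariance(self, small_model, make_bag, rng):
        bag = make_bag(m=20, d=32)
        pred, attn = small_model.forward(bag)
        for _ in range(100):
            perm = rng.permutation(20)
            shuffled = FeatureBag(bag.slide_id, bag.features[perm], bag.coords[perm])
            pred_s, attn_s = small_model.forward(shuffled)
            assert np.abs(pred_s.probabilities - pred.probabilities).max() <= 1e-6
            assert attn_s.weights == pytest.approx(attn.weights[perm], abs=1e-9)

    def test_identical_instances_match_single_instance_oracle(self, small_model):
        row = np.linspace(-0.5, 0.5, 32, dtype=np.float32)
        bag5 = FeatureBag("five", np.tile(row, (5, 1)), np.zeros((5, 2), int))
        bag1 = FeatureBag("one", row[None, :], np.zeros((1, 2), int))
        p5, a5 = small_model.forward(bag5)
        p1, _ = small_model.forward(bag1)
        assert a5.weights == pytest.approx(np.full(5, 0.2), abs=1e-9)
        assert p5.probabilities == pytest.approx(p1.probabilities, abs=1e-6)

    def test_repeat_runs_bit_identical(self, small_model, make_bag):
        bag = make_bag()
        p1, a1 = small_model.forward(bag)
        p2, a2 = small_model.forward(bag)
        assert np.array_equal(p1.probabilities, p2.probabilities)
        assert np.array_equal(a1.weights, a2.weights)


class TestGradients:
    def test_backprop_matches_numerical_gradients(self):
        """Analytic gradients agree with central differences (float64 run)."""
        cfg = ModelConfig(input_dim=10, embed_dim=7, attn_dim=5, hidden_dim=4,
                          n_classes=3, dropout=0.0, seed=3)
        params = {k: v.astype(np.float64) for k, v in init_params(cfg).items()}
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5, 10))
        y = 1
        with mock.patch.object(np, "float32", np.float64):
            def loss(p):
                logits, _ = _forward_cache(X, p, cfg)
                return -np.log(softmax(logits)[y])

            logits, cache = _forward_cache(X, params, cfg)
            dl = softmax(logits).copy()
            dl[y] -= 1
            grads = _backward(dl, cache, params, cfg)
            eps = 1e-6
            for name in ("W1", "Wv", "Wu", "wa", "W2", "W3", "b1", "b3"):
                g_num = np.zeros_like(params[name])
                it = np.nditer(params[name], flags=["multi_index"])
                for _ in it:
                    i = it.multi_index
                    p2 = {k: v.copy() for k, v in params.items()}
                    p2[name][i] += eps
                    up = loss(p2)
                    p2[name][i] -= 2 * eps
                    down = loss(p2)
                    g_num[i] = (up - down) / (2 * eps)
                scale = max(np.abs(g_num).max(), np.abs(grads[name]).max(), 1e-8)
                assert np.abs(g_num - grads[name]).max() / scale < 1e-6, name


class TestCheckpoint:
    def test_save_load_round_trip(self, small_model, make_bag, tmp_path):
        path = tmp_path / "model.npz"
        small_model.save(path)
        loaded = MILModel.load(path)
        bag = make_bag()
        p1, _ = small_model.forward(bag)
        p2, _ = loaded.forward(bag)
        assert np.array_equal(p1.probabilities, p2.probabilities)
        assert loaded.config == small_model.config

    def test_garbage_file_is_format_error(self, tmp_path):
        path = tmp_path / "bad.npz"
        path.write_bytes(b"not a checkpoint")
        with pytest.raises(FormatError):
            MILModel.load(path)
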
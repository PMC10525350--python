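import numpy as np
import pytest

from epimci.autograd import Tensor
from epimci.genome_io import ValidationError
from epimci.hypergraph import Hyperedge, HyperedgeSet, build_hypergraph, propagation_matrix
from epimci.model import (
    ModelConfig,
    TupleBatch,
    attention_embed,
    attention_weights,
    batch_from_samples,
    classify,
    forward,
    hconv,
    init_params,
    kl_align,
    load_checkpoint,
    make_batch,
    mlp_embed,
    save_checkpoint,
    score_tuples,
    total_loss,
)
from epimci.sampling import LabeledSample
from tests.conftest import random_hypergraph

LN2 = np.log(2.0)


def tiny_config(**overrides):
    defaults = dict(
        feature_dim=3, embed_dim=4, n_heads=2, hconv_layers=2, dropout=0.0
    )
    defaults.update(overrides)
    return ModelConfig(**defaults)


def tiny_batch(rng, config, b=3, n_bins=8):
    embeddings = rng.normal(size=(n_bins, config.feature_dim))
    tuples, labels = [], []
    for _ in range(b):
        order = int(rng.integers(3, 7))
        tuples.append(tuple(sorted(rng.choice(n_bins, size=order, replace=False).tolist())))
        labels.append(int(rng.integers(2)))
    return make_batch(tuples, embeddings, 6, labels), embeddings


class TestAttention:
    def test_rows_sum_to_one_over_allowed(self, rng):
        config = tiny_config()
        params = init_params(config, seed=1)
        batch, _ = tiny_batch(rng, config)
        alpha = attention_weights(batch, params, head=0)
        for b in range(alpha.shape[0]):
            for i in range(int(batch.mask[b].sum())):
                row = alpha[b, i]
                allowed = batch.mask[b].copy()
                allowed[i] = 0.0
                np.testing.assert_allclose(row.sum(), 1.0, atol=1e-12)
                assert np.all(row[allowed == 0.0] == 0.0)

    def test_output_in_tanh_range(self, rng):
        config = tiny_config()
        params = init_params(config, seed=2)
        batch, _ = tiny_batch(rng, config)
        e_dep = attention_embed(batch, params).data
        assert np.all(e_dep > -1.0) and np.all(e_dep < 1.0)

    def test_hand_computation_2d(self, rng):
        # independent oracle: explicit loops over the attention equations
        config = ModelConfig(feature_dim=2, embed_dim=2, n_heads=1, dropout=0.0)
        params = init_params(config, seed=3)
        x = rng.normal(size=(3, 2))
        batch = make_batch([(0, 1, 2)], np.vstack([x, np.zeros((1, 2))]), 3)
        wq = params["attn_q0"].data
        wk = params["attn_k0"].data
        wv = params["attn_v0"].data
        wo = params["attn_out"].data
        expected = np.zeros((3, 2))
        for i in range(3):
            scores = {}
            for j in range(3):
                if j == i:
                    continue
                scores[j] = float((wq.T @ x[i]) @ (wk.T @ x[j]))
            weights = np.exp(np.array(list(scores.values())))
            weights = weights / weights.sum()
            ctx = sum(w * (wv.T @ x[j]) for w, j in zip(weights, scores))
            expected[i] = ctx
        expected = np.tanh(expected @ wo)
        got = attention_embed(batch, params).data[0]
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestMLP:
    def test_zero_params_zero_output(self, rng):
        config = tiny_config()
        params = init_params(config, seed=1)
        for name in ("mlp_w1", "mlp_b1", "mlp_w2", "mlp_b2", "mlp_w3", "mlp_b3"):
            params[name].data *= 0.0
        batch, _ = tiny_batch(rng, config)
        np.testing.assert_array_equal(mlp_embed(batch, params).data, 0.0)

    def test_vertex_independence(self, rng):
        config = tiny_config()
        params = init_params(config, seed=4)
        embeddings = rng.normal(size=(8, 3))
        batch1 = make_batch([(0, 1, 2)], embeddings, 6)
        batch2 = make_batch([(0, 5, 6)], embeddings, 6)
        out1 = mlp_embed(batch1, params).data
        out2 = mlp_embed(batch2, params).data
        np.testing.assert_array_equal(out1[0, 0], out2[0, 0])

    def test_hand_computation_2d(self):
        config = ModelConfig(feature_dim=2, embed_dim=2, n_heads=1, dropout=0.0)
        params = init_params(config, seed=5)
        w1 = np.array([[1.0, -1.0], [0.5, 2.0]])
        b1 = np.array([0.1, -0.2])
        w2 = np.array([[2.0, 0.0], [1.0, 1.0]])
        b2 = np.array([0.0, 0.3])
        w3 = np.array([[1.0, 1.0], [-1.0, 0.5]])
        b3 = np.array([-0.1, 0.0])
        for name, value in [
            ("mlp_w1", w1), ("mlp_b1", b1), ("mlp_w2", w2),
            ("mlp_b2", b2), ("mlp_w3", w3), ("mlp_b3", b3),
        ]:
            params[name].data = value
        x = np.array([0.7, -0.4])
        embeddings = np.vstack([x, np.ones((2, 2))])
        batch = make_batch([(0, 1, 2)], embeddings, 3)
        h1 = np.maximum(x @ w1 + b1, 0)
        h2 = np.maximum(h1 @ w2 + b2, 0)
        expected = h2 @ w3 + b3
        np.testing.assert_allclose(mlp_embed(batch, params).data[0, 0], expected, atol=1e-12)


class TestKLAlign:
    def test_identical_channels_zero(self, rng):
        e = Tensor(rng.normal(size=(2, 3, 4)))
        mask = np.ones((2, 3))
        assert kl_align(e, e, mask).item() == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative(self, rng):
        for _ in range(20):
            a = Tensor(rng.normal(size=(2, 3, 4)))
            b = Tensor(rng.normal(size=(2, 3, 4)))
            assert kl_align(a, b, np.ones((2, 3))).item() >= 0.0

    def test_hand_computation(self):
        # two fixed 4-d pooled vectors, base-2 KL of their softmaxes
        a = np.array([0.2, -1.0, 0.5, 0.0])
        b = np.array([1.0, 0.0, -0.5, 0.25])
        p = np.exp(a) / np.exp(a).sum()
        q = np.exp(b) / np.exp(b).sum()
        expected = float(np.sum(p * np.log2(p / q)))
        got = kl_align(
            Tensor(a.reshape(1, 1, 4).repeat(2, axis=1)),
            Tensor(b.reshape(1, 1, 4).repeat(2, axis=1)),
            np.ones((1, 2)),
        ).item()
        assert got == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValidationError):
            kl_align(Tensor(np.zeros((1, 2, 3))), Tensor(np.zeros((1, 2, 4))), np.ones((1, 2)))


def dense_hconv_oracle(x, graph, weights, slope=0.01):
    """Brute-force dense evaluation of the propagation rule."""
    h = graph.H.toarray()
    w = np.diag(graph.W.diagonal())
    dv = np.diag(graph.Dv.diagonal())
    de = np.diag(graph.De.diagonal())
    dv_isqrt = np.linalg.pinv(np.sqrt(dv))
    de_inv = np.linalg.pinv(de)
    prop = dv_isqrt @ h @ w @ de_inv @ h.T @ dv_isqrt
    out = np.asarray(x, dtype=float)
    for wt in weights:
        pre = prop @ out @ wt
        out = np.where(pre > 0, pre, slope * pre)
    return out


class TestHconv:
    def test_hand_two_vertices(self):
        # one hyperedge over both vertices, identity weights, X = (1, 0)^T:
        # Dv = I, De = 2 -> propagated X = (0.5, 0.5)^T
        edges = HyperedgeSet((Hyperedge((0, 1), 1),), 2)
        graph = build_hypergraph(edges)
        prop = propagation_matrix(graph).toarray()
        np.testing.assert_allclose(prop @ np.array([1.0, 0.0]), [0.5, 0.5])

    def test_zero_input_zero_output(self, rng):
        config = tiny_config()
        params = init_params(config, seed=1)
        graph = build_hypergraph(random_hypergraph(rng))
        out = hconv(np.zeros((graph.n_bins, config.feature_dim)), graph, params)
        np.testing.assert_array_equal(out.data, 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_sparse_equals_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        config = tiny_config(hconv_layers=3)
        params = init_params(config, seed=seed)
        graph = build_hypergraph(random_hypergraph(rng))
        x = rng.normal(size=(graph.n_bins, config.feature_dim))
        weights = [params[f"hconv_w{t}"].data for t in range(3)]
        expected = dense_hconv_oracle(x, graph, weights)
        np.testing.assert_allclose(hconv(x, graph, params).data, expected, atol=1e-10)

    def test_dimension_mismatch(self, rng):
        config = tiny_config()
        params = init_params(config, seed=0)
        graph = build_hypergraph(random_hypergraph(rng))
        with pytest.raises(ValidationError):
            hconv(np.zeros((graph.n_bins + 1, config.feature_dim)), graph, params)


class TestFuseAndScore:
    def test_zero_head_gives_half(self, rng):
        config = tiny_config()
        params = init_params(config, seed=1)
        params["head_w"].data *= 0.0
        params["head_b"].data *= 0.0
        batch, embeddings = tiny_batch(rng, config)
        graph = build_hypergraph(random_hypergraph(rng, n=8))
        p, _ = forward(params, batch, embeddings, graph)
        np.testing.assert_allclose(p.data, 0.5, atol=1e-12)

    def test_probabilities_in_unit_interval(self, rng):
        config = tiny_config()
        params = init_params(config, seed=2)
        batch, embeddings = tiny_batch(rng, config)
        graph = build_hypergraph(random_hypergraph(rng, n=8))
        p, _ = forward(params, batch, embeddings, graph)
        assert np.all(p.data > 0.0) and np.all(p.data < 1.0)

    def test_hand_logits_average(self):
        # engineered logits (1, 0, -1) -> p = (sig(1)+sig(0)+sig(-1))/3 = 0.5
        config = ModelConfig(
            feature_dim=1, embed_dim=1, n_heads=1, dropout=0.0, variant="noCHE"
        )
        params = init_params(config, seed=0)
        for name in ("attn_q0", "attn_k0", "attn_v0", "attn_out"):
            params[name].data *= 0.0
        params["mlp_w1"].data = np.array([[2.0]])
        params["mlp_b1"].data = np.array([0.0])
        params["mlp_w2"].data = np.array([[1.0]])
        params["mlp_b2"].data = np.array([0.0])
        params["mlp_w3"].data = np.array([[1.0]])
        params["mlp_b3"].data = np.array([0.0])
        params["fusion_w"].data = np.array([[1.0]])
        params["fusion_b"].data = np.array([0.0])
        params["head_w"].data = np.array([[1.0]])
        params["head_b"].data = np.array([-1.0])
        embeddings = np.array([[2.0], [1.0], [0.0]])
        batch = make_batch([(0, 1, 2)], embeddings, 3)
        p, _ = forward(params, batch)
        expected = (1 / (1 + np.exp(-1)) + 0.5 + 1 / (1 + np.exp(1))) / 3
        assert expected == pytest.approx(0.5)
        np.testing.assert_allclose(p.data, [expected], atol=1e-12)


class TestInvariances:
    def test_masking_invariance_bitwise(self, rng):
        config = tiny_config()
        params = init_params(config, seed=6)
        embeddings = rng.normal(size=(8, config.feature_dim))
        graph = build_hypergraph(random_hypergraph(rng, n=8))
        structural = hconv(embeddings, graph, params)
        tup = (1, 4, 6)
        for pad_to in (3, 4, 6):
            batch = make_batch([tup], embeddings, pad_to)
            p, kl = forward(params, batch, structural=structural)
            if pad_to == 3:
                reference_p, reference_kl = p.data.copy(), kl.item()
            else:
                np.testing.assert_array_equal(p.data, reference_p)
                assert kl.item() == reference_kl

    def test_permutation_invariance(self, rng):
        config = tiny_config()
        params = init_params(config, seed=7)
        embeddings = rng.normal(size=(8, config.feature_dim))
        graph = build_hypergraph(random_hypergraph(rng, n=8))
        structural = hconv(embeddings, graph, params)
        p1, _ = forward(params, make_batch([(1, 4, 6, 7)], embeddings, 6), structural=structural)
        p2, _ = forward(params, make_batch([(7, 1, 6, 4)], embeddings, 6), structural=structural)
        np.testing.assert_allclose(p1.data, p2.data, atol=1e-12)


class TestTotalLoss:
    def test_confident_correct_near_zero(self):
        p = Tensor(np.array([1.0 - 1e-7]))
        loss = total_loss(p, np.array([1.0]), Tensor(0.0), 0.0)
        assert loss.item() == pytest.approx(0.0, abs=1e-6)

    def test_half_probability_is_ln2(self):
        p = Tensor(np.array([0.5]))
        loss = total_loss(p, np.array([1.0]), Tensor(0.0), 0.0)
        assert loss.item() == pytest.approx(LN2, rel=1e-12)

    def test_lambda_zero_is_bce_alone(self, rng):
        p = Tensor(rng.uniform(0.1, 0.9, size=5))
        labels = rng.integers(0, 2, size=5).astype(float)
        kl = Tensor(3.7)
        bce_only = total_loss(p, labels, kl, 0.0).item()
        with_kl = total_loss(p, labels, kl, 2.0).item()
        assert with_kl == pytest.approx(bce_only + 2.0 * 3.7)

    def test_extreme_probabilities_clamped(self):
        p = Tensor(np.array([0.0, 1.0]))
        loss = total_loss(p, np.array([1.0, 0.0]), Tensor(0.0), 0.0)
        assert np.isfinite(loss.item())


class TestClassify:
    def test_threshold_inclusive(self):
        assert classify(np.array([0.5]))[0] == 1

    def test_just_below_threshold(self):
        assert classify(np.array([0.4999]))[0] == 0

    def test_zero_threshold_all_positive(self, rng):
        assert classify(rng.uniform(size=20), threshold=0.0).sum() == 20


class TestGradientCheck:
    def test_finite_difference_matches_autodiff(self, rng):
        config = tiny_config(hconv_layers=2)
        params = init_params(config, seed=8)
        graph = build_hypergraph(random_hypergraph(rng))
        embeddings = rng.normal(size=(graph.n_bins, config.feature_dim))
        samples = [
            LabeledSample((0, 1, 2), 1),
            LabeledSample((1, 3, 4, 5), 0),
        ]
        batch = batch_from_samples(samples, embeddings, 6)
        # zero-initialized biases put closed rectifier units exactly on the
        # kink; perturb to a generic smooth point before differencing
        for t in params.all_tensors():
            t.data += rng.normal(scale=0.05, size=t.data.shape)

        def loss_value():
            p, kl = forward(params, batch, embeddings, graph)
            return total_loss(p, batch.labels, kl, 1.0)

        from tests.conftest import assert_gradients_match

        assert_gradients_match(loss_value, params, rng, n_coords=4)


class TestBatchesAndCheckpoint:
    def test_tuple_batch_validation(self):
        with pytest.raises(ValidationError):
            TupleBatch(
                features=np.zeros((1, 3, 2)),
                mask=np.array([[1.0, 0.0, 0.0]]),
                vertex_ids=np.zeros((1, 3), dtype=int),
            )

    def test_make_batch_order_overflow(self, rng):
        with pytest.raises(ValidationError):
            make_batch([tuple(range(7))], rng.normal(size=(10, 2)), 6)

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        config = tiny_config()
        params = init_params(config, seed=9)
        path = tmp_path / "model.ckpt"
        save_checkpoint(params, path)
        again = load_checkpoint(path)
        assert again.config == config
        for name, tensor in params.tensors.items():
            np.testing.assert_array_equal(again[name].data, tensor.data)

    def test_score_tuples_matches_forward(self, rng):
        config = tiny_config()
        params = init_params(config, seed=10)
        graph = build_hypergraph(random_hypergraph(rng))
        embeddings = rng.normal(size=(graph.n_bins, config.feature_dim))
        tuples = [(0, 1, 2), (1, 2, 3, 4)]
        scores = score_tuples(params, tuples, embeddings, graph)
        structural = hconv(embeddings, graph, params)
        p, _ = forward(params, make_batch(tuples, embeddings, 6), structural=structural)
        np.testing.assert_allclose(scores, p.data, atol=1e-12)

    def test_ablation_variants_drop_channels(self, rng):
        for variant in ("noSHE", "noCHE"):
            config = tiny_config(variant=variant)
            params = init_params(config, seed=11)
            if variant == "noSHE":
                assert "mlp_w1" not in params.tensors
                assert "attn_q0" not in params.tensors
            else:
                assert "hconv_w0" not in params.tensors
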
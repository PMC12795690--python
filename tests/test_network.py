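"""Network module: encoders, attention layer, pooling, fusion, gradients."""

import numpy as np
import pytest

from ppisurf.autodiff import Tensor
from ppisurf.errors import ShapeError, ValidationError
from ppisurf.graphs import GeometricGraph, build_schull
from ppisurf.network import (BatchedGraphs, ModelConfig, PairBatch,
                             PairClassifier)


def small_model(H=8, dtype="float64", **kw) -> PairClassifier:
    return PairClassifier(ModelConfig(hidden_dim=H, rng_seed=0, dtype=dtype, **kw)).eval()


def random_graph(seed, n, f=32):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    g = build_schull(pts) if n >= 4 else GeometricGraph(
        pts, None, np.zeros((2, 0), int))
    g.x = rng.normal(size=(n, f))
    return g


def pt_layer_oracle(model: PairClassifier, h: np.ndarray, pos: np.ndarray,
                    edge_index: np.ndarray, layer: int = 0) -> np.ndarray:
    """Dense per-node re-implementation of the attention layer (eval mode)."""
    p = {k: v.data for k, v in model.params.items()}

    def mlp(x, pre):
        hid = np.maximum(x @ p[f"{pre}_W1"] + p[f"{pre}_b1"], 0.0)
        return hid @ p[f"{pre}_W2"] + p[f"{pre}_b2"]

    n = len(h)
    nbrs = {i: [] for i in range(n)}
    for s, d in edge_index.T:
        nbrs[int(d)].append(int(s))
    for i in range(n):
        nbrs[i].append(i)  # self-loop
    out = np.zeros_like(h)
    for i in range(n):
        js = nbrs[i]
        delta = np.stack([mlp(pos[i] - pos[j], f"L{layer}_pos") for j in js])
        logits = np.stack([
            mlp(h[i] @ p[f"L{layer}_W1"] - h[j] @ p[f"L{layer}_W2"] + delta[k],
                f"L{layer}_att")
            for k, j in enumerate(js)])
        e = np.exp(logits - logits.max(axis=0))
        alpha = e / e.sum(axis=0)
        msgs = np.stack([h[j] @ p[f"L{layer}_W3"] + delta[k]
                         for k, j in enumerate(js)])
        out[i] = np.maximum((alpha * msgs).sum(axis=0), 0.0)
    return out


class TestEncodeNodes:
    def test_zero_row_maps_to_zero(self):
        m = small_model()
        out = m.encode_nodes(np.zeros((3, 32)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    @pytest.mark.parametrize("H", [8, 64])
    def test_output_width(self, H):
        m = small_model(H=H)
        assert m.encode_nodes(np.random.default_rng(0).normal(size=(5, 32))).shape == (5, H)

    def test_eval_mode_deterministic(self):
        m = small_model()
        x = np.random.default_rng(1).normal(size=(6, 32))
        np.testing.assert_array_equal(m.encode_nodes(x).data, m.encode_nodes(x).data)

    def test_width_mismatch_raises(self):
        with pytest.raises(ShapeError):
            small_model().encode_nodes(np.zeros((3, 30)))


class TestPositionalEncoding:
    def test_identical_positions_give_h_theta_zero(self):
        m = small_model()
        pos = np.ones((5, 3))
        ei = np.array([[0, 1, 2, 1, 2, 0], [1, 0, 1, 2, 0, 2]])
        out = m.positional_encoding(pos, ei).data
        assert np.allclose(out, out[0], atol=1e-12)

    def test_translation_invariance(self):
        m = small_model()
        rng = np.random.default_rng(2)
        pos = rng.normal(size=(6, 3))
        g = build_schull(pos)
        a = m.positional_encoding(pos, g.edge_index).data
        b = m.positional_encoding(pos + np.array([5.0, -3.0, 11.0]), g.edge_index).data
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_permutation_equivariance_vs_loop(self):
        m = small_model()
        rng = np.random.default_rng(3)
        pos = rng.normal(size=(7, 3))
        g = build_schull(pos)
        out = m.positional_encoding(pos, g.edge_index).data
        # explicit per-node loop
        p = {k: v.data for k, v in m.params.items()}

        def htheta(d):
            hid = np.maximum(d @ p["pe_W1"] + p["pe_b1"], 0.0)
            return hid @ p["pe_W2"] + p["pe_b2"]

        for i in range(7):
            js = [s for s, d in g.edge_index.T if d == i]
            expected = np.mean([htheta(pos[i] - pos[j]) for j in js], axis=0)
            np.testing.assert_allclose(out[i], expected, atol=1e-10)
        # permuting node order permutes rows identically
        perm = rng.permutation(7)
        inv = np.argsort(perm)
        ei_p = np.stack([inv[g.edge_index[0]], inv[g.edge_index[1]]])
        out_p = m.positional_encoding(pos[perm], ei_p).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-10)

    def test_empty_neighborhood_receives_h_theta_zero(self):
        m = small_model()
        out = m.positional_encoding(np.zeros((4, 3)), np.zeros((2, 0), int)).data
        p = {k: v.data for k, v in m.params.items()}
        h0 = np.maximum(np.zeros(3) @ p["pe_W1"] + p["pe_b1"], 0.0) @ p["pe_W2"] + p["pe_b2"]
        np.testing.assert_allclose(out, np.tile(h0, (4, 1)), atol=1e-12)


class TestPtLayer:
    def test_isolated_node_single_softmax(self):
        m = small_model()
        h = Tensor(np.random.default_rng(4).normal(size=(1, 8)))
        pos = np.zeros((1, 3))
        out = m.pt_layer(h, pos, np.zeros((2, 0), int)).data
        p = {k: v.data for k, v in m.params.items()}
        delta = (np.maximum(np.zeros(3) @ p["L0_pos_W1"] + p["L0_pos_b1"], 0)
                 @ p["L0_pos_W2"] + p["L0_pos_b2"])
        expected = np.maximum(h.data[0] @ p["L0_W3"] + delta, 0.0)
        np.testing.assert_allclose(out[0], expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        m = small_model()
        g = random_graph(seed + 100, n)
        h = rng.normal(size=(n, 8))
        out = m.pt_layer(Tensor(h), g.pos, g.edge_index).data
        expected = pt_layer_oracle(m, h, g.pos, g.edge_index)
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_attention_normalized_per_channel(self):
        from ppisurf.autodiff import segment_softmax

        rng = np.random.default_rng(5)
        logits = Tensor(rng.normal(size=(12, 4)))
        seg = np.array([0, 0, 0, 1, 1, 2, 2, 2, 2, 3, 3, 3])
        alpha = segment_softmax(logits, seg, 4).data
        sums = np.zeros((4, 4))
        np.add.at(sums, seg, alpha)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)


class TestPoolChain:
    def test_constant_embeddings_pool_to_constant(self):
        v = np.arange(8.0)
        h = Tensor(np.tile(v, (5, 1)))
        out = PairClassifier.pool_chain(h, np.array([0, 0, 1, 1, 1]), 2).data
        np.testing.assert_allclose(out, np.tile(v, (2, 1)))

    def test_chains_pooled_independently_and_match_loop(self):
        rng = np.random.default_rng(6)
        h = rng.normal(size=(10, 4))
        chains = np.array([0, 0, 0, 1, 1, 1, 1, 0, 1, 1])
        out = PairClassifier.pool_chain(Tensor(h), chains, 2).data
        for c in (0, 1):
            np.testing.assert_allclose(out[c], h[chains == c].mean(axis=0), atol=1e-12)
        # changing the other chain's nodes leaves this chain's pool untouched
        h2 = h.copy()
        h2[chains == 1] += 100.0
        out2 = PairClassifier.pool_chain(Tensor(h2), chains, 2).data
        np.testing.assert_allclose(out2[0], out[0], atol=1e-12)


class TestProjectSequence:
    def test_zero_input_zero_biases_gives_zero(self):
        m = small_model()
        np.testing.assert_allclose(m.project_sequence(np.zeros(1024)).data, 0.0)

    def test_output_width_and_determinism(self):
        m = small_model(H=16)
        s = np.random.default_rng(7).normal(size=(3, 1024))
        out = m.project_sequence(s)
        assert out.shape == (3, 16)
        np.testing.assert_array_equal(out.data, m.project_sequence(s).data)

    def test_width_mismatch(self):
        with pytest.raises(ShapeError):
            small_model().project_sequence(np.zeros(512))


def make_batch(seeds, seq_dim=1024):
    """One pair per seed, each generated independently of batch order."""
    graphs_l, graphs_r, seq_l, seq_r = [], [], [], []
    for s in seeds:
        rng = np.random.default_rng(s)
        graphs_l.append(random_graph(s, int(rng.integers(6, 12))))
        graphs_r.append(random_graph(s + 50, int(rng.integers(6, 12))))
        seq_l.append(rng.normal(size=seq_dim))
        seq_r.append(rng.normal(size=seq_dim))
    return PairBatch(
        ligand=BatchedGraphs.from_graphs(graphs_l),
        receptor=BatchedGraphs.from_graphs(graphs_r),
        seq_ligand=np.stack(seq_l),
        seq_receptor=np.stack(seq_r),
        labels=np.array([s % 2 for s in seeds]))


class TestForwardPair:
    def test_probabilities_strictly_in_unit_interval(self):
        m = small_model()
        probs = m.forward_pair(make_batch([1, 2, 3, 4])).data
        assert np.all(probs > 0) and np.all(probs < 1)

    def test_disabling_sequence_halves_fusion_width(self):
        with_seq = small_model(H=8)
        without = small_model(H=8, use_sequence=False)
        assert with_seq.params["head_W1"].shape == (32, 8)
        assert without.params["head_W1"].shape == (16, 8)
        probs = without.forward_pair(make_batch([1, 2])).data
        assert probs.shape == (2,)

    def test_ablation_flags_run(self):
        batch = make_batch([3, 4])
        for kw in ({"use_positional_encoder": False}, {"use_pt_block": False},
                   {"num_pt_layers": 1}, {"num_pt_layers": 5}):
            probs = small_model(H=8, **kw).forward_pair(batch).data
            assert probs.shape == (2,) and np.all((probs > 0) & (probs < 1))

    def test_batch_permutation_equivariance(self):
        m = small_model()
        seeds = [11, 12, 13, 14]
        probs = m.forward_pair(make_batch(seeds)).data
        probs_rev = m.forward_pair(make_batch(seeds[::-1])).data
        np.testing.assert_allclose(probs_rev, probs[::-1], atol=1e-10)

    def test_invalid_layer_count_rejected(self):
        with pytest.raises(ValidationError):
            ModelConfig(num_pt_layers=6)


class TestCheckpoint:
    def test_save_load_round_trip_preserves_predictions(self, tmp_path):
        m = small_model(H=8, dtype="float32")
        batch = make_batch([41, 42, 43])
        probs = m.forward_pair(batch).data
        m.save(tmp_path / "w.npz", tmp_path / "cfg.json")
        m2 = PairClassifier.load(tmp_path / "w.npz", tmp_path / "cfg.json").eval()
        assert m2.cfg == m.cfg
        np.testing.assert_array_equal(m2.forward_pair(batch).data, probs)


class TestGradients:
    def test_gradients_reach_every_parameter_group(self):
        from ppisurf.train_eval import _bce

        m = small_model(H=4).train()
        batch = make_batch([21, 22])
        loss = _bce(m.forward_pair(batch), batch.labels)
        loss.backward()
        for name, p in m.params.items():
            assert p.grad is not None, name
            assert np.all(np.isfinite(p.grad)), name
        nonzero = [name for name, p in m.params.items() if np.any(p.grad != 0)]
        for group in ("W_in", "pe_W1", "L0_W1", "L0_W3", "L0_att_W1",
                      "L0_pos_W1", "seq_W1", "head_W1"):
            assert group in nonzero

    def test_finite_difference_gradient_check(self):
        from ppisurf.train_eval import _bce

        m = small_model(H=4).eval()  # eval mode: no dropout noise in the check
        batch = make_batch([31, 32])

        def loss_value():
            return float(_bce(m.forward_pair(batch), batch.labels).data)

        for p in m.params.values():
            p.grad = None
        loss = _bce(m.forward_pair(batch), batch.labels)
        loss.backward()
        rng = np.random.default_rng(0)
        eps = 1e-6
        for name in ("W_in", "L0_att_W1", "L1_W3", "seq_W2", "head_W1", "pe_W2"):
            p = m.params[name]
            flat = p.data.ravel()
            for _ in range(3):
                i = int(rng.integers(flat.size))
                orig = flat[i]
                flat[i] = orig + eps
                up = loss_value()
                flat[i] = orig - eps
                down = loss_value()
                flat[i] = orig
                fd = (up - down) / (2 * eps)
                an = p.grad.ravel()[i]
                assert abs(fd - an) <= 1e-4 * max(1.0, abs(fd)), name
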
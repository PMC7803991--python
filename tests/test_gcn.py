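"""GCN layers, forward determinism, training loop and stopping rule."""

import numpy as np
import pytest

import gcnqsar as g
from gcnqsar.gcn import GraphBatch, TrainingDiverged, TrainingTrace

from conftest import featurized


def _bn_relu(z):
    z = np.asarray(z, dtype=float)
    xhat = (z - z.mean(axis=0)) / np.sqrt(z.var(axis=0) + 1e-5)
    return np.maximum(xhat, 0.0)


class TestGraphConv:
    def test_zero_weights_give_zero_vector(self):
        graph = g.featurize_molecule("C")
        out = g.graph_conv(
            graph, np.ones((1, 3)), np.zeros((3, 2)), np.zeros((3, 2)), np.zeros(2)
        )
        assert np.allclose(out, 0.0)

    def test_two_atom_identity_weights_match_hand_update(self):
        graph = g.featurize_molecule("CC")
        states = np.array([[1.0], [2.0]])
        w = np.array([[1.0]])
        out = g.graph_conv(graph, states, w, w, np.zeros(1))
        # own + neighbour = (1+2, 2+1), then batch-norm and ReLU
        expected = _bn_relu(np.array([[3.0], [3.0]]))
        assert np.allclose(out, expected)

    def test_permutation_equivariance(self):
        graph = g.featurize_molecule("CCO")
        rng = np.random.default_rng(0)
        states = rng.normal(size=(3, 4))
        w_self, w_nbr = rng.normal(size=(4, 5)), rng.normal(size=(4, 5))
        bias = rng.normal(size=5)
        out = g.graph_conv(graph, states, w_self, w_nbr, bias)
        perm = [2, 0, 1]
        permuted = g.MolecularGraph(
            smiles=graph.smiles,
            n_atoms=3,
            atom_feats=graph.atom_feats[perm],
            neighbors=[[perm.index(u) for u in graph.neighbors[v]] for v in perm],
        )
        out_p = g.graph_conv(permuted, states[perm], w_self, w_nbr, bias)
        assert np.allclose(out_p, out[perm])

    def test_dimension_mismatch_is_a_contract_error(self):
        graph = g.featurize_molecule("CC")
        with pytest.raises(ValueError):
            g.graph_conv(graph, np.ones((2, 3)), np.zeros((4, 2)), np.zeros((4, 2)),
                         np.zeros(2))


class TestGraphPool:
    def test_path_graph_hand_example(self):
        graph = g.featurize_molecule("CCC")
        states = np.array([[1.0], [5.0], [2.0]])
        assert np.allclose(g.graph_pool(graph, states), [[5.0], [5.0], [5.0]])

    def test_isolated_atom_keeps_its_state(self):
        graph = g.featurize_molecule("C")
        assert np.allclose(g.graph_pool(graph, np.array([[3.5, -1.0]])), [[3.5, -1.0]])

    def test_equal_states_are_unchanged(self):
        graph = g.featurize_molecule("c1ccccc1")
        states = np.full((6, 3), 0.7)
        assert np.allclose(g.graph_pool(graph, states), states)


class TestGraphGather:
    def test_single_atom_is_tanh_of_its_dense_output(self):
        d = np.array([[0.3, -2.0]])
        assert np.allclose(g.graph_gather(d), np.tanh(d[0]))

    def test_opposite_outputs_cancel_to_zero(self):
        d = np.array([[1.0, -0.5], [-1.0, 0.5]])
        assert np.allclose(g.graph_gather(d), 0.0)

    def test_output_length_is_dense_size(self):
        d = np.random.default_rng(1).normal(size=(7, 13))
        assert g.graph_gather(d).shape == (13,)


class TestForward:
    @pytest.fixture(scope="class")
    def model(self):
        cfg = g.GCNConfig(n_conv_layers=2, conv_size=16, dense_size=12, seed=5)
        rng = np.random.default_rng(cfg.seed)
        from gcnqsar.gcn import init_params

        params, running = init_params(cfg, rng)
        return g.GCNModel(params, running, cfg)

    def test_fresh_model_emits_finite_scalars(self, model):
        graphs = g.featurize_many(["CCO", "c1ccccc1", "CC(=O)O"])
        preds = model.predict(graphs)
        assert preds.shape == (3,) and np.all(np.isfinite(preds))

    def test_identical_molecules_in_one_batch_agree(self, model):
        graphs = g.featurize_many(["CCO"] * 4)
        preds = model.predict_batch(GraphBatch(graphs))
        assert np.allclose(preds, preds[0])

    def test_batch_prediction_matches_per_molecule(self, model):
        graphs = g.featurize_many(["CCO", "c1ccncc1", "CC(C)Br", "C1CCCCC1O"])
        batched = model.predict_batch(GraphBatch(graphs))
        singles = [model.predict_batch(GraphBatch([gr]))[0] for gr in graphs]
        assert np.allclose(batched, singles, atol=1e-5)

    def test_atom_relabeling_leaves_prediction_unchanged(self, model):
        a = model.predict(g.featurize_many(["OCCc1ccccc1"]))[0]
        b = model.predict(g.featurize_many(["c1ccccc1CCO"]))[0]
        assert a == pytest.approx(b, abs=1e-5)


class TestEpochSelection:
    def _trace(self, trmae):
        t = TrainingTrace()
        for i, v in enumerate(trmae, start=1):
            t.append(i, 0.5, 0.5, v)
        return t

    def test_single_epoch(self):
        assert g.select_final_epoch(self._trace([0.4])) == 1

    def test_tie_goes_to_earliest(self):
        assert g.select_final_epoch(self._trace([0.1, 0.7, 0.7])) == 2

    def test_monotone_sequence_selects_last(self):
        assert g.select_final_epoch(self._trace([0.1, 0.2, 0.9])) == 3


def replay_stopping_rule(valid_maes, block):
    """Independent implementation of the epoch-block stopping rule."""
    global_min = np.inf
    epoch = 0
    while epoch < len(valid_maes):
        chunk = valid_maes[epoch : epoch + block]
        if len(chunk) < block:
            raise AssertionError("trace does not end on a block boundary")
        epoch += block
        block_min = min(chunk)
        if block_min >= global_min:
            return epoch
        global_min = block_min
    return epoch  # trace exhausted while still improving


class TestStoppingRule:
    @pytest.mark.parametrize(
        "block_minima,expected_blocks",
        [((0.50, 0.48, 0.49), 3), ((0.50, 0.50), 2), ((0.5, 0.4, 0.3, 0.3), 4)],
    )
    def test_oracle_on_hand_sequences(self, block_minima, expected_blocks):
        block = 4
        maes = []
        for m in block_minima:
            maes.extend([m + 0.05] * (block - 1) + [m])
        assert replay_stopping_rule(maes, block) == expected_blocks * block

    def test_trained_traces_replay_to_the_recorded_stopping_epoch(self, tiny_sets):
        for seed in (0, 1):
            cfg = g.GCNConfig(conv_size=16, dense_size=16, batch_size=50,
                              max_epoch_block=10, seed=seed)
            _, trace = g.train(tiny_sets["train"], tiny_sets["valid"], cfg)
            assert len(trace.valid_mae) == trace.stopping_epoch
            assert replay_stopping_rule(trace.valid_mae, 10) == trace.stopping_epoch
            assert trace.selected_epoch == trace.epochs[
                int(np.argmax(trace.valid_trmae))
            ]


def _reference_forward_backward(params, batch, cfg, y):
    """Independent float64 forward and hand-derived backward on dense
    adjacency matrices; the oracle for the float32 training kernels."""
    X = batch.X.astype(np.float64)
    adj = batch.adj.toarray().astype(np.float64)
    caches, H = [], X
    for l in range(cfg.n_conv_layers):
        Ws = params[f"conv{l}_wself"].astype(np.float64)
        Wn = params[f"conv{l}_wnbr"].astype(np.float64)
        gam = params[f"conv{l}_gamma"].astype(np.float64)
        bet = params[f"conv{l}_beta"].astype(np.float64)
        N = adj @ H
        Z = H @ Ws + N @ Wn + params[f"conv{l}_b"].astype(np.float64)
        invstd = 1 / np.sqrt(Z.var(0) + 1e-5)
        xhat = (Z - Z.mean(0)) * invstd
        B = gam * xhat + bet
        R = np.maximum(B, 0)
        A = len(R)
        P, arg = R.copy(), np.tile(np.arange(A)[:, None], (1, R.shape[1]))
        for v in range(A):
            for u in np.where(adj[v] > 0)[0]:
                better = R[u] > P[v]
                P[v] = np.where(better, R[u], P[v])
                arg[v] = np.where(better, u, arg[v])
        caches.append(dict(H=H, N=N, invstd=invstd, xhat=xhat, B=B, P=P, arg=arg))
        H = P
    Wd = params["dense_w"].astype(np.float64)
    Wo = params["out_w"].astype(np.float64)
    D = H @ Wd + params["dense_b"].astype(np.float64)
    S = np.zeros((batch.n_mols, D.shape[1]))
    np.add.at(S, batch.mol_index, D)
    fp = np.tanh(S)
    pred = fp @ Wo[:, 0] + params["out_b"].astype(np.float64)[0]

    grads = {}
    gpred = 2 * (pred - y) / len(y)
    grads["out_b"] = np.array([gpred.sum()])
    grads["out_w"] = (fp.T @ gpred)[:, None]
    gS = (gpred[:, None] * Wo[:, 0]) * (1 - fp**2)
    gD = gS[batch.mol_index]
    grads["dense_w"] = caches[-1]["P"].T @ gD
    grads["dense_b"] = gD.sum(0)
    gH = gD @ Wd.T
    for l in range(cfg.n_conv_layers - 1, -1, -1):
        c = caches[l]
        gR = np.zeros_like(c["P"])
        for v in range(len(gR)):
            for col in range(gR.shape[1]):
                gR[c["arg"][v, col], col] += gH[v, col]
        gB = gR * (c["B"] > 0)
        gam = params[f"conv{l}_gamma"].astype(np.float64)
        grads[f"conv{l}_gamma"] = (gB * c["xhat"]).sum(0)
        grads[f"conv{l}_beta"] = gB.sum(0)
        gxhat = gB * gam
        m = len(gB)
        gZ = (c["invstd"] / m) * (
            m * gxhat - gxhat.sum(0) - c["xhat"] * (gxhat * c["xhat"]).sum(0)
        )
        grads[f"conv{l}_wself"] = c["H"].T @ gZ
        grads[f"conv{l}_wnbr"] = c["N"].T @ gZ
        gH = gZ @ params[f"conv{l}_wself"].astype(np.float64).T + adj.T @ (
            gZ @ params[f"conv{l}_wnbr"].astype(np.float64).T
        )
    return pred, grads


def test_backward_matches_independent_float64_reference():
    """The float32 training kernels reproduce an independent dense float64
    implementation of the same network, for predictions and gradients.
    (The conv bias is excluded: batch norm makes it a no-op, so its true
    gradient is ~0 and only float noise remains.)"""
    from gcnqsar.gcn import GraphBatch, _backward, _forward, init_params

    graphs = g.featurize_many(["CCO", "c1ccncc1", "CC(C)Br", "C1CCCCC1O"])
    y = np.array([6.0, 7.5, 5.0, 6.5], dtype=np.float32)
    batch = GraphBatch(graphs, y)
    for layers in (1, 2):
        cfg = g.GCNConfig(n_conv_layers=layers, conv_size=5, dense_size=4, seed=3)
        rng = np.random.default_rng(cfg.seed)
        params, running = init_params(cfg, rng)
        pred_ref, grads_ref = _reference_forward_backward(params, batch, cfg, y)
        pred, cache = _forward(params, running, batch, cfg, training=True, rng=rng)
        assert np.allclose(pred, pred_ref, atol=1e-5)
        gpred = (2.0 / len(y)) * (pred - y).astype(np.float32)
        grads = _backward(params, batch, cfg, cache, gpred)
        for key, ref in grads_ref.items():
            scale = np.abs(ref).max() + 1e-8
            err = np.abs(np.asarray(grads[key], dtype=float) - ref).max()
            assert err / scale < 1e-4, key


def test_output_path_gradients_match_finite_differences():
    """Central finite differences on the smooth output path (dense/gather/
    tanh/linear, no ReLU or pooling kinks) confirm the analytic gradients."""
    from gcnqsar.gcn import GraphBatch, _backward, _forward, init_params

    graphs = g.featurize_many(["CCO", "c1ccncc1", "CC(C)Br"])
    y = np.array([6.0, 7.5, 5.0], dtype=np.float32)
    batch = GraphBatch(graphs, y)
    cfg = g.GCNConfig(n_conv_layers=1, conv_size=6, dense_size=4, seed=9)
    rng = np.random.default_rng(cfg.seed)
    params, running = init_params(cfg, rng)

    def loss_at():
        run = {k: v.copy() for k, v in running.items()}
        pred, _ = _forward(params, run, batch, cfg, training=True, rng=rng)
        return float(np.mean((pred - y) ** 2))

    run = {k: v.copy() for k, v in running.items()}
    pred, cache = _forward(params, run, batch, cfg, training=True, rng=rng)
    gpred = (2.0 / len(y)) * (pred - y).astype(np.float32)
    grads = _backward(params, batch, cfg, cache, gpred)

    probe = np.random.default_rng(0)
    h = 1e-2
    for key in ("dense_w", "dense_b", "out_w", "out_b"):
        flat = params[key].reshape(-1)
        for idx in probe.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + h
            up = loss_at()
            flat[idx] = orig - h
            down = loss_at()
            flat[idx] = orig
            numeric = (up - down) / (2 * h)
            analytic = float(np.asarray(grads[key]).reshape(-1)[idx])
            assert analytic == pytest.approx(numeric, abs=2e-3, rel=0.05), key


class TestTraining:
    def test_noiseless_planted_sar_is_learned(self):
        spec = g.SARSpec(n=300, seed=13, noise_sd=0.0)
        curated, _ = g.build_dataset(g.generate_activity_table(spec))
        split = g.split_dataset(curated, seed=2)
        cfg = g.GCNConfig(conv_size=96, dense_size=96, batch_size=40,
                          learning_rate=1.5e-3, dropout=0.2, seed=3)
        _, trace = g.train(featurized(split.train), featurized(split.valid), cfg)
        idx = trace.epochs.index(trace.selected_epoch)
        assert trace.valid_r2[idx] > 0.9

    def test_training_is_reproducible_for_a_fixed_seed(self, tiny_sets):
        cfg = g.GCNConfig(conv_size=16, dense_size=16, batch_size=50,
                          dropout=0.2, seed=21)
        m1, t1 = g.train_fixed_epochs(tiny_sets["train"], tiny_sets["valid"], cfg, 8)
        m2, t2 = g.train_fixed_epochs(tiny_sets["train"], tiny_sets["valid"], cfg, 8)
        assert t1.valid_mae == t2.valid_mae
        graphs = tiny_sets["test"][0]
        assert np.array_equal(m1.predict(graphs), m2.predict(graphs))

    def test_divergence_aborts_with_diagnostic(self, tiny_sets):
        graphs, y = tiny_sets["train"]
        wild = (graphs, np.full_like(y, 1e25))  # loss overflows float32
        cfg = g.GCNConfig(conv_size=16, dense_size=16, seed=0)
        with pytest.raises(TrainingDiverged, match="non-finite"):
            g.train_fixed_epochs(wild, tiny_sets["valid"], cfg, 3)

    def test_model_roundtrips_through_its_file_format(self, tiny_sets, tmp_path):
        cfg = g.GCNConfig(conv_size=16, dense_size=16, seed=2)
        model, _ = g.train_fixed_epochs(tiny_sets["train"], tiny_sets["valid"], cfg, 5)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = g.GCNModel.load(path)
        graphs = tiny_sets["test"][0]
        assert np.array_equal(model.predict(graphs), loaded.predict(graphs))
        assert loaded.config == cfg


def test_noise_floor_is_approached_as_data_grows():
    """With noise sd 0.3, test MAE should come within 50% of the Gaussian
    noise floor sigma*sqrt(2/pi) at n=1000, improving on n=150."""
    results = {}
    for n in (150, 1000):
        spec = g.SARSpec(n=n, seed=31, noise_sd=0.3)
        curated, _ = g.build_dataset(g.generate_activity_table(spec))
        split = g.split_dataset(curated, seed=8)
        cfg = g.GCNConfig(conv_size=96, dense_size=96, batch_size=50,
                          learning_rate=1.5e-3, dropout=0.25, seed=4)
        model, _ = g.train(featurized(split.train), featurized(split.valid), cfg)
        graphs, y = featurized(split.test)
        results[n] = g.compute_mae(y, model.predict(graphs))
    floor = 0.3 * np.sqrt(2 / np.pi)
    assert results[1000] < 1.5 * floor
    assert results[1000] < results[150] + 0.05
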
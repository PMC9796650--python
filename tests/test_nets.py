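"""Predictor architectures: conversions, forward contracts, equivariances,
training determinism, and checkpoint round-trips."""

import numpy as np
import pytest

from resqa import graphbuild, nn
from resqa.graphbuild import ProteinGraph
from resqa.nets import (LawNet, LawRegressor, Mass2Net, Mass2Regressor,
                        deviation_to_s, s_to_deviation)


class TestConversions:
    def test_d0_equals_deviation_gives_half(self):
        assert deviation_to_s(5.0, d0=5.0) == pytest.approx(0.5)
        assert deviation_to_s(3.0, d0=3.0) == pytest.approx(0.5)

    def test_zero_deviation_gives_one(self):
        assert deviation_to_s(0.0, d0=5.0) == 1.0

    def test_s_half_converts_to_three_angstroms(self):
        assert s_to_deviation(0.5, d0=3.0) == pytest.approx(3.0)

    @pytest.mark.parametrize("d0", [3.0, 5.0])
    def test_roundtrip_exact(self, d0):
        rng = np.random.default_rng(0)
        d = rng.uniform(0.0, 25.0, size=1000)
        back = s_to_deviation(deviation_to_s(d, d0), d0)
        assert np.max(np.abs(back - d)) < 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            s_to_deviation(0.0)
        with pytest.raises(ValueError):
            s_to_deviation(1.5)
        with pytest.raises(ValueError):
            deviation_to_s(-1.0)


def _random_graph(L=12, seed=0, dv=7, du=6):
    rng = np.random.default_rng(seed)
    coords = np.cumsum(3.8 * rng.normal(size=(L, 3)) /
                       np.linalg.norm(rng.normal(size=(L, 3)), axis=1,
                                      keepdims=True), axis=0)
    from resqa.structio import ModelStructure
    m = ModelStructure("m", "t", np.arange(1, L + 1), "A" * L, coords)
    return graphbuild.build_graph(m, rng.normal(size=(L, dv)),
                                  rng.normal(size=du))


class TestMass2Net:
    def test_untrained_output_shape_and_range(self):
        rng = np.random.default_rng(0)
        net = Mass2Net(n_features=9, n_neighbors=5, channels=8, kernel=3,
                       dropout=0.0, slope=0.01, rng=rng)
        net.eval()
        L = 14
        out = net(rng.normal(size=(L, 9)), rng.normal(size=(L, 45)),
                  np.ones((L, 5)))
        assert out.shape == (L, 1)
        assert np.all(out.data > 0) and np.all(out.data < 1)

    def test_layer_census(self):
        rng = np.random.default_rng(0)
        net = Mass2Net(n_features=9, n_neighbors=5, channels=8, kernel=3,
                       dropout=0.2, slope=0.01, rng=rng)
        assert net.n_residual_blocks == 24
        convs = [m for m in net.modules() if isinstance(m, nn.Conv1d)]
        # 24 blocks x 2 convs + 3 branch-1 convs + 1 branch-2 entry conv
        assert len(convs) == 24 * 2 + 4
        linears = [m for m in net.modules() if isinstance(m, nn.Linear)]
        assert len(linears) == 1   # the width-1 projection head
        bns = [m for m in net.modules() if isinstance(m, nn.BatchNorm1d)]
        assert len(bns) == 48


class TestLawNet:
    def test_output_shape_and_range(self):
        g = _random_graph(seed=1)
        net = LawNet(7, 3, 6, hidden=16, kernel=3, slope=0.01,
                     rng=np.random.default_rng(0))
        net.eval()
        out = net(g)
        assert out.shape == (g.n_nodes, 1)
        assert np.all(out.data > 0) and np.all(out.data < 1)

    def test_permutation_equivariance(self):
        g = _random_graph(L=15, seed=2)
        net = LawNet(7, 3, 6, hidden=16, kernel=1, slope=0.01,
                     rng=np.random.default_rng(3))
        net.eval()
        out = net(g).data.ravel()
        rng = np.random.default_rng(4)
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        g2 = ProteinGraph(
            node_features=g.node_features[perm],
            edges=np.column_stack([inv[g.edges[:, 0]],
                                   inv[g.edges[:, 1]]]),
            edge_features=g.edge_features,
            global_features=g.global_features)
        out2 = net(g2).data.ravel()
        assert np.max(np.abs(out2 - out[perm])) < 1e-5

    def test_edge_order_invariance(self):
        g = _random_graph(L=12, seed=5)
        net = LawNet(7, 3, 6, hidden=16, kernel=3, slope=0.01,
                     rng=np.random.default_rng(6))
        net.eval()
        out = net(g).data
        rng = np.random.default_rng(7)
        order = rng.permutation(len(g.edges))
        g2 = ProteinGraph(g.node_features, g.edges[order],
                          g.edge_features[order], g.global_features)
        np.testing.assert_allclose(net(g2).data, out, atol=1e-6)

    def test_twin_components_get_identical_outputs(self):
        # two disconnected identical components: per-node outputs must
        # repeat across the copies (kernel 1 keeps the readout per-node)
        g = _random_graph(L=8, seed=8)
        L = g.n_nodes
        twin = ProteinGraph(
            node_features=np.vstack([g.node_features, g.node_features]),
            edges=np.vstack([g.edges, g.edges + L]),
            edge_features=np.vstack([g.edge_features, g.edge_features]),
            global_features=g.global_features)
        net = LawNet(7, 3, 6, hidden=16, kernel=1, slope=0.01,
                     rng=np.random.default_rng(9))
        net.eval()
        out = net(twin).data.ravel()
        np.testing.assert_allclose(out[:L], out[L:], atol=1e-9)


def _tiny_mass2_data(n_models=3, L=20, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for _ in range(n_models):
        per = rng.normal(size=(L, 9))
        nc = rng.normal(size=(L, 45))
        mask = np.ones((L, 5))
        dev = rng.uniform(0, 10, size=L)
        X.append((per, nc, mask))
        y.append(dev)
    return X, y


class TestTraining:
    def test_same_seed_identical_loss_curves(self):
        X, y = _tiny_mass2_data()
        kw = dict(channels=6, max_epochs=4, random_state=11,
                  stop_train_mse=0.0)
        h1 = Mass2Regressor(**kw).fit(X, y).history_
        h2 = Mass2Regressor(**kw).fit(X, y).history_
        assert h1["train_mse"] == h2["train_mse"]

    def test_nan_target_residues_are_masked(self):
        X, y = _tiny_mass2_data()
        y[0][3] = np.nan
        est = Mass2Regressor(channels=6, max_epochs=2, random_state=0)
        est.fit(X, y)
        assert np.all(np.isfinite(est.history_["train_mse"]))

    def test_predict_shapes_and_positive(self):
        X, y = _tiny_mass2_data()
        est = Mass2Regressor(channels=6, max_epochs=2, random_state=0)
        est.fit(X, y)
        preds = est.predict(X)
        assert [len(p) for p in preds] == [20, 20, 20]
        assert all(np.all(p >= 0) for p in preds)

    def test_checkpoint_roundtrip(self, tmp_path):
        X, y = _tiny_mass2_data()
        est = Mass2Regressor(channels=6, max_epochs=2, random_state=0)
        est.fit(X, y)
        p = tmp_path / "m.npz"
        est.save(p)
        back = Mass2Regressor.load(p)
        np.testing.assert_array_equal(back.predict_s(X)[0],
                                      est.predict_s(X)[0])

    def test_law_fit_predict_smoke(self):
        graphs = [_random_graph(L=10, seed=s, dv=7) for s in range(3)]
        y = [np.random.default_rng(s).uniform(0, 9, size=10)
             for s in range(3)]
        est = LawRegressor(hidden=8, max_epochs=3, random_state=0)
        est.fit(graphs, y)
        preds = est.predict(graphs)
        assert [len(p) for p in preds] == [10, 10, 10]

    def test_mismatched_lengths_error(self):
        X, y = _tiny_mass2_data()
        with pytest.raises(ValueError):
            Mass2Regressor().fit(X, y[:1])
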
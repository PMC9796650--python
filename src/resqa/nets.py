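"""The two residue-specific quality predictors.

``Mass2Regressor`` is a two-branch 1-D residual CNN: one branch convolves
the concatenated features of each residue's five spatially closest
sequence-distant residues, the other convolves the residue's own features
through six residual blocks; the concatenated branches pass through another
18 residual blocks (24 in total) and a width-1 projection.  A sigmoid gives
a per-residue S-score, converted to a deviation in Angstroms via
d = d0 * sqrt(1/S - 1) with d0 = 3.

``LawRegressor`` is a graph network: five blocks of edge / node / global
updates (Linear-ReLU-Linear update functions, scatter-mean aggregations)
over the 8-A residue contact graph, then a three-convolution readout to the
same sigmoid S-score head.

Both are scikit-learn estimators (``fit`` / ``predict`` /
``get_params``) trained with Adam on the mean-squared error between
predicted and true S-scores, batch = one model, with early stopping on a
held-out validation split.  Fixed ``random_state`` gives bitwise-identical
training histories on CPU.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import nn
from .graphbuild import PAD, ProteinGraph

__all__ = ["Mass2Regressor", "LawRegressor", "s_to_deviation",
           "deviation_to_s", "D0_HEAD", "D0_EVAL"]

D0_HEAD = 3.0   # deviation <-> S-score constant of the prediction head
D0_EVAL = 5.0   # constant used by the evaluation metrics


def deviation_to_s(d, d0: float = D0_HEAD):
    """S = 1 / (1 + (d / d0)^2);  S(0) = 1, S(d0) = 0.5."""
    d = np.asarray(d, dtype=float)
    if np.any(d[~np.isnan(d)] < 0):
        raise ValueError("deviations must be >= 0")
    return 1.0 / (1.0 + (d / d0) ** 2)


def s_to_deviation(s, d0: float = D0_HEAD):
    """Inverse transform d = d0 * sqrt(1/S - 1); requires S in (0, 1]."""
    s = np.asarray(s, dtype=float)
    valid = s[~np.isnan(s)]
    if np.any(valid <= 0) or np.any(valid > 1):
        raise ValueError("S-scores must be in (0, 1]")
    return d0 * np.sqrt(1.0 / s - 1.0)


# ---------------------------------------------------------------------------
# network definitions
# ---------------------------------------------------------------------------

class _ConvLReLU(nn.Module):
    def __init__(self, n_in, n_out, kernel, slope, rng):
        super().__init__()
        self.conv = nn.Conv1d(n_in, n_out, kernel, rng)
        self.act = nn.LeakyReLU(slope)

    def __call__(self, x):
        return self.act(self.conv(x))


class Mass2Net(nn.Module):
    """Two-branch residual CNN; see module docstring."""

    def __init__(self, n_features: int, n_neighbors: int, channels: int,
                 kernel: int, dropout: float, slope: float,
                 rng: np.random.Generator):
        super().__init__()
        self.n_features = n_features
        self.n_neighbors = n_neighbors
        nb_in = n_neighbors * n_features + n_neighbors  # + presence mask
        self.branch1 = [
            _ConvLReLU(nb_in, channels, kernel, slope, rng),
            _ConvLReLU(channels, channels, kernel, slope, rng),
            _ConvLReLU(channels, channels, kernel, slope, rng),
        ]
        self.branch2_conv = _ConvLReLU(n_features, channels, kernel, slope,
                                       rng)
        self.branch2_blocks = [
            nn.ResidualBlock(channels, kernel, dropout, slope, rng)
            for _ in range(6)]
        self.trunk_blocks = [
            nn.ResidualBlock(2 * channels, kernel, dropout, slope, rng)
            for _ in range(18)]
        self.head = nn.Linear(2 * channels, 1, rng)

    @property
    def n_residual_blocks(self) -> int:
        return len(self.branch2_blocks) + len(self.trunk_blocks)

    def __call__(self, per_residue, neighbor_concat, neighbor_mask):
        b1 = nn.concat([nn.Tensor(neighbor_concat),
                        nn.Tensor(neighbor_mask)], axis=1)
        for layer in self.branch1:
            b1 = layer(b1)
        b2 = self.branch2_conv(nn.Tensor(per_residue))
        for block in self.branch2_blocks:
            b2 = block(b2)
        h = nn.concat([b1, b2], axis=1)
        for block in self.trunk_blocks:
            h = block(h)
        return self.head(h).sigmoid()


class GraphBlock(nn.Module):
    """One edge/node/global update round of the graph network."""

    def __init__(self, dv, de, du, hidden, rng):
        super().__init__()
        self.phi_e = nn.MLP2(2 * dv + de + du, hidden, hidden, rng)
        self.phi_se = nn.MLP2(dv + hidden, hidden, hidden, rng)
        self.phi_v = nn.MLP2(dv + hidden + du, hidden, hidden, rng)
        self.phi_u = nn.MLP2(2 * hidden + du, hidden, hidden, rng)

    def __call__(self, v, e, u, senders, receivers, n_nodes):
        u_edge = nn.gather(u, np.zeros(len(senders), dtype=int))
        u_node = nn.gather(u, np.zeros(n_nodes, dtype=int))
        # step 1: edge update on [sender, receiver, edge, global]
        e_new = self.phi_e(nn.concat(
            [nn.gather(v, senders), nn.gather(v, receivers), e, u_edge]))
        # step 2: message from [sender, edge], mean over receivers, node
        # update on [node, aggregate, global]
        msg = self.phi_se(nn.concat([nn.gather(v, senders), e_new]))
        agg = nn.segment_mean(msg, receivers, n_nodes)
        v_new = self.phi_v(nn.concat([v, agg, u_node]))
        # step 3: global update on [mean edges, mean nodes, global]
        u_new = self.phi_u(nn.concat(
            [e_new.mean_axis0(), v_new.mean_axis0(), u]))
        return v_new, e_new, u_new


class LawNet(nn.Module):
    def __init__(self, dv: int, de: int, du: int, hidden: int, kernel: int,
                 slope: float, rng: np.random.Generator):
        super().__init__()
        self.blocks = [GraphBlock(dv, de, du, hidden, rng)]
        for _ in range(4):
            self.blocks.append(GraphBlock(hidden, hidden, hidden, hidden,
                                          rng))
        self.readout = [
            _ConvLReLU(3 * hidden, hidden, kernel, slope, rng),
            _ConvLReLU(hidden, hidden // 4, kernel, slope, rng),
        ]
        self.readout_final = nn.Conv1d(hidden // 4, 1, kernel, rng)

    def __call__(self, graph: ProteinGraph):
        senders = graph.edges[:, 0]
        receivers = graph.edges[:, 1]
        n = graph.n_nodes
        v = nn.Tensor(graph.node_features)
        e = nn.Tensor(graph.edge_features)
        u = nn.Tensor(graph.global_features.reshape(1, -1))
        for block in self.blocks:
            v, e, u = block(v, e, u, senders, receivers, n)
        agg = nn.segment_mean(e, receivers, n)
        u_node = nn.gather(u, np.zeros(n, dtype=int))
        h = nn.concat([agg, v, u_node])
        for layer in self.readout:
            h = layer(h)
        return self.readout_final(h).sigmoid()


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class _QaRegressorBase(BaseEstimator, RegressorMixin):
    """Shared training loop: Adam on S-score MSE, batch = one model."""

    def _forward(self, item, training: bool):
        raise NotImplementedError

    def _build_net(self, X, rng):
        raise NotImplementedError

    def _fit_loop(self, X, y) -> "._QaRegressorBase":
        if len(X) < 1:
            raise ValueError("need at least one training model")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        rng = np.random.default_rng(self.random_state)
        self.net_ = self._build_net(X, rng)
        drop_rng = np.random.default_rng(
            np.random.default_rng(self.random_state).integers(2 ** 31))
        for m in self.net_.modules():
            if isinstance(m, nn.Dropout):
                m.rng = drop_rng

        targets = []
        masks = []
        for dev in y:
            dev = np.asarray(dev, dtype=float)
            mask = np.isfinite(dev)
            t = np.zeros_like(dev)
            t[mask] = deviation_to_s(dev[mask], self.d0)
            targets.append(t[:, None])
            masks.append(mask.astype(float)[:, None])

        n = len(X)
        idx = rng.permutation(n)
        n_val = int(round(self.validation_fraction * n))
        n_val = min(n_val, n - 1)
        val_idx, train_idx = idx[:n_val], idx[n_val:]

        opt = nn.Adam(self.net_.parameters(), lr=self.learning_rate)
        history = {"train_mse": [], "val_mse": []}
        best_val = np.inf
        best_state = None
        patience_left = self.patience
        for epoch in range(self.max_epochs):
            self.net_.train()
            order = rng.permutation(len(train_idx))
            losses = []
            for j in train_idx[order]:
                opt.zero_grad()
                pred = self._forward(X[j], training=True)
                if not np.all(np.isfinite(pred.data)):
                    raise FloatingPointError(
                        "non-finite activation in network output")
                m = nn.Tensor(masks[j])
                diff = (pred - nn.Tensor(targets[j])) * m
                denom = max(float(masks[j].sum()), 1.0)
                loss = (diff * diff).sum() * (1.0 / denom)
                if not np.isfinite(loss.data):
                    raise FloatingPointError("NaN training loss")
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            # fit quality is reported without dropout noise: eval-mode MSE
            # over the training models at epoch end
            train_mse = self._score_mse(
                [X[j] for j in train_idx], [targets[j] for j in train_idx],
                [masks[j] for j in train_idx])
            history["train_mse"].append(train_mse)

            if len(val_idx):
                val_mse = self._score_mse(
                    [X[j] for j in val_idx], [targets[j] for j in val_idx],
                    [masks[j] for j in val_idx])
            else:
                val_mse = train_mse
            history["val_mse"].append(val_mse)
            if val_mse < best_val - 1e-9:
                best_val = val_mse
                best_state = [a.copy() for a in self.net_.state_arrays()]
                patience_left = self.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
            if train_mse < self.stop_train_mse:
                best_state = [a.copy() for a in self.net_.state_arrays()]
                break
        if best_state is not None:
            self.net_.load_state_arrays(best_state)
        self.net_.eval()
        self.history_ = history
        self.n_epochs_ = len(history["train_mse"])
        return self

    def _score_mse(self, X, targets, masks) -> float:
        self.net_.eval()
        num, den = 0.0, 0.0
        for item, t, m in zip(X, targets, masks):
            pred = self._forward(item, training=False).data
            num += float((((pred - t) * m) ** 2).sum())
            den += float(m.sum())
        return num / max(den, 1.0)

    def predict_s(self, X) -> list[np.ndarray]:
        """Per-residue predicted S-scores, one array per model."""
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        self.net_.eval()
        return [self._forward(item, training=False).data.ravel()
                for item in X]

    def predict(self, X) -> list[np.ndarray]:
        """Per-residue predicted deviations in Angstroms."""
        return [s_to_deviation(np.clip(s, 1e-6, 1.0), self.d0)
                for s in self.predict_s(X)]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.net_.parameters()))

    # -- checkpointing ------------------------------------------------------

    FORMAT_VERSION = 1

    def save(self, path) -> None:
        arrays = {f"arr_{i}": a
                  for i, a in enumerate(self.net_.state_arrays())}
        meta = json.dumps({"params": self.get_params(),
                           "class": type(self).__name__,
                           "build": self._build_meta_,
                           "format_version": self.FORMAT_VERSION})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "_QaRegressorBase":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            est = cls(**meta["params"])
            est._build_meta_ = meta["build"]
            rng = np.random.default_rng(est.random_state)
            est.net_ = est._build_net_from_meta(meta["build"], rng)
            n = len([k for k in z.files if k.startswith("arr_")])
            est.net_.load_state_arrays(
                [z[f"arr_{i}"] for i in range(n)])
        est.net_.eval()
        est.history_ = {"train_mse": [], "val_mse": []}
        return est


class Mass2Regressor(_QaRegressorBase):
    """Residual-CNN predictor of per-residue deviations.

    Parameters
    ----------
    channels : conv channels per branch (the trunk runs at 2x).
    kernel : odd convolution width.
    dropout, leaky_slope : regularisation / activation settings of every
        residual block.
    d0 : S-score constant of the head (3 A).
    learning_rate, max_epochs, patience, validation_fraction,
    stop_train_mse : Adam/early-stopping controls.
    random_state : seed for init, shuffling and dropout.

    ``fit(X, y)`` takes X = sequence of (per_residue (L, 83),
    neighbor_concat (L, 5*83)[, neighbor_mask (L, 5)]) tuples and
    y = matching per-residue true deviations in Angstroms (NaN = residue
    missing from the reference, excluded from the loss).
    """

    def __init__(self, channels: int = 32, kernel: int = 3,
                 dropout: float = 0.2, leaky_slope: float = 0.01,
                 d0: float = D0_HEAD, learning_rate: float = 1e-3,
                 max_epochs: int = 300, patience: int = 50,
                 validation_fraction: float = 0.0,
                 stop_train_mse: float = 0.008,
                 random_state: Optional[int] = 0):
        self.channels = channels
        self.kernel = kernel
        self.dropout = dropout
        self.leaky_slope = leaky_slope
        self.d0 = d0
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.stop_train_mse = stop_train_mse
        self.random_state = random_state

    @staticmethod
    def _unpack(item):
        if len(item) == 3:
            per_residue, nc, mask = item
        else:
            per_residue, nc = item
            mask = None
        per_residue = np.asarray(per_residue, dtype=float)
        nc = np.asarray(nc, dtype=float)
        L, D = per_residue.shape
        if nc.shape[0] != L:
            raise ValueError("per-residue and neighbour inputs disagree on L")
        k = nc.shape[1] // D
        if mask is None:
            mask = (np.abs(nc.reshape(L, k, D)).sum(axis=2) > 0).astype(float)
        return per_residue, nc, np.asarray(mask, dtype=float)

    def _build_net(self, X, rng):
        per_residue, nc, mask = self._unpack(X[0])
        n_feat = per_residue.shape[1]
        n_nb = mask.shape[1]
        self.n_features_in_ = n_feat
        self._build_meta_ = {"n_features": n_feat, "n_neighbors": n_nb}
        return Mass2Net(n_feat, n_nb, self.channels, self.kernel,
                        self.dropout, self.leaky_slope, rng)

    def _build_net_from_meta(self, meta, rng):
        self.n_features_in_ = meta["n_features"]
        return Mass2Net(meta["n_features"], meta["n_neighbors"],
                        self.channels, self.kernel, self.dropout,
                        self.leaky_slope, rng)

    def _forward(self, item, training: bool):
        per_residue, nc, mask = self._unpack(item)
        if training:
            self.net_.train()
        else:
            self.net_.eval()
        return self.net_(per_residue, nc, mask)

    def fit(self, X, y):
        return self._fit_loop(list(X), list(y))


class LawRegressor(_QaRegressorBase):
    """Graph-network predictor of per-residue deviations.

    ``fit(X, y)`` takes X = sequence of ``ProteinGraph`` and y = matching
    per-residue true deviations (NaN excluded from the loss).  See
    ``Mass2Regressor`` for the shared training controls.
    """

    def __init__(self, hidden: int = 64, kernel: int = 3,
                 leaky_slope: float = 0.01, d0: float = D0_HEAD,
                 learning_rate: float = 1e-3, max_epochs: int = 300,
                 patience: int = 50, validation_fraction: float = 0.0,
                 stop_train_mse: float = 0.008,
                 random_state: Optional[int] = 0):
        self.hidden = hidden
        self.kernel = kernel
        self.leaky_slope = leaky_slope
        self.d0 = d0
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.stop_train_mse = stop_train_mse
        self.random_state = random_state

    def _build_net(self, X, rng):
        g: ProteinGraph = X[0]
        dv = g.node_features.shape[1]
        de = g.edge_features.shape[1]
        du = g.global_features.size
        self.n_features_in_ = dv
        self._build_meta_ = {"dv": dv, "de": de, "du": du}
        return LawNet(dv, de, du, self.hidden, self.kernel,
                      self.leaky_slope, rng)

    def _build_net_from_meta(self, meta, rng):
        self.n_features_in_ = meta["dv"]
        return LawNet(meta["dv"], meta["de"], meta["du"], self.hidden,
                      self.kernel, self.leaky_slope, rng)

    def _forward(self, graph: ProteinGraph, training: bool):
        if training:
            self.net_.train()
        else:
            self.net_.eval()
        return self.net_(graph)

    def fit(self, X, y):
        return self._fit_loop(list(X), list(y))
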
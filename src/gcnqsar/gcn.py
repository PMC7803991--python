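"""Graph-convolutional regression network for pIC50 prediction.

Architecture (conv → pool, repeated L times, then dense → gather → linear):

* **graph convolution** — each atom's state is updated from its own state
  and the sum of its bonded neighbours' states,
  ``h'_v = ReLU(BatchNorm(W_self·h_v + Σ_{u∈N(v)} W_nbr·h_u + b))``;
* **graph pooling** — elementwise maximum over the closed neighbourhood
  ``{v} ∪ N(v)``;
* **dense** — a linear layer applied atomwise;
* **graph gathering** — the per-atom dense outputs are summed per molecule
  and passed through tanh, yielding the molecule's "neural fingerprint";
* **output** — a single linear neuron on the fingerprint.

Training minimizes mean-squared error with Adam.  Two regimes are
provided: a fixed-epoch regime (used when the epoch count is itself a
hyperparameter under search) and a block regime used for final model
fitting — epochs run in blocks of 100, training stops when the running
minimum validation MAE fails to decrease during a block, and the final
weights are the snapshot from the epoch with the maximum validation
2R2_MAE = (R² − MAE) + R².

Everything is implemented on NumPy/scipy.sparse in float32; mini-batches
are formed once from a seeded shuffle and their *order* is reshuffled each
epoch, so per-batch graph structures (adjacency, pooling and gathering
indices) are precomputed.  With dropout fixed and the same seed, training
is reproducible run-to-run on the same platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numba
import numpy as np
import scipy.sparse as sp

from .featurize import MolecularGraph, N_ATOM_FEATURES

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class GCNConfig:
    """Hyperparameters of one network (values live inside the search ranges)."""

    n_conv_layers: int = 1
    conv_size: int = 64
    dense_size: int = 64
    learning_rate: float = 1e-3
    dropout: float = 0.0
    batch_size: int = 50
    max_epoch_block: int = 100  # block length for the stopping rule
    seed: int = 0

    def validate(self) -> None:
        if self.n_conv_layers not in (1, 2, 3, 4):
            raise ValueError("n_conv_layers must be 1..4")
        if not (0.0 <= self.dropout <= 0.5):
            raise ValueError("dropout must lie in [0, 0.5]")
        for name in ("conv_size", "dense_size", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainingTrace:
    """Per-epoch validation metrics plus the stopping and selected epochs."""

    epochs: list = field(default_factory=list)  # 1-based epoch indices
    valid_mae: list = field(default_factory=list)
    valid_r2: list = field(default_factory=list)
    valid_trmae: list = field(default_factory=list)
    stopping_epoch: int = 0
    selected_epoch: int = 0

    def append(self, epoch: int, mae: float, r2: float, trmae: float) -> None:
        self.epochs.append(epoch)
        self.valid_mae.append(mae)
        self.valid_r2.append(r2)
        self.valid_trmae.append(trmae)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "mae": self.valid_mae,
                "r2": self.valid_r2,
                "trmae": self.valid_trmae,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def select_final_epoch(trace: TrainingTrace) -> int:
    """Epoch with the maximum validation 2R2_MAE; ties go to the earliest."""
    if not trace.epochs:
        raise ValueError("empty training trace")
    return trace.epochs[int(np.argmax(trace.valid_trmae))]


# ---------------------------------------------------------------------------
# Batched graph structures
# ---------------------------------------------------------------------------

class GraphBatch:
    """Concatenated atom matrices and index structures for a molecule batch.

    Atoms of each molecule occupy a contiguous index range, so the gather
    (per-molecule sum) is a ``reduceat`` over molecule offsets and the
    closed-neighbourhood max-pool is a ``reduceat`` over a flattened,
    atom-grouped membership list.
    """

    __slots__ = (
        "n_mols", "n_atoms", "X", "adj", "pool_idx", "pool_off",
        "mol_off", "mol_index", "y",
    )

    def __init__(self, graphs: list[MolecularGraph], y=None):
        sizes = [g.n_atoms for g in graphs]
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        A = int(offsets[-1])
        self.n_mols = len(graphs)
        self.n_atoms = A
        self.X = np.concatenate([g.atom_feats for g in graphs]).astype(np.float32)

        src, dst, pool_idx, pool_off = [], [], [], []
        pos = 0
        for g, off in zip(graphs, offsets):
            for v, nb in enumerate(g.neighbors):
                dst.extend([off + v] * len(nb))
                src.extend(off + u for u in nb)
                pool_off.append(pos)
                pool_idx.append(off + v)  # closed neighbourhood: self first
                pool_idx.extend(off + u for u in nb)
                pos += 1 + len(nb)
        src = np.asarray(src, dtype=np.int64)
        dst = np.asarray(dst, dtype=np.int64)
        # both bond directions are present, so the adjacency is symmetric
        self.adj = sp.csr_matrix(
            (np.ones(len(src), dtype=np.float32), (dst, src)), shape=(A, A)
        )
        self.pool_idx = np.asarray(pool_idx, dtype=np.int64)
        self.pool_off = np.asarray(pool_off + [pos], dtype=np.int64)  # +sentinel
        self.mol_off = np.asarray(
            list(offsets[:-1]) + [A], dtype=np.int64
        )  # +sentinel
        self.mol_index = np.repeat(np.arange(self.n_mols), sizes)
        self.y = None if y is None else np.asarray(y, dtype=np.float32)


@numba.njit(cache=True)
def _pool_fwd_kernel(H, pool_idx, pool_off):
    n_grp = pool_off.shape[0] - 1
    C = H.shape[1]
    P = np.empty((n_grp, C), dtype=H.dtype)
    amax = np.empty((n_grp, C), dtype=np.int64)
    for v in range(n_grp):
        first = pool_idx[pool_off[v]]
        for c in range(C):
            P[v, c] = H[first, c]
            amax[v, c] = first
        for j in range(pool_off[v] + 1, pool_off[v + 1]):
            u = pool_idx[j]
            for c in range(C):
                if H[u, c] > P[v, c]:
                    P[v, c] = H[u, c]
                    amax[v, c] = u
    return P, amax


@numba.njit(cache=True)
def _pool_bwd_kernel(gP, amax, n_atoms):
    # subgradient of the per-group max routed to the (first) argmax entry
    C = gP.shape[1]
    gH = np.zeros((n_atoms, C), dtype=gP.dtype)
    for v in range(gP.shape[0]):
        for c in range(C):
            gH[amax[v, c], c] += gP[v, c]
    return gH


@numba.njit(cache=True)
def _segment_sum_kernel(D, mol_off):
    n_mol = mol_off.shape[0] - 1
    C = D.shape[1]
    S = np.zeros((n_mol, C), dtype=D.dtype)
    for m in range(n_mol):
        for a in range(mol_off[m], mol_off[m + 1]):
            for c in range(C):
                S[m, c] += D[a, c]
    return S


def _pool_forward(batch: GraphBatch, H: np.ndarray):
    return _pool_fwd_kernel(H, batch.pool_idx, batch.pool_off)


def _pool_backward(batch: GraphBatch, amax: np.ndarray, gP: np.ndarray):
    return _pool_bwd_kernel(gP, amax, batch.n_atoms)


def _gather_forward(batch: GraphBatch, D: np.ndarray):
    return _segment_sum_kernel(D, batch.mol_off)


@numba.njit(cache=True)
def _bn_stats_kernel(Z):
    """Per-feature batch mean and 1/std of Z (eps 1e-5).

    Two-pass variance: the single-pass E[z²]−E[z]² form cancels
    catastrophically in float32 once activations drift off-centre.
    """
    m, C = Z.shape
    mu = np.zeros(C, dtype=Z.dtype)
    for i in range(m):
        for c in range(C):
            mu[c] += Z[i, c]
    for c in range(C):
        mu[c] /= m
    var = np.zeros(C, dtype=Z.dtype)
    for i in range(m):
        for c in range(C):
            d = Z[i, c] - mu[c]
            var[c] += d * d
    invstd = np.empty(C, dtype=Z.dtype)
    for c in range(C):
        invstd[c] = 1.0 / np.sqrt(var[c] / m + 1e-5)
    return mu, invstd


@numba.njit(cache=True)
def _bn_relu_fwd_kernel(Z, mu, invstd, gamma, beta):
    """Batch-norm (given statistics) followed by ReLU; returns (xhat, out)."""
    m, C = Z.shape
    xhat = np.empty_like(Z)
    out = np.empty_like(Z)
    for i in range(m):
        for c in range(C):
            x = (Z[i, c] - mu[c]) * invstd[c]
            xhat[i, c] = x
            b = gamma[c] * x + beta[c]
            out[i, c] = b if b > 0.0 else 0.0
    return xhat, out


@numba.njit(cache=True)
def _bn_relu_bwd_kernel(gOut, xhat, invstd, gamma, beta):
    """Backward of batch-norm → ReLU; the ReLU gate is recomputed from xhat.

    Returns (gZ, dgamma, dbeta).
    """
    m, C = gOut.shape
    gZ = np.empty_like(gOut)
    dgamma = np.zeros(C, dtype=gOut.dtype)
    dbeta = np.zeros(C, dtype=gOut.dtype)
    s1 = np.zeros(C, dtype=gOut.dtype)
    s2 = np.zeros(C, dtype=gOut.dtype)
    for i in range(m):
        for c in range(C):
            x = xhat[i, c]
            g = gOut[i, c]
            if gamma[c] * x + beta[c] <= 0.0:
                g = 0.0
            dgamma[c] += g * x
            dbeta[c] += g
            gx = g * gamma[c]
            gZ[i, c] = gx
            s1[c] += gx
            s2[c] += gx * x
    for i in range(m):
        for c in range(C):
            gZ[i, c] = (invstd[c] / m) * (m * gZ[i, c] - s1[c] - xhat[i, c] * s2[c])
    return gZ, dgamma, dbeta


@numba.njit(cache=True)
def _adam_kernel(p, m, v, g, lr, b1, b2, eps, bc1, bc2):
    for i in range(p.shape[0]):
        m[i] = b1 * m[i] + (1.0 - b1) * g[i]
        v[i] = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
        p[i] -= lr * (m[i] / bc1) / (np.sqrt(v[i] / bc2) + eps)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def _glorot(rng, n_in, n_out):
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out)).astype(np.float32)


def init_params(config: GCNConfig, rng: np.random.Generator):
    params, running = {}, {}
    d_in = N_ATOM_FEATURES
    for layer in range(config.n_conv_layers):
        c = config.conv_size
        params[f"conv{layer}_wself"] = _glorot(rng, d_in, c)
        params[f"conv{layer}_wnbr"] = _glorot(rng, d_in, c)
        params[f"conv{layer}_b"] = np.zeros(c, dtype=np.float32)
        params[f"conv{layer}_gamma"] = np.ones(c, dtype=np.float32)
        params[f"conv{layer}_beta"] = np.zeros(c, dtype=np.float32)
        running[f"conv{layer}_mean"] = np.zeros(c, dtype=np.float32)
        running[f"conv{layer}_var"] = np.ones(c, dtype=np.float32)
        d_in = c
    params["dense_w"] = _glorot(rng, d_in, config.dense_size)
    params["dense_b"] = np.zeros(config.dense_size, dtype=np.float32)
    params["out_w"] = _glorot(rng, config.dense_size, 1)
    params["out_b"] = np.zeros(1, dtype=np.float32)
    return params, running


def _copy_state(params, running):
    return (
        {k: v.copy() for k, v in params.items()},
        {k: v.copy() for k, v in running.items()},
    )


# ---------------------------------------------------------------------------
# Forward / backward
# ---------------------------------------------------------------------------

def _forward(params, running, batch: GraphBatch, config: GCNConfig,
             training: bool, rng: np.random.Generator | None = None):
    """Forward pass; in training mode returns a cache for backprop."""
    cache = {"layers": []} if training else None
    H = batch.X
    p_drop = config.dropout if training else 0.0
    for layer in range(config.n_conv_layers):
        N = batch.adj @ H
        Z = H @ params[f"conv{layer}_wself"] + N @ params[f"conv{layer}_wnbr"]
        Z += params[f"conv{layer}_b"]
        if training:
            mu, invstd = _bn_stats_kernel(Z)
            xhat, Dp = _bn_relu_fwd_kernel(
                Z, mu, invstd,
                params[f"conv{layer}_gamma"], params[f"conv{layer}_beta"],
            )
            if p_drop > 0.0:
                mask = (rng.random(Z.shape, dtype=np.float32) >= p_drop).astype(
                    np.float32
                )
                mask *= np.float32(1.0 / (1.0 - p_drop))
                Dp = Dp * mask
            else:
                mask = None
            var = 1.0 / (invstd * invstd) - _BN_EPS
            running[f"conv{layer}_mean"] *= _BN_MOMENTUM
            running[f"conv{layer}_mean"] += (1 - _BN_MOMENTUM) * mu
            running[f"conv{layer}_var"] *= _BN_MOMENTUM
            running[f"conv{layer}_var"] += (1 - _BN_MOMENTUM) * var
        else:
            invstd = 1.0 / np.sqrt(running[f"conv{layer}_var"] + _BN_EPS)
            xhat = (Z - running[f"conv{layer}_mean"]) * invstd
            Dp = np.maximum(
                xhat * params[f"conv{layer}_gamma"] + params[f"conv{layer}_beta"], 0.0
            )
            mask = None
        P, amax = _pool_forward(batch, np.ascontiguousarray(Dp))
        if training:
            cache["layers"].append(
                {"H": H, "N": N, "xhat": xhat, "invstd": invstd,
                 "mask": mask, "amax": amax}
            )
        H = P
    D = H @ params["dense_w"] + params["dense_b"]
    if p_drop > 0.0:
        dmask = (rng.random(D.shape, dtype=np.float32) >= p_drop).astype(np.float32)
        dmask *= np.float32(1.0 / (1.0 - p_drop))
        D *= dmask
    else:
        dmask = None
    S = _gather_forward(batch, np.ascontiguousarray(D))
    fp = np.tanh(S)
    pred = (fp @ params["out_w"])[:, 0] + params["out_b"][0]
    if training:
        cache.update({"H_last": H, "D": D, "dmask": dmask, "fp": fp})
    return pred, cache


def _backward(params, batch: GraphBatch, config: GCNConfig, cache, gpred):
    grads = {}
    fp = cache["fp"]
    grads["out_b"] = np.array([gpred.sum()], dtype=np.float32)
    grads["out_w"] = (fp.T @ gpred)[:, None].astype(np.float32)
    gfp = gpred[:, None] * params["out_w"][:, 0]
    gS = gfp * (1.0 - fp * fp)
    gD = gS[batch.mol_index]
    if cache["dmask"] is not None:
        gD *= cache["dmask"]
    grads["dense_w"] = cache["H_last"].T @ gD
    grads["dense_b"] = gD.sum(axis=0)
    gH = gD @ params["dense_w"].T
    for layer in range(config.n_conv_layers - 1, -1, -1):
        lc = cache["layers"][layer]
        gDp = _pool_backward(batch, lc["amax"], np.ascontiguousarray(gH))
        if lc["mask"] is not None:
            gDp *= lc["mask"]
        gZ, dgamma, dbeta = _bn_relu_bwd_kernel(
            gDp, lc["xhat"], lc["invstd"],
            params[f"conv{layer}_gamma"], params[f"conv{layer}_beta"],
        )
        grads[f"conv{layer}_gamma"] = dgamma
        grads[f"conv{layer}_beta"] = dbeta
        grads[f"conv{layer}_wself"] = lc["H"].T @ gZ
        grads[f"conv{layer}_wnbr"] = lc["N"].T @ gZ
        grads[f"conv{layer}_b"] = gZ.sum(axis=0)
        gH = gZ @ params[f"conv{layer}_wself"].T + batch.adj @ (
            gZ @ params[f"conv{layer}_wnbr"].T
        )  # adjacency is symmetric
    return grads


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            _adam_kernel(
                params[k].reshape(-1), self.m[k].reshape(-1), self.v[k].reshape(-1),
                np.ascontiguousarray(g, dtype=np.float32).reshape(-1),
                self.lr, self.b1, self.b2, self.eps, bc1, bc2,
            )


# ---------------------------------------------------------------------------
# Model wrapper
# ---------------------------------------------------------------------------

class GCNModel:
    """Trained network state plus its configuration."""

    def __init__(self, params, running, config: GCNConfig):
        self.params = params
        self.running = running
        self.config = config

    def predict_batch(self, batch: GraphBatch) -> np.ndarray:
        pred, _ = _forward(self.params, self.running, batch, self.config, training=False)
        return pred.astype(np.float64)

    def predict(self, graphs: list[MolecularGraph], batch_size: int = 1024) -> np.ndarray:
        out = []
        for i in range(0, len(graphs), batch_size):
            out.append(self.predict_batch(GraphBatch(graphs[i : i + batch_size])))
        return np.concatenate(out) if out else np.empty(0)

    # -- serialization: one portable .npz with a versioned header ----------
    def save(self, path) -> None:
        arrays = {f"p__{k}": v for k, v in self.params.items()}
        arrays.update({f"r__{k}": v for k, v in self.running.items()})
        np.savez(
            path,
            format_version=np.array([1]),
            config_json=np.frombuffer(
                json.dumps(asdict(self.config)).encode(), dtype=np.uint8
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "GCNModel":
        data = np.load(path if str(path).endswith(".npz") else str(path))
        if int(data["format_version"][0]) != 1:
            raise ValueError("unsupported model file version")
        config = GCNConfig(**json.loads(bytes(data["config_json"]).decode()))
        params = {k[3:]: data[k] for k in data.files if k.startswith("p__")}
        running = {k[3:]: data[k] for k in data.files if k.startswith("r__")}
        return cls(params, running, config)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _metrics(y, f):
    # validation MAE / R² / 2R2_MAE (same formulas as the metrics module)
    d = f - y
    mae = float(np.mean(np.abs(d)))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(d * d)) / tss if tss > 0 else float("nan")
    return mae, r2, (r2 - mae) + r2


def _make_batches(graphs, y, batch_size, rng):
    n = len(graphs)
    order = rng.permutation(n)
    batches = []
    for i in range(0, n, batch_size):
        take = order[i : i + batch_size]
        batches.append(GraphBatch([graphs[j] for j in take], np.asarray(y)[take]))
    return batches


def _train_loop(train_graphs, y_train, valid_graphs, y_valid, config: GCNConfig,
                n_epochs: int | None, max_blocks: int | None):
    config.validate()
    rng = np.random.default_rng(config.seed)
    params, running = init_params(config, rng)
    batches = _make_batches(train_graphs, y_train, min(config.batch_size, len(train_graphs)), rng)
    vbatch = GraphBatch(valid_graphs, y_valid)
    adam = _Adam(params, config.learning_rate)
    trace = TrainingTrace()

    block = config.max_epoch_block
    best = {"trmae": -np.inf, "state": None, "epoch": 0}
    global_min_mae = np.inf
    epoch = 0

    def run_epoch(evaluate=True):
        nonlocal epoch
        epoch += 1
        for bi in rng.permutation(len(batches)):
            b = batches[bi]
            pred, cache = _forward(params, running, b, config, training=True, rng=rng)
            resid = pred - b.y
            loss = float(np.mean(resid * resid))
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch} with config {config}"
                )
            gpred = (2.0 / len(resid)) * resid.astype(np.float32)
            grads = _backward(params, b, config, cache, gpred)
            adam.step(params, grads)
        if not evaluate:
            return None
        vpred, _ = _forward(params, running, vbatch, config, training=False)
        mae, r2, trmae = _metrics(vbatch.y.astype(np.float64), vpred)
        trace.append(epoch, mae, r2, trmae)
        if trmae > best["trmae"]:
            best.update(trmae=trmae, state=_copy_state(params, running), epoch=epoch)
        return mae

    if n_epochs is not None:
        # fixed-epoch (search) regime: only the final epoch is scored
        for e in range(n_epochs):
            run_epoch(evaluate=(e == n_epochs - 1))
        trace.stopping_epoch = epoch
        trace.selected_epoch = epoch  # the epoch count is the hyperparameter
        model = GCNModel(params, running, config)
        return model, trace

    # block regime: stop when the running-minimum validation MAE fails to
    # decrease during a block of `block` epochs; no cap on total epochs.
    n_blocks = 0
    while True:
        block_min = min(run_epoch() for _ in range(block))
        n_blocks += 1
        if block_min >= global_min_mae:
            break
        global_min_mae = block_min
        if max_blocks is not None and n_blocks >= max_blocks:
            break
    trace.stopping_epoch = epoch
    trace.selected_epoch = select_final_epoch(trace)
    params, running = best["state"]
    return GCNModel(params, running, config), trace


def train(train_data, valid_data, config: GCNConfig,
          max_blocks: int | None = None) -> tuple[GCNModel, TrainingTrace]:
    """Final-model training with the epoch-block stopping rule.

    ``train_data``/``valid_data`` are ``(graphs, y)`` pairs.  Runs Adam/MSE
    in blocks of ``config.max_epoch_block`` epochs, stops when the running
    minimum validation MAE does not decrease within a block, and returns
    the weight snapshot from the epoch with maximal validation 2R2_MAE.
    ``max_blocks`` is an optional safety cap (default: none).
    """
    return _train_loop(*train_data, *valid_data, config, n_epochs=None, max_blocks=max_blocks)


def train_fixed_epochs(train_data, valid_data, config: GCNConfig,
                       n_epochs: int) -> tuple[GCNModel, TrainingTrace]:
    """Train for an exact epoch count (the search regime, where the epoch
    count is itself a hyperparameter); returns the final-epoch weights."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    return _train_loop(*train_data, *valid_data, config, n_epochs=n_epochs, max_blocks=None)


# ---------------------------------------------------------------------------
# Single-graph functional layers (contract-level API)
# ---------------------------------------------------------------------------

def graph_conv(graph: MolecularGraph, states: np.ndarray, w_self: np.ndarray,
               w_nbr: np.ndarray, bias: np.ndarray,
               gamma: np.ndarray | None = None, beta: np.ndarray | None = None) -> np.ndarray:
    """One convolution update on a single graph with batch-statistics
    normalization: ReLU(BatchNorm(W_self·h_v + Σ_nbr W_nbr·h_u + b))."""
    states = np.asarray(states, dtype=np.float64)
    if states.shape != (graph.n_atoms, w_self.shape[0]):
        raise ValueError(
            f"state shape {states.shape} incompatible with graph of "
            f"{graph.n_atoms} atoms and weight input dim {w_self.shape[0]}"
        )
    nbr_sum = np.zeros_like(states)
    for v, nb in enumerate(graph.neighbors):
        for u in nb:
            nbr_sum[v] += states[u]
    z = states @ w_self + nbr_sum @ w_nbr + bias
    mu, var = z.mean(axis=0), z.var(axis=0)
    xhat = (z - mu) / np.sqrt(var + _BN_EPS)
    if gamma is not None:
        xhat = xhat * gamma
    if beta is not None:
        xhat = xhat + beta
    return np.maximum(xhat, 0.0)


def graph_pool(graph: MolecularGraph, states: np.ndarray) -> np.ndarray:
    """Elementwise max over each atom's closed neighbourhood {v} ∪ N(v)."""
    states = np.asarray(states, dtype=np.float64)
    out = states.copy()
    for v, nb in enumerate(graph.neighbors):
        for u in nb:
            out[v] = np.maximum(out[v], states[u])
    return out


def graph_gather(dense_outputs: np.ndarray) -> np.ndarray:
    """Molecule-level neural fingerprint: tanh of the per-atom sum."""
    return np.tanh(np.asarray(dense_outputs, dtype=np.float64).sum(axis=0))


def forward(graph: MolecularGraph, model: GCNModel) -> float:
    """Deterministic single-molecule prediction (inference mode)."""
    return float(model.predict_batch(GraphBatch([graph]))[0])
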
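"""Graph-convolutional regressor for log Sw, with its training loop.

The network is a small two-block graph-convolutional architecture:

* per conv block ℓ (widths 64 and 128 by default):
  message ``m_i = h_i + Σ_{j∈N(i)} h_j``, then an affine map, batch
  normalization, a leaky-rectifier activation, and a graph max-pool
  ``h''_i = max over {h'_i} ∪ {h'_j : j ∈ N(i)}`` (element-wise),
* a per-node dense layer + batch normalization + activation,
* a sum readout over each molecule's nodes and a linear head to one scalar.

Training minimizes mean absolute error (L1) with adaptive-moment gradient
descent (Adam) at learning rate 5e-4, dropout 0.1, over 130 epochs — the
configuration that a validation-curve sweep selects for this architecture.
Labels are standardized internally (the mean/SD are stored with the model
and predictions are returned on the original log-unit scale).

Everything — forward, backpropagation, Adam — is implemented directly on
NumPy arrays (sparse adjacency for neighbor sums), which keeps the model
fully deterministic for a seed on one worker.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .augmentation import AugmentedExample
from .curation import CuratedRecord
from .featurize import (
    FeatureSpec,
    GraphBatch,
    MolGraph,
    _graph_arrays,
    batch_graphs,
    featurize,
)
from .records import StructureError

MODEL_FORMAT_VERSION = "solugraph-gcn-1"


@dataclass(frozen=True)
class GCNConfig:
    layer_widths: tuple[int, ...] = (64, 128)
    dense_width: int = 128
    learning_rate: float = 5e-4
    dropout: float = 0.1
    epochs: int = 130
    leaky_slope: float = 0.1
    batch_size: int = 64
    optimizer_name: str = "adam"
    loss: str = "mae"
    bn_momentum: float = 0.9
    bn_eps: float = 1e-5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.layer_widths or any(w <= 0 for w in self.layer_widths):
            raise ValueError("layer widths must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["layer_widths"] = list(self.layer_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GCNConfig":
        d = dict(d)
        d["layer_widths"] = tuple(d["layer_widths"])
        return cls(**d)


@dataclass
class TrainedModel:
    """Weights, normalization statistics and provenance of one trained GCN."""

    params: dict[str, np.ndarray]
    running: dict[str, np.ndarray]  # batch-norm running mean/var per BN layer
    config: GCNConfig
    feature_spec: FeatureSpec
    label_mean: float
    label_std: float
    history: dict[str, list[float]] = field(default_factory=dict)
    format_version: str = MODEL_FORMAT_VERSION


class TrainingDivergedError(RuntimeError):
    pass


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    # for x<0 and 0<slope<1, slope*x > x, so an elementwise max implements it
    out = x * np.float32(slope)
    np.maximum(out, x, out=out)
    return out


def _leaky_grad_mul(d: np.ndarray, x: np.ndarray, slope: float) -> np.ndarray:
    """d * dleaky(x)/dx in one pass."""
    if _HAVE_NUMBA:
        out = np.empty_like(d)
        _leaky_grad_mul_kernel(d.ravel(), x.ravel(), np.float32(slope), out.ravel())
        return out
    return np.where(x > 0, d, d * np.float32(slope))


def init_params(
    spec: FeatureSpec, cfg: GCNConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Fan-in-scaled uniform initialization; BN scales start at 1, shifts 0."""

    def linear(name: str, n_in: int, n_out: int, params: dict) -> None:
        bound = 1.0 / np.sqrt(n_in)
        params[f"{name}.W"] = rng.uniform(-bound, bound, (n_in, n_out)).astype(np.float32)
        params[f"{name}.b"] = rng.uniform(-bound, bound, n_out).astype(np.float32)

    def bn(name: str, width: int, params: dict, running: dict) -> None:
        params[f"{name}.gamma"] = np.ones(width, dtype=np.float32)
        params[f"{name}.beta"] = np.zeros(width, dtype=np.float32)
        running[f"{name}.mean"] = np.zeros(width, dtype=np.float32)
        running[f"{name}.var"] = np.ones(width, dtype=np.float32)

    params: dict[str, np.ndarray] = {}
    running: dict[str, np.ndarray] = {}
    n_in = spec.width
    for i, width in enumerate(cfg.layer_widths):
        linear(f"conv{i}", n_in, width, params)
        bn(f"bn{i}", width, params, running)
        n_in = width
    linear("dense", n_in, cfg.dense_width, params)
    bn("bn_dense", cfg.dense_width, params, running)
    # zero-initialized head: the network starts out predicting the label mean,
    # which stabilizes the short (130-epoch) training schedule
    params["head.W"] = np.zeros((cfg.dense_width, 1), dtype=np.float32)
    params["head.b"] = np.zeros(1, dtype=np.float32)
    return params, running


def _bn_backward(dout, gamma, cache):
    xhat, inv = cache
    n = np.float32(dout.shape[0])
    dgamma = (dout * xhat).sum(axis=0, dtype=np.float32)
    dbeta = dout.sum(axis=0, dtype=np.float32)
    dxhat = dout * gamma
    dz = (inv / n) * (
        n * dxhat - dxhat.sum(axis=0, dtype=np.float32) - xhat * (dxhat * xhat).sum(axis=0, dtype=np.float32)
    )
    return dz.astype(np.float32), dgamma, dbeta


def _bn_act_train(z, gamma, beta, running, name, eps, momentum, slope):
    """Batch-norm (batch statistics) + leaky activation, fused when possible.

    Returns the activation and the cache (u, xhat, invstd) for backward;
    updates the layer's running statistics in place.
    """
    if _HAVE_NUMBA:
        n, c = z.shape
        u = np.empty_like(z)
        a = np.empty_like(z)
        xhat = np.empty_like(z)
        mean = np.empty(c, dtype=np.float32)
        var = np.empty(c, dtype=np.float32)
        invstd = np.empty(c, dtype=np.float32)
        _bn_act_forward_kernel(
            z, gamma, beta, np.float32(eps), np.float32(slope),
            u, a, xhat, mean, var, invstd,
        )
    else:
        mean = z.mean(axis=0, dtype=np.float32)
        var = z.var(axis=0, dtype=np.float32)
        invstd = (1.0 / np.sqrt(var + eps)).astype(np.float32)
        xhat = (z - mean) * invstd
        u = gamma * xhat + beta
        a = _leaky(u, slope)
    running[f"{name}.mean"] = (momentum * running[f"{name}.mean"] + (1 - momentum) * mean).astype(np.float32)
    running[f"{name}.var"] = (momentum * running[f"{name}.var"] + (1 - momentum) * var).astype(np.float32)
    return a, (u, xhat, invstd)


def _bn_act_infer(z, gamma, beta, running, name, eps, slope):
    inv = (1.0 / np.sqrt(running[f"{name}.var"] + eps)).astype(np.float32)
    u = gamma * (z - running[f"{name}.mean"]) * inv + beta
    return _leaky(u, slope)


def _bn_act_backward(da, bn_cache, gamma, slope):
    """Backward through leaky activation + batch norm; returns dz, dgamma, dbeta."""
    u, xhat, invstd = bn_cache
    if _HAVE_NUMBA:
        dz = np.empty_like(da)
        dgamma = np.empty(da.shape[1], dtype=np.float32)
        dbeta = np.empty(da.shape[1], dtype=np.float32)
        _bn_act_backward_kernel(
            np.ascontiguousarray(da, dtype=np.float32), u, gamma, xhat, invstd,
            np.float32(slope), dz, dgamma, dbeta,
        )
        return dz, dgamma, dbeta
    dout = _leaky_grad_mul(da, u, slope)
    return _bn_backward(dout, gamma, (xhat, invstd))


def _pool_forward(h: np.ndarray, pool_index: np.ndarray) -> np.ndarray:
    """Element-wise max over each node and its neighbors (iterative reduce)."""
    out = h[pool_index[:, 0]].copy()
    for k in range(1, pool_index.shape[1]):
        np.maximum(out, h[pool_index[:, k]], out=out)
    return out


try:  # numba accelerates the max-pool backward kernel; NumPy path is equivalent
    import numba

    @numba.njit(cache=True)
    def _leaky_grad_mul_kernel(d, x, slope, out):  # pragma: no cover
        for i in range(d.size):
            out[i] = d[i] if x[i] > 0 else d[i] * slope

    @numba.njit(cache=True)
    def _bn_act_forward_kernel(  # pragma: no cover
        z, gamma, beta, eps, slope, u, a, xhat, mean, var, invstd
    ):
        n, c = z.shape
        for j in range(c):
            mean[j] = 0.0
            var[j] = 0.0
        for i in range(n):
            for j in range(c):
                mean[j] += z[i, j]
        for j in range(c):
            mean[j] /= n
        for i in range(n):
            for j in range(c):
                d = z[i, j] - mean[j]
                var[j] += d * d
        for j in range(c):
            var[j] /= n
            invstd[j] = 1.0 / np.sqrt(var[j] + eps)
        for i in range(n):
            for j in range(c):
                xh = (z[i, j] - mean[j]) * invstd[j]
                xhat[i, j] = xh
                uu = gamma[j] * xh + beta[j]
                u[i, j] = uu
                a[i, j] = uu if uu > 0 else slope * uu

    @numba.njit(cache=True)
    def _bn_act_backward_kernel(  # pragma: no cover
        da, u, gamma, xhat, invstd, slope, dz, dgamma, dbeta
    ):
        n, c = da.shape
        for j in range(c):
            dgamma[j] = 0.0
            dbeta[j] = 0.0
        for i in range(n):
            for j in range(c):
                dout = da[i, j] if u[i, j] > 0 else slope * da[i, j]
                dz[i, j] = dout
                dgamma[j] += dout * xhat[i, j]
                dbeta[j] += dout
        for i in range(n):
            for j in range(c):
                dxhat = dz[i, j] * gamma[j]
                dz[i, j] = (invstd[j] / n) * (
                    n * dxhat
                    - gamma[j] * dbeta[j]
                    - xhat[i, j] * gamma[j] * dgamma[j]
                )

    @numba.njit(cache=True)
    def _pool_backward_kernel(pool_index, a, pooled, dpooled, out):  # pragma: no cover
        n, k = pool_index.shape
        c = a.shape[1]
        for i in range(n):
            for j in range(c):
                p = pooled[i, j]
                for s in range(k):
                    r = pool_index[i, s]
                    if a[r, j] == p:
                        out[r, j] += dpooled[i, j]
                        break

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _pool_backward(dpooled, h, pooled, batch) -> np.ndarray:
    """Route each pooled gradient to the first candidate achieving the max.

    Candidate order is the node itself first, then its neighbors in index
    order, so the tie-break is deterministic.  This is the conventional
    max-pool subgradient.
    """
    dpooled = np.ascontiguousarray(dpooled, dtype=np.float32)
    if _HAVE_NUMBA:
        out = np.zeros_like(h)
        _pool_backward_kernel(batch.pool_index, h, pooled, dpooled, out)
        return out
    cand = h[batch.pool_index]  # (N, K, C)
    first = (cand == pooled[:, None, :]).argmax(axis=1)  # first winner per feature
    src = np.take_along_axis(batch.pool_index, first, axis=1)
    out = np.zeros_like(h)
    cols = np.broadcast_to(np.arange(h.shape[1]), dpooled.shape)
    np.add.at(out, (src, cols), dpooled)
    return out


def forward(
    batch: GraphBatch,
    model: TrainedModel,
    mode: str = "infer",
    rng: np.random.Generator | None = None,
) -> np.ndarray | tuple[np.ndarray, dict]:
    """Run the network on a batch; returns per-graph predictions (log units).

    In ``train`` mode dropout is active, batch statistics feed the
    normalization layers, and a cache for backpropagation is returned
    alongside the (still label-normalized) outputs.
    """
    if batch.node_features.shape[1] != model.feature_spec.width:
        raise ValueError("batch feature dimension does not match the model")
    if batch.n_nodes == 0:
        raise ValueError("empty graph batch")
    train = mode == "train"
    if train and rng is None:
        raise ValueError("train mode needs an RNG for dropout")
    cfg = model.config
    p, run = model.params, model.running
    A = batch.adjacency
    cache: dict = {"drop": [], "conv": []}

    h = batch.node_features
    for i in range(len(cfg.layer_widths)):
        m = h + A @ h
        z = m @ p[f"conv{i}.W"] + p[f"conv{i}.b"]
        if train:
            a, bn_cache = _bn_act_train(
                z, p[f"bn{i}.gamma"], p[f"bn{i}.beta"], run, f"bn{i}",
                cfg.bn_eps, cfg.bn_momentum, cfg.leaky_slope,
            )
        else:
            a = _bn_act_infer(
                z, p[f"bn{i}.gamma"], p[f"bn{i}.beta"], run, f"bn{i}",
                cfg.bn_eps, cfg.leaky_slope,
            )
        pooled = _pool_forward(a, batch.pool_index)
        if train and cfg.dropout > 0:
            mask = (
                rng.random(pooled.shape, dtype=np.float32) >= cfg.dropout
            ).astype(np.float32) / np.float32(1.0 - cfg.dropout)
            dropped = pooled * mask
        else:
            mask = None
            dropped = pooled
        if train:
            cache["conv"].append(
                {"m": m, "bn": bn_cache, "a": a, "pooled": pooled, "mask": mask}
            )
        h = dropped

    zd = h @ p["dense.W"] + p["dense.b"]
    if train:
        ad, bnd_cache = _bn_act_train(
            zd, p["bn_dense.gamma"], p["bn_dense.beta"], run, "bn_dense",
            cfg.bn_eps, cfg.bn_momentum, cfg.leaky_slope,
        )
    else:
        ad = _bn_act_infer(
            zd, p["bn_dense.gamma"], p["bn_dense.beta"], run, "bn_dense",
            cfg.bn_eps, cfg.leaky_slope,
        )
    if train and cfg.dropout > 0:
        mask_d = (
            rng.random(ad.shape, dtype=np.float32) >= cfg.dropout
        ).astype(np.float32) / np.float32(1.0 - cfg.dropout)
        qd = ad * mask_d
    else:
        mask_d = None
        qd = ad

    # sum readout per graph, then linear head
    g = (batch.segment @ qd).astype(np.float32)
    y = (g @ p["head.W"] + p["head.b"]).ravel()

    if not train:
        return y * model.label_std + model.label_mean
    cache.update({"dense_in": h, "bnd": bnd_cache, "mask_d": mask_d, "g": g})
    return y, cache


def _backward(
    batch: GraphBatch,
    model: TrainedModel,
    cache: dict,
    dy: np.ndarray,
) -> dict[str, np.ndarray]:
    cfg = model.config
    p = model.params
    A = batch.adjacency
    grads: dict[str, np.ndarray] = {}

    dy = dy.astype(np.float32).reshape(-1, 1)
    grads["head.W"] = cache["g"].T @ dy
    grads["head.b"] = dy.sum(axis=0)
    dg = dy @ p["head.W"].T  # (G, C)
    dqd = dg[batch.graph_index]  # readout backward

    if cache["mask_d"] is not None:
        dad = dqd * cache["mask_d"]
    else:
        dad = dqd
    dzd, grads["bn_dense.gamma"], grads["bn_dense.beta"] = _bn_act_backward(
        dad, cache["bnd"], p["bn_dense.gamma"], cfg.leaky_slope
    )
    grads["dense.W"] = cache["dense_in"].T @ dzd
    grads["dense.b"] = dzd.sum(axis=0)
    dh = dzd @ p["dense.W"].T

    for i in reversed(range(len(cfg.layer_widths))):
        c = cache["conv"][i]
        if c["mask"] is not None:
            dh = dh * c["mask"]
        da = _pool_backward(dh, c["a"], c["pooled"], batch)
        dz, grads[f"bn{i}.gamma"], grads[f"bn{i}.beta"] = _bn_act_backward(
            da, c["bn"], p[f"bn{i}.gamma"], cfg.leaky_slope
        )
        grads[f"conv{i}.W"] = c["m"].T @ dz
        grads[f"conv{i}.b"] = dz.sum(axis=0)
        if i > 0:
            dm = dz @ p[f"conv{i}.W"].T
            dh = dm + A.T @ dm  # adjacency is symmetric
    return grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v, dtype=np.float32) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float32) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, gr in grads.items():
            gr = gr.reshape(params[k].shape).astype(np.float32)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * gr
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * gr * gr
            params[k] = params[k] - self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


@lru_cache(maxsize=200_000)
def _graph_template(smiles: str, spec: FeatureSpec) -> MolGraph:
    return featurize(smiles, spec)


def _featurize_examples(
    examples: Sequence[AugmentedExample], spec: FeatureSpec
) -> list[MolGraph]:
    """Featurize variants, sharing immutable graph templates across folds."""
    graphs = []
    for ex in examples:
        t = _graph_template(ex.variant_smiles, spec)
        g = MolGraph(t.node_features, t.neighbors, parent_id=ex.parent_id, label=ex.label)
        g.__dict__["_arrays"] = _graph_arrays(t)  # share edge/pool arrays too
        graphs.append(g)
    return graphs


def _rmse(pred: np.ndarray, truth: np.ndarray) -> float:
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def train(
    train_examples: Sequence[AugmentedExample],
    valid_parents: Sequence[CuratedRecord],
    cfg: GCNConfig | None = None,
    feature_spec: FeatureSpec | None = None,
) -> TrainedModel:
    """Train one GCN on augmented examples, validating on unaugmented parents.

    Runs exactly ``cfg.epochs`` epochs of shuffled mini-batch Adam on mean
    absolute error.  The per-epoch validation rmse is computed on the parent
    canonical structures in inference mode, so the history is comparable to
    held-out fold statistics.  Fully reproducible given ``cfg.rng_seed``.
    """
    cfg = cfg or GCNConfig()
    spec = feature_spec or FeatureSpec()
    if not train_examples:
        raise ValueError("empty training set")

    graphs = _featurize_examples(train_examples, spec)
    labels = np.array([g.label for g in graphs], dtype=np.float64)
    label_mean = float(labels.mean())
    label_std = float(labels.std())
    if label_std < 1e-8:
        label_std = 1.0

    valid_batch = None
    valid_truth = None
    if valid_parents:
        valid_graphs = [
            featurize(r.canonical_smiles, spec, parent_id=r.inchikey, label=r.logsw)
            for r in valid_parents
        ]
        valid_batch = batch_graphs(valid_graphs)
        valid_truth = np.array([g.label for g in valid_graphs], dtype=np.float64)

    rng = np.random.default_rng(cfg.rng_seed)
    params, running = init_params(spec, cfg, rng)
    model = TrainedModel(
        params=params,
        running=running,
        config=cfg,
        feature_spec=spec,
        label_mean=label_mean,
        label_std=label_std,
        history={"train_rmse": [], "valid_rmse": []},
    )
    optimizer = _Adam(params, cfg.learning_rate)

    n = len(graphs)
    norm_labels = (labels - label_mean) / label_std
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        sq_err_sum = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            batch = batch_graphs([graphs[i] for i in idx])
            target = norm_labels[idx]
            y, cache = forward(batch, model, mode="train", rng=rng)
            err = y - target
            if not np.all(np.isfinite(err)):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {_epoch}; aborting"
                )
            dy = np.sign(err) / len(idx)  # d(mean |err|)/d y
            grads = _backward(batch, model, cache, dy)
            optimizer.step(params, grads)
            sq_err_sum += float(np.sum((err * label_std) ** 2))
        model.history["train_rmse"].append(float(np.sqrt(sq_err_sum / n)))
        if valid_batch is not None:
            vp = forward(valid_batch, model, mode="infer")
            model.history["valid_rmse"].append(_rmse(vp, valid_truth))
    return model


def predict(
    model: TrainedModel, smiles_list: Sequence[str]
) -> list[tuple[float | None, str]]:
    """Predict log Sw per SMILES; unparseable inputs get status ``failed``.

    Order is preserved; one bad input never aborts the batch.
    """
    graphs: list[MolGraph | None] = []
    for smi in smiles_list:
        try:
            graphs.append(featurize(smi, model.feature_spec))
        except (StructureError, ValueError):
            graphs.append(None)
    good = [g for g in graphs if g is not None]
    preds = iter(
        forward(batch_graphs(good), model, mode="infer") if good else []
    )
    out: list[tuple[float | None, str]] = []
    for g in graphs:
        if g is None:
            out.append((None, "failed"))
        else:
            out.append((float(next(preds)), "ok"))
    return out


def predict_records(model: TrainedModel, records: Sequence[CuratedRecord]) -> np.ndarray:
    """Predict for curated records (canonical structures); returns an array."""
    graphs = [featurize(r.canonical_smiles, model.feature_spec) for r in records]
    return forward(batch_graphs(graphs), model, mode="infer")


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write a single-archive model file (named arrays + JSON metadata)."""
    path = Path(path)
    meta = {
        "format_version": model.format_version,
        "config": model.config.to_dict(),
        "feature_spec": model.feature_spec.to_dict(),
        "label_mean": model.label_mean,
        "label_std": model.label_std,
        "history": model.history,
        "param_keys": sorted(model.params),
        "running_keys": sorted(model.running),
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta))
        buf = io.BytesIO()
        arrays = {f"p__{k}": v for k, v in model.params.items()}
        arrays.update({f"r__{k}": v for k, v in model.running.items()})
        np.savez(buf, **arrays)
        zf.writestr("arrays.npz", buf.getvalue())


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta["format_version"] != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {meta['format_version']!r}")
        with zf.open("arrays.npz") as fh:
            data = np.load(io.BytesIO(fh.read()))
            params = {k[3:]: data[k] for k in data.files if k.startswith("p__")}
            running = {k[3:]: data[k] for k in data.files if k.startswith("r__")}
    return TrainedModel(
        params=params,
        running=running,
        config=GCNConfig.from_dict(meta["config"]),
        feature_spec=FeatureSpec.from_dict(meta["feature_spec"]),
        label_mean=float(meta["label_mean"]),
        label_std=float(meta["label_std"]),
        history=meta["history"],
        format_version=meta["format_version"],
    )


def write_training_log(model: TrainedModel, path: str | Path) -> None:
    hist = model.history
    n = len(hist.get("train_rmse", []))
    df = pd.DataFrame(
        {
            "epoch": np.arange(1, n + 1),
            "train_rmse": hist.get("train_rmse", [np.nan] * n),
            "valid_rmse": hist.get("valid_rmse", [np.nan] * n) or [np.nan] * n,
        }
    )
    df.to_csv(path, index=False)
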
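"""Deep graph convolutional classifier for whole correlation networks.

The architecture follows the DGCNN family: a stack of graph convolutions
with propagation rule

    Z(l+1) = sigma( D~^{-1} A~ Z(l) W(l) ),   A~ = A + I,

where for correlation-valued (signed) adjacency the normalizing degree is
D~_ii = sum_j |A~_ij| so the propagation operator stays well defined while
edge signs are preserved.  The per-layer activations are concatenated
horizontally and passed through SortPooling (rows reordered by descending
last channel of the final graph-conv layer, ties broken by ascending node
index, truncated to k rows), then a 1-D convolutional head: one
convolution with kernel = stride = total channel width (a per-node dense
map), one ordinary 1-D convolution, max pooling, a dense layer with
dropout and a 2-class softmax.

Everything is NumPy with hand-written backpropagation and an Adam
optimizer; training is deterministic for a fixed seed on one platform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .graph_dataset import CorrelationNetwork, GraphDataset

logger = logging.getLogger(__name__)

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda out: 1.0 - out**2),
    "relu": (lambda x: np.maximum(x, 0.0), lambda out: (out > 0).astype(float)),
    "identity": (lambda x: x, lambda out: np.ones_like(out)),
}


@dataclass
class DgcnnConfig:
    """Architecture and training hyperparameters.

    conv_channels: widths of the stacked graph-conv layers (the last layer
    provides the SortPooling key, conventionally width 1).
    sortpool_k: nodes kept by SortPooling; None means all p nodes (every
    network in a dataset shares the node set, so no truncation is needed).
    conv1d_spec: (filters, kernel, stride) for the two 1-D convolutions;
    a None kernel in the first entry means "total channel width".
    """

    conv_channels: list[int] = field(default_factory=lambda: [32, 32, 32, 1])
    sortpool_k: int | None = None
    conv1d_spec: tuple = ((16, None, None), (32, 5, 1))
    pool_size: int = 2
    dense_units: int = 128
    dropout: float = 0.5
    activation: str = "tanh"
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0


@dataclass
class PredictionResult:
    """Class-1 ('diseased') probability and hard label for one network."""

    p_disease: float
    predicted_label: int


@dataclass
class DgcnnModel:
    """Trained weights plus configuration; all forward passes are pure."""

    weights: dict
    config: DgcnnConfig
    n_nodes: int
    taxon_ids: list[str] | None = None

    def predict(self, network: CorrelationNetwork, node_info: np.ndarray | None = None) -> PredictionResult:
        return forward(self, network, node_info)

    def predict_proba(self, adjacency_stack: np.ndarray, node_info: np.ndarray | None = None) -> np.ndarray:
        if node_info is None:
            node_info = np.eye(self.n_nodes)
        probs, _ = _forward_batch(self, adjacency_stack, node_info)
        return probs


# --------------------------------------------------------------------------
# Core ops

def graph_conv_forward(
    adjacency: np.ndarray,
    node_info: np.ndarray,
    weights: np.ndarray,
    activation: str = "tanh",
) -> np.ndarray:
    """One propagation step sigma(D~^{-1} A~ Z W) with A~ = A + I and
    D~_ii = sum_j |A~_ij| (absolute-value degree for signed weights)."""
    A = np.asarray(adjacency, float)
    At = A + np.eye(A.shape[0])
    deg = np.abs(At).sum(axis=1)
    P = At / deg[:, None]
    act, _ = _ACTIVATIONS[activation]
    return act(P @ np.asarray(node_info, float) @ np.asarray(weights, float))


def sort_pooling(layer_outputs: list[np.ndarray], k: int) -> np.ndarray:
    """Concatenate layer activations horizontally, reorder rows by the
    descending last channel of the final layer (ties by ascending original
    node index) and keep the first k rows."""
    p = layer_outputs[0].shape[0]
    if k > p:
        raise ValueError(f"sortpool_k = {k} exceeds node count {p}")
    concat = np.concatenate(layer_outputs, axis=1)
    key = layer_outputs[-1][:, -1]
    order = np.argsort(-key, kind="stable")  # stable: ties keep ascending index
    return concat[order[:k]]


# --------------------------------------------------------------------------
# Batched forward/backward

def _propagation_operator(A_stack: np.ndarray) -> np.ndarray:
    At = A_stack + np.eye(A_stack.shape[1])[None]
    deg = np.abs(At).sum(axis=2)
    return At / deg[:, :, None]


def _resolve_spec(config: DgcnnConfig, p: int):
    k = config.sortpool_k if config.sortpool_k is not None else p
    if k > p:
        raise ValueError(f"sortpool_k = {k} exceeds node count {p}")
    ctot = sum(config.conv_channels)
    (f1, k1, s1), (f2, k2, s2) = config.conv1d_spec
    k1 = ctot if k1 is None else k1
    s1 = k1 if s1 is None else s1
    k2 = min(k2, k)  # small graphs: clamp the second kernel
    len2 = (k - k2) // s2 + 1
    pool = config.pool_size if len2 >= config.pool_size else 1
    len3 = len2 // pool
    return k, ctot, (f1, k1, s1), (f2, k2, s2), pool, len2, len3


def init_model(config: DgcnnConfig, n_nodes: int, n_node_features: int | None = None,
               taxon_ids: list[str] | None = None) -> DgcnnModel:
    """Glorot-initialized model for graphs with a fixed node set."""
    p = n_nodes
    d0 = p if n_node_features is None else n_node_features
    rng = np.random.default_rng(config.seed)
    k, ctot, (f1, k1, s1), (f2, k2, s2), pool, len2, len3 = _resolve_spec(config, p)

    def glorot(shape):
        lim = np.sqrt(6.0 / (shape[0] + shape[-1]))
        return rng.uniform(-lim, lim, size=shape)

    weights: dict[str, np.ndarray] = {}
    din = d0
    for l, width in enumerate(config.conv_channels):
        weights[f"gc{l}"] = glorot((din, width))
        din = width
    weights["c1_w"] = glorot((k1, f1))
    weights["c1_b"] = np.zeros(f1)
    weights["c2_w"] = glorot((k2 * f1, f2))
    weights["c2_b"] = np.zeros(f2)
    weights["d1_w"] = glorot((len3 * f2, config.dense_units))
    weights["d1_b"] = np.zeros(config.dense_units)
    weights["out_w"] = glorot((config.dense_units, 2))
    weights["out_b"] = np.zeros(2)
    return DgcnnModel(weights=weights, config=config, n_nodes=p, taxon_ids=taxon_ids)


def _forward_batch(model: DgcnnModel, A_stack: np.ndarray, node_info: np.ndarray,
                   dropout_rng: np.random.Generator | None = None):
    """Forward pass on a stack of adjacencies; returns (probs, cache)."""
    cfg = model.config
    W = model.weights
    B, p, _ = A_stack.shape
    k, ctot, (f1, k1, s1), (f2, k2, s2), pool, len2, len3 = _resolve_spec(cfg, p)
    act, dact = _ACTIVATIONS[cfg.activation]

    P = _propagation_operator(A_stack)            # (B,p,p)
    Z = np.broadcast_to(node_info, (B,) + node_info.shape)
    zs = []
    for l in range(len(cfg.conv_channels)):
        Z = act(P @ Z @ W[f"gc{l}"])
        zs.append(Z)
    concat = np.concatenate(zs, axis=2)           # (B,p,ctot)
    key = zs[-1][:, :, -1]
    order = np.argsort(-key, axis=1, kind="stable")[:, :k]   # (B,k)
    bidx = np.arange(B)[:, None]
    sorted_feat = concat[bidx, order]             # (B,k,ctot)

    # conv1: kernel = stride = channel width -> per-node dense map
    h1_pre = sorted_feat @ W["c1_w"] + W["c1_b"]  # (B,k,f1)
    h1 = np.maximum(h1_pre, 0.0)

    # conv2: ordinary 1-D convolution along the node axis
    windows = np.stack([h1[:, i : i + k2] for i in range(len2)], axis=1)  # (B,len2,k2,f1)
    win_flat = windows.reshape(B, len2, k2 * f1)
    h2_pre = win_flat @ W["c2_w"] + W["c2_b"]     # (B,len2,f2)
    h2 = np.maximum(h2_pre, 0.0)

    # max pooling
    if pool > 1:
        trimmed = h2[:, : len3 * pool].reshape(B, len3, pool, f2)
        pool_arg = trimmed.argmax(axis=2)
        h3 = trimmed.max(axis=2)
    else:
        pool_arg, h3 = None, h2

    flat = h3.reshape(B, -1)
    d1_pre = flat @ W["d1_w"] + W["d1_b"]
    d1 = np.maximum(d1_pre, 0.0)
    if dropout_rng is not None and cfg.dropout > 0:
        mask = (dropout_rng.random(d1.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
        d1 = d1 * mask
    else:
        mask = None
    logits = d1 @ W["out_w"] + W["out_b"]
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)

    cache = dict(
        P=P, zs=zs, order=order, sorted_feat=sorted_feat,
        h1=h1, win_flat=win_flat, h2=h2, pool_arg=pool_arg, flat=flat,
        d1=d1, mask=mask, probs=probs,
        dims=(B, p, k, ctot, f1, k2, f2, pool, len2, len3),
        node_info=node_info, dact=dact,
    )
    return probs, cache


def _backward_batch(model: DgcnnModel, cache: dict, dlogits: np.ndarray) -> dict:
    """Gradients of the loss wrt all weights given d(loss)/d(logits).

    The SortPooling permutation and max-pool indices are treated as
    constants (standard piecewise-linear backprop)."""
    cfg = model.config
    W = model.weights
    B, p, k, ctot, f1, k2, f2, pool, len2, len3 = cache["dims"]
    grads: dict[str, np.ndarray] = {}

    d1 = cache["d1"]
    grads["out_w"] = d1.T @ dlogits
    grads["out_b"] = dlogits.sum(axis=0)
    dd1 = dlogits @ W["out_w"].T
    if cache["mask"] is not None:
        dd1 = dd1 * cache["mask"]
    dd1 = dd1 * (d1 > 0)
    flat = cache["flat"]
    grads["d1_w"] = flat.T @ dd1
    grads["d1_b"] = dd1.sum(axis=0)
    dflat = dd1 @ W["d1_w"].T
    dh3 = dflat.reshape(B, len3, f2)

    if pool > 1:
        dh2 = np.zeros((B, len2, f2))
        pa = cache["pool_arg"]  # (B,len3,f2)
        b_i, l_i, f_i = np.meshgrid(
            np.arange(B), np.arange(len3), np.arange(f2), indexing="ij"
        )
        dh2[b_i, l_i * pool + pa, f_i] = dh3
    else:
        dh2 = dh3
    dh2 = dh2 * (cache["h2"] > 0)
    win_flat = cache["win_flat"]
    grads["c2_w"] = np.einsum("blc,blf->cf", win_flat, dh2)
    grads["c2_b"] = dh2.sum(axis=(0, 1))
    dwin = (dh2 @ W["c2_w"].T).reshape(B, len2, k2, f1)
    dh1 = np.zeros((B, k, f1))
    for i in range(len2):
        dh1[:, i : i + k2] += dwin[:, i]
    dh1 = dh1 * (cache["h1"] > 0)
    sorted_feat = cache["sorted_feat"]
    grads["c1_w"] = np.einsum("bkc,bkf->cf", sorted_feat, dh1)
    grads["c1_b"] = dh1.sum(axis=(0, 1))
    dsorted = dh1 @ W["c1_w"].T                   # (B,k,ctot)

    dconcat = np.zeros((B, p, ctot))
    bidx = np.arange(B)[:, None]
    dconcat[bidx, cache["order"]] = dsorted

    # back through the graph-conv stack
    widths = cfg.conv_channels
    offsets = np.cumsum([0] + list(widths))
    dZ_next = np.zeros_like(cache["zs"][-1])
    P = cache["P"]
    dact = cache["dact"]
    for l in reversed(range(len(widths))):
        dZ = dconcat[:, :, offsets[l] : offsets[l + 1]] + dZ_next
        dpre = dZ * dact(cache["zs"][l])
        Zprev = cache["zs"][l - 1] if l > 0 else np.broadcast_to(
            cache["node_info"], (B,) + cache["node_info"].shape
        )
        PZ = P @ Zprev
        grads[f"gc{l}"] = np.einsum("bpc,bpw->cw", PZ, dpre)
        if l > 0:
            dZ_next = np.einsum("bqp,bqw->bpw", P, dpre) @ W[f"gc{l}"].T
    return grads


def forward(model: DgcnnModel, network: CorrelationNetwork,
            node_info: np.ndarray | None = None) -> PredictionResult:
    """Deterministic class prediction for one network (dropout off)."""
    if network.n_nodes != model.n_nodes:
        raise ValueError(
            f"network has {network.n_nodes} nodes; model expects {model.n_nodes}"
        )
    if node_info is None:
        node_info = np.eye(model.n_nodes)
    probs, _ = _forward_batch(model, network.adjacency[None], node_info)
    p1 = float(probs[0, 1])
    return PredictionResult(p_disease=p1, predicted_label=int(p1 >= 0.5))


def save_model(model: DgcnnModel, prefix) -> None:
    """Serialize weights (compressed arrays) and configuration (JSON)."""
    import dataclasses
    import json

    np.savez_compressed(f"{prefix}.npz", **model.weights)
    meta = {
        "config": dataclasses.asdict(model.config),
        "n_nodes": model.n_nodes,
        "taxon_ids": model.taxon_ids,
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(prefix) -> DgcnnModel:
    import json

    arrays = np.load(f"{prefix}.npz")
    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    cfg_dict = meta["config"]
    cfg_dict["conv1d_spec"] = tuple(tuple(s) for s in cfg_dict["conv1d_spec"])
    cfg = DgcnnConfig(**cfg_dict)
    return DgcnnModel(
        weights={k: arrays[k] for k in arrays.files},
        config=cfg,
        n_nodes=meta["n_nodes"],
        taxon_ids=meta["taxon_ids"],
    )


# --------------------------------------------------------------------------
# Training and evaluation

class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.m = {key: np.zeros_like(v) for key, v in params.items()}
        self.v = {key: np.zeros_like(v) for key, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for key, g in grads.items():
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1**self.t)
            vhat = self.v[key] / (1 - b2**self.t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def evaluate(model: DgcnnModel, dataset: GraphDataset) -> dict:
    """Accuracy, precision, recall (class 1 positive) and AUC on a dataset."""
    labels = dataset.labels
    if np.unique(labels).size < 2:
        raise ValueError("evaluation requires both classes present (AUC undefined)")
    probs = model.predict_proba(dataset.adjacency_stack, dataset.node_info)
    scores = probs[:, 1]
    pred = (scores >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    return {
        "accuracy": float(np.mean(pred == labels)),
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
        "auc": float(roc_auc_score(labels, scores)),
    }


def train(
    dataset_train: GraphDataset,
    dataset_val: GraphDataset,
    config: DgcnnConfig | None = None,
) -> tuple[DgcnnModel, list[dict]]:
    """Train by mini-batch cross-entropy minimization with Adam.

    Returns the fitted model and per-epoch train/validation metrics.  The
    seed in ``config`` controls weight initialization, shuffling and
    dropout, giving reproducible trajectories on one platform.
    """
    config = config or DgcnnConfig()
    if dataset_train.taxon_ids != dataset_val.taxon_ids:
        raise ValueError("train and validation sets must share the taxon set")
    p = len(dataset_train.taxon_ids)
    node_info = dataset_train.node_info
    model = init_model(config, p, node_info.shape[1], taxon_ids=dataset_train.taxon_ids)
    opt = _Adam(model.weights, config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]).generate_state(1)[0])

    A_train = dataset_train.adjacency_stack
    y_train = dataset_train.labels
    n = len(y_train)
    history: list[dict] = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            probs, cache = _forward_batch(model, A_train[idx], node_info, dropout_rng=rng)
            y = y_train[idx]
            loss = -np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or check the input networks"
                )
            epoch_loss += loss * len(y)
            dlogits = probs.copy()
            dlogits[np.arange(len(y)), y] -= 1.0
            dlogits /= len(y)
            grads = _backward_batch(model, cache, dlogits)
            opt.step(model.weights, grads)
        metrics = {
            "epoch": epoch,
            "loss": epoch_loss / n,
            "train": evaluate(model, dataset_train),
            "val": evaluate(model, dataset_val),
        }
        history.append(metrics)
    return model, history
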
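"""The pocket-graph regression network.

Architecture: graph convolution → graph attention → graph attention →
graph convolution, each followed by batch normalization and ELU, then a
mean readout over each graph's nodes to a single scalar (the predicted
absorption maximum).  No layer adds self-loops and each attention layer
uses a single head.

The GCN layers use the 1/d edge weights inside the symmetric
normalization (weighted degrees); the attention layers receive the edge
weight as a learned scalar contribution to the attention logit.  The
output head carries a frozen affine target scaling (mean/std of the
training labels) so the network's raw output lives near unit scale.

All tensor math runs on the package's reverse-mode autodiff engine
(:mod:`rhopocket.autodiff`); gradients are validated against central
finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .graphs import MolecularGraph

BN_EPS = 1e-5
BN_MOMENTUM = 0.1
LEAKY_SLOPE = 0.2


@dataclass(frozen=True)
class LayerDims:
    """Hidden widths of the four layers: F_in → a → b → c → 1."""

    f_in: int
    a: int = 32
    b: int = 32
    c: int = 32

    def __post_init__(self):
        if min(self.f_in, self.a, self.b, self.c) <= 0:
            raise ValueError("layer dims must be positive")


@dataclass
class ModelParams:
    """All weights, attention vectors and batch-norm state of the network.

    ``arrays`` keys: W1..W4, b1..b4 (layer weights/biases), g*/s* (batch
    norm scale/shift), rm*/rv* (batch-norm running mean/var, not
    trainable), and for attention layers a2s/a2d/a2e, a3s/a3d/a3e.
    ``label_mean``/``label_std`` freeze the target scaling of the output
    head (fitted on training labels, identity by default).
    """

    arrays: dict[str, np.ndarray]
    dims: LayerDims
    attention: bool = True
    final_norm: bool = False
    label_mean: float = 0.0
    label_std: float = 1.0
    meta: dict = field(default_factory=dict)

    def trainable_keys(self) -> list[str]:
        return [k for k in self.arrays if not k.startswith(("rm", "rv"))]

    def n_trainable(self) -> int:
        return int(sum(self.arrays[k].size for k in self.trainable_keys()))

    def architecture_report(self) -> list[str]:
        mid = "GAT" if self.attention else "GCN"
        return ["GCN", mid, mid, "GCN"]

    def copy(self) -> "ModelParams":
        return ModelParams(
            arrays={k: v.copy() for k, v in self.arrays.items()},
            dims=self.dims,
            attention=self.attention,
            final_norm=self.final_norm,
            label_mean=self.label_mean,
            label_std=self.label_std,
            meta=dict(self.meta),
        )


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(
    dims: LayerDims, seed: int, attention: bool = True, final_norm: bool = False
) -> ModelParams:
    """Deterministic Glorot-uniform initialization; zero biases, unit BN.

    ``final_norm`` controls whether the last layer is followed by batch
    norm + ELU like the others (the default linear readout avoids
    bounding the prediction range through the final ELU).
    """
    rng = np.random.default_rng(seed)
    widths = [dims.f_in, dims.a, dims.b, dims.c, 1]
    arrays: dict[str, np.ndarray] = {}
    for layer in range(4):
        fi, fo = widths[layer], widths[layer + 1]
        arrays[f"W{layer + 1}"] = _glorot(rng, fi, fo, (fi, fo))
        arrays[f"b{layer + 1}"] = np.zeros(fo)
        if layer < 3 or final_norm:
            arrays[f"g{layer + 1}"] = np.ones(fo)
            arrays[f"s{layer + 1}"] = np.zeros(fo)
            arrays[f"rm{layer + 1}"] = np.zeros(fo)
            arrays[f"rv{layer + 1}"] = np.ones(fo)
        if attention and layer in (1, 2):
            arrays[f"a{layer + 1}s"] = _glorot(rng, fo, 1, (fo,))
            arrays[f"a{layer + 1}d"] = _glorot(rng, fo, 1, (fo,))
            arrays[f"a{layer + 1}e"] = np.zeros(())
    return ModelParams(arrays=arrays, dims=dims, attention=attention,
                       final_norm=final_norm)


def param_count(dims: LayerDims, attention: bool = True, final_norm: bool = False) -> int:
    """Closed-form trainable parameter count for the architecture."""
    widths = [dims.f_in, dims.a, dims.b, dims.c, 1]
    total = 0
    for layer in range(4):
        fi, fo = widths[layer], widths[layer + 1]
        total += fi * fo + fo      # W, b
        if layer < 3 or final_norm:
            total += 2 * fo        # batch-norm scale + shift
        if attention and layer in (1, 2):
            total += 2 * fo + 1    # a_src, a_dst, a_edge
    return total


# --------------------------------------------------------------------------
# batching
# --------------------------------------------------------------------------

@dataclass
class GraphBatch:
    """Disjoint union of graphs with per-node graph membership."""

    x: np.ndarray          # (N_total, F)
    src: np.ndarray        # (E,) message sources
    dst: np.ndarray        # (E,) message destinations
    w: np.ndarray          # (E,) edge weights
    graph_index: np.ndarray  # (N_total,)
    n_graphs: int

    @classmethod
    def from_graphs(cls, graphs: list[MolecularGraph]) -> "GraphBatch":
        if not graphs:
            raise ValueError("empty batch")
        xs, srcs, dsts, ws, gidx = [], [], [], [], []
        offset = 0
        for gi, g in enumerate(graphs):
            if g.n_nodes == 0:
                raise ValueError(f"graph {g.graph_id!r} has no nodes")
            xs.append(g.node_features)
            if g.n_directed_edges:
                srcs.append(g.edges[:, 0] + offset)
                dsts.append(g.edges[:, 1] + offset)
                ws.append(g.edge_weights)
            gidx.append(np.full(g.n_nodes, gi))
            offset += g.n_nodes
        cat = lambda parts, dt: (
            np.concatenate(parts) if parts else np.empty(0, dtype=dt)
        )
        return cls(
            x=np.vstack(xs),
            src=cat(srcs, int).astype(int),
            dst=cat(dsts, int).astype(int),
            w=cat(ws, float).astype(float),
            graph_index=np.concatenate(gidx).astype(int),
            n_graphs=len(graphs),
        )


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

def gcn_coefficients(src, dst, w, n_nodes: int) -> np.ndarray:
    """Per-edge symmetric normalization  w_ij / sqrt(d̃_src d̃_dst)
    with weighted degrees d̃_i = Σ_j w_ij; no self term."""
    deg = np.zeros(n_nodes)
    np.add.at(deg, dst, w)
    return w / np.sqrt(deg[src] * deg[dst])


def gcn_layer(h: Tensor, src, dst, w, n_nodes: int, W: Tensor, b: Tensor) -> Tensor:
    """H'_i = Σ_{j∈N(i)} (w_ij/√(d̃_i d̃_j)) (H_j W) + b; isolated → bias."""
    hw = h @ W
    if len(src) == 0:
        return hw * 0.0 + b  # bias everywhere, keeps shape (N, F')
    coeff = gcn_coefficients(src, dst, w, n_nodes)
    msg = hw.gather_rows(src) * coeff[:, None]
    return msg.scatter_add_rows(dst, n_nodes) + b


def gat_layer(
    h: Tensor, src, dst, w, n_nodes: int,
    W: Tensor, b: Tensor, a_src: Tensor, a_dst: Tensor, a_edge: Tensor,
    leaky_slope: float = LEAKY_SLOPE,
) -> Tensor:
    """Single-head graph attention without self-loops.

    Logit for the message j→i:
    e_ij = LeakyReLU(a_dst·(H_i W) + a_src·(H_j W) + a_edge · w_ij);
    α softmax-normalized over each node's in-neighbourhood.
    """
    hw = h @ W
    if len(src) == 0:
        return hw * 0.0 + b
    e = (
        (hw.gather_rows(dst) * a_dst.reshape(1, -1)).sum(axis=1)
        + (hw.gather_rows(src) * a_src.reshape(1, -1)).sum(axis=1)
        + a_edge * Tensor(w)
    ).leaky_relu(leaky_slope)
    # per-destination max subtraction (detached) for a stable softmax
    m = np.full(n_nodes, -np.inf)
    np.maximum.at(m, dst, e.value)
    ez = (e - m[dst]).exp()
    denom = ez.scatter_add_rows(dst, n_nodes).gather_rows(dst)
    alpha = ez / denom
    msg = hw.gather_rows(src) * alpha.reshape(-1, 1)
    return msg.scatter_add_rows(dst, n_nodes) + b


def batch_norm(
    h: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running: tuple[np.ndarray, np.ndarray],
    mode: str,
    momentum: float = BN_MOMENTUM,
    eps: float = BN_EPS,
) -> Tensor:
    """Per-feature batch normalization over all node rows.

    In train mode the batch statistics are used (biased variance, as is
    conventional) and the running stats in ``running`` are updated in
    place with the given momentum; eval mode uses the running stats and
    performs no update.
    """
    rm, rv = running
    if mode == "train":
        n = h.shape[0]
        if n < 2:
            raise ValueError("batch_norm: train mode needs at least 2 node rows")
        mu = h.mean(axis=0, keepdims=True)
        var = ((h - mu) * (h - mu)).mean(axis=0, keepdims=True)
        rm *= 1.0 - momentum
        rm += momentum * mu.value[0]
        rv *= 1.0 - momentum
        rv += momentum * var.value[0] * n / (n - 1)  # unbiased for the running stat
        norm = (h - mu) / (var + eps).sqrt()
    elif mode == "eval":
        norm = (h - Tensor(rm[None, :])) / Tensor(np.sqrt(rv[None, :] + eps))
    else:
        raise ValueError(f"unknown batch_norm mode {mode!r}")
    return norm * gamma.reshape(1, -1) + beta.reshape(1, -1)


# --------------------------------------------------------------------------
# full forward pass
# --------------------------------------------------------------------------

def forward_tensor(
    batch: GraphBatch,
    params: ModelParams,
    mode: str = "eval",
    leaves: dict[str, Tensor] | None = None,
) -> Tensor:
    """Per-graph predictions as a Tensor of shape (n_graphs,).

    ``leaves`` may supply pre-wrapped parameter Tensors (used by the
    trainer so gradients can be read back); otherwise fresh constants are
    created.
    """
    if batch.x.shape[1] != params.dims.f_in:
        raise ValueError(
            f"node feature width {batch.x.shape[1]} != model F_in {params.dims.f_in}"
        )
    if leaves is None:
        leaves = {k: Tensor(v) for k, v in params.arrays.items()
                  if not k.startswith(("rm", "rv"))}
    t = lambda k: leaves[k]
    h = Tensor(batch.x)
    src, dst, w, n = batch.src, batch.dst, batch.w, batch.x.shape[0]

    for layer in (1, 2, 3, 4):
        if params.attention and layer in (2, 3):
            h = gat_layer(
                h, src, dst, w, n,
                t(f"W{layer}"), t(f"b{layer}"),
                t(f"a{layer}s"), t(f"a{layer}d"), t(f"a{layer}e"),
            )
        else:
            h = gcn_layer(h, src, dst, w, n, t(f"W{layer}"), t(f"b{layer}"))
        if layer < 4 or params.final_norm:
            h = batch_norm(
                h, t(f"g{layer}"), t(f"s{layer}"),
                (params.arrays[f"rm{layer}"], params.arrays[f"rv{layer}"]),
                mode,
            )
            h = h.elu()

    pooled = h.scatter_add_rows(batch.graph_index, batch.n_graphs)
    counts = np.bincount(batch.graph_index, minlength=batch.n_graphs).astype(float)
    mean = pooled / counts[:, None]
    raw = mean.reshape(batch.n_graphs)
    return raw * params.label_std + params.label_mean


def forward(
    graphs: list[MolecularGraph] | MolecularGraph,
    params: ModelParams,
    mode: str = "eval",
) -> np.ndarray:
    """Predicted absorption maxima, one per graph, in the model's target unit."""
    if isinstance(graphs, MolecularGraph):
        graphs = [graphs]
    batch = GraphBatch.from_graphs(graphs)
    return forward_tensor(batch, params, mode=mode).value.copy()


# --------------------------------------------------------------------------
# checkpointing
# --------------------------------------------------------------------------

def save_checkpoint(
    params: ModelParams,
    path: str | Path,
    feature_columns: list[str] | None = None,
    norm_stats=None,
    target_units: str = "nm",
    extra_meta: dict | None = None,
) -> None:
    """Self-sufficient JSON checkpoint: dims, weights, BN state, feature
    schema + normalization, target unit and provenance metadata."""
    payload = {
        "format": "rhopocket-checkpoint-v1",
        "dims": [params.dims.f_in, params.dims.a, params.dims.b, params.dims.c],
        "attention": params.attention,
        "final_norm": params.final_norm,
        "label_mean": params.label_mean,
        "label_std": params.label_std,
        "arrays": {k: v.tolist() for k, v in params.arrays.items()},
        "target_units": target_units,
        "feature_columns": feature_columns,
        "meta": {**params.meta, **(extra_meta or {})},
    }
    if norm_stats is not None:
        payload["norm_stats"] = {
            "mean": norm_stats.mean.tolist(),
            "std": norm_stats.std.tolist(),
            "retained_mask": norm_stats.retained_mask.astype(int).tolist(),
        }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path):
    """Load a checkpoint; returns (ModelParams, info dict).

    ``info`` carries target_units, feature_columns and, if present, the
    reconstructed NormalizationStats.
    """
    try:
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "rhopocket-checkpoint-v1":
            raise ValueError(f"not a rhopocket checkpoint: {path}")
        dims = LayerDims(*payload["dims"])
        arrays = {
            k: np.array(v, dtype=float) for k, v in payload["arrays"].items()
        }
        params = ModelParams(
            arrays=arrays,
            dims=dims,
            attention=bool(payload["attention"]),
            final_norm=bool(payload.get("final_norm", False)),
            label_mean=float(payload["label_mean"]),
            label_std=float(payload["label_std"]),
            meta=payload.get("meta", {}),
        )
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"corrupted checkpoint {path}: {exc}") from exc
    info = {
        "target_units": payload.get("target_units", "nm"),
        "feature_columns": payload.get("feature_columns"),
        "norm_stats": None,
    }
    if payload.get("norm_stats") is not None:
        from .features import NormalizationStats

        ns = payload["norm_stats"]
        info["norm_stats"] = NormalizationStats(
            mean=np.array(ns["mean"]),
            std=np.array(ns["std"]),
            retained_mask=np.array(ns["retained_mask"], dtype=bool),
        )
    return params, info
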
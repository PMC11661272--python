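"""Graph-transformer networks over the residue and atomic graphs.

Two networks share one architecture family:

* ``ResidueNet`` — six message-passing layers of width 150 with a single
  attention head, over the residue graph.  Readout heads predict the six
  global physicochemical targets (solvation free energy, radius of
  gyration, hydrodynamic radius, translational/rotational diffusion,
  volume), molecular SASA, residue-level SASA and residue pKa.
* ``LocalChargeNet`` — three layers of width 75 with three attention heads,
  over the atomic environment graph, with a pKa readout head.

Each message-passing layer transforms the 300-dimensional Gaussian-smeared
edge features to the node width through a two-layer shifted-softplus MLP,
attends over in-neighbors (scaled dot-product attention with the edge term
added to both keys and values), and applies a gated residual update

    h^(l+1) = h^(l) + ReLU(LayerNorm(W_R ssp(hhat^(l)) + b_R)).

Pooling readouts (global mean, radius-restricted means, target-residue
means) are concatenated exactly as the architecture prescribes: 7 x 150 =
1050 features for residue-level pKa, 3 x 75 = 225 for the atomic variant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import (
    Parameter,
    Tensor,
    concat,
    dropout,
    gather,
    layer_norm,
    relu,
    segment_mean,
    segment_softmax,
    segment_sum,
    shifted_softplus,
)
from .featurize import ATOMIC_RBF, RESIDUE_RBF, AtomGraph, ResidueGraph

__all__ = [
    "Module",
    "Linear",
    "MLP",
    "Embedding",
    "MessagePassingLayer",
    "ResidueNet",
    "LocalChargeNet",
    "GraphBatch",
    "batch_residue_graphs",
    "batch_atom_graphs",
    "readout_global",
    "readout_sasa",
    "readout_rsasa",
    "readout_pka_residue",
    "readout_pka_atomic",
    "save_model",
    "load_model",
    "PKA_RADII",
]

PKA_RADII: tuple[float, ...] = (6.0, 8.0, 10.0, 12.0, 15.0)

GLOBAL_TASKS: tuple[str, ...] = ("dG_sol", "Rg", "Rh", "Dt", "Dr", "V")

# Continuous encoder inputs are standardized by fixed nominal scales so they
# enter the feed-forward encoders with roughly unit variance: protein partial
# charges have a spread of about 0.25 e, and Calpha-to-center-of-mass
# distances are of order 10 A.
CHARGE_INPUT_SCALE = 1.0 / 0.25
DCOM_INPUT_SCALE = 1.0 / 10.0


class Module:
    """Tiny parameter-container base class."""

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out[f"{key}.{i}"] = item
            elif isinstance(value, dict):
                for k, item in value.items():
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{k}."))
        return out

    def zero_grad(self) -> None:
        for p in self.named_parameters().values():
            p.grad = None


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Parameter(_glorot(rng, n_in, n_out))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLP(Module):
    """Feed-forward stack with shifted-softplus between the linear maps."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = shifted_softplus(x)
        return x


class Embedding(Module):
    """Learned lookup table for discrete inputs (amino acid, atom type)."""

    def __init__(self, n: int, dim: int, rng: np.random.Generator):
        self.W = Parameter(rng.normal(0.0, 1.0, size=(n, dim)))

    def __call__(self, index: np.ndarray) -> Tensor:
        index = np.asarray(index)
        if index.size and (index.min() < 0 or index.max() >= self.W.data.shape[0]):
            raise ValueError("unknown discrete index in embedding lookup")
        return gather(self.W, index)


class PkaHead(Module):
    """Six linear layers (1024 hidden), five SSP activations, 20% dropout.

    Dropout is applied to the input of every linear map and is active only
    in training mode; inference is deterministic.
    """

    def __init__(self, n_in: int, rng: np.random.Generator, hidden: int = 1024, p_drop: float = 0.2):
        dims = [n_in, hidden, hidden, hidden, hidden, hidden, 1]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.p_drop = p_drop

    def __call__(self, x: Tensor, training: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        rng = rng or np.random.default_rng(0)
        for i, layer in enumerate(self.layers):
            x = dropout(x, self.p_drop, rng, training)
            x = layer(x)
            if i < len(self.layers) - 1:
                x = shifted_softplus(x)
        return x


class GlobalHead(Module):
    """Four linear layers with 1024 hidden channels and three SSP activations."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, hidden: int = 1024):
        self.mlp = MLP([n_in, hidden, hidden, hidden, n_out], rng)

    def __call__(self, x: Tensor, training: bool = False, rng=None) -> Tensor:
        return self.mlp(x)


class MessagePassingLayer(Module):
    """Transformer-style attention message passing with edge features.

    The raw edge feature (K = 300 Gaussians) is mapped to the node width by
    an affine/ssp/affine transform, split across heads, and added to both
    the keys and the values.  Attention logits are scaled dot products over
    each node's in-neighbors; nodes without in-edges receive a zero message
    and are carried by the residual path.
    """

    def __init__(self, width: int, n_heads: int, edge_dim: int, rng: np.random.Generator):
        if width % n_heads:
            raise ValueError("width must be divisible by the head count")
        self.width = width
        self.n_heads = n_heads
        self.head_dim = width // n_heads
        self.edge1 = Linear(edge_dim, width, rng)
        self.edge2 = Linear(width, width, rng)
        self.query = Linear(width, width, rng)
        self.key = Linear(width, width, rng)
        self.value = Linear(width, width, rng)
        self.residual = Linear(width, width, rng)
        self.ln_gain = Parameter(np.ones(width))
        self.ln_bias = Parameter(np.zeros(width))

    def transform_edges(self, edge_attr: Tensor) -> Tensor:
        return self.edge2(shifted_softplus(self.edge1(edge_attr)))

    def __call__(
        self,
        h: Tensor,
        edge_src: np.ndarray,
        edge_dst: np.ndarray,
        edge_attr: Tensor,
        n_nodes: int,
    ) -> Tensor:
        H, D = self.n_heads, self.head_dim
        n_edges = len(edge_src)
        if n_edges:
            ec = self.transform_edges(edge_attr).reshape(n_edges, H, D)
            q = gather(self.query(h), edge_dst).reshape(n_edges, H, D)
            k = gather(self.key(h), edge_src).reshape(n_edges, H, D) + ec
            v = gather(self.value(h), edge_src).reshape(n_edges, H, D) + ec
            logits = (q * k).sum(axis=2) * (1.0 / math.sqrt(D))
            alpha = segment_softmax(logits, edge_dst, n_nodes)
            msg = alpha.reshape(n_edges, H, 1) * v
            hhat = segment_sum(msg, edge_dst, n_nodes).reshape(n_nodes, self.width)
        else:
            hhat = Tensor(np.zeros((n_nodes, self.width)))
        update = relu(
            layer_norm(self.residual(shifted_softplus(hhat)), self.ln_gain, self.ln_bias)
        )
        return h + update

    def attention_weights(self, h, edge_src, edge_dst, edge_attr, n_nodes) -> np.ndarray:
        """Per-edge attention coefficients (E, heads); diagnostics only."""
        H, D = self.n_heads, self.head_dim
        n_edges = len(edge_src)
        ec = self.transform_edges(edge_attr).reshape(n_edges, H, D)
        q = gather(self.query(h), edge_dst).reshape(n_edges, H, D)
        k = gather(self.key(h), edge_src).reshape(n_edges, H, D) + ec
        logits = (q * k).sum(axis=2) * (1.0 / math.sqrt(D))
        return segment_softmax(logits, edge_dst, n_nodes).data


# ---------------------------------------------------------------------------
# Batching


@dataclass
class GraphBatch:
    """Disjoint union of graphs with per-node graph ids."""

    node_graph: np.ndarray          # (N,) graph id per node
    n_graphs: int
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_attr: np.ndarray           # (E, K)
    aa_index: np.ndarray
    # residue-graph fields
    dihedrals: np.ndarray | None = None
    d_com: np.ndarray | None = None
    ca_positions: np.ndarray | None = None
    # atom-graph fields
    atom_type: np.ndarray | None = None
    charge: np.ndarray | None = None
    target_ca: np.ndarray | None = None     # (B,) global node index per graph
    in_target: np.ndarray | None = None     # (N,) bool

    @property
    def n_nodes(self) -> int:
        return len(self.node_graph)


def _offsets(graphs) -> np.ndarray:
    sizes = [g.n_nodes for g in graphs]
    return np.concatenate([[0], np.cumsum(sizes)])


def batch_residue_graphs(graphs: Sequence[ResidueGraph]) -> GraphBatch:
    off = _offsets(graphs)
    return GraphBatch(
        node_graph=np.concatenate(
            [np.full(g.n_nodes, i, dtype=np.intp) for i, g in enumerate(graphs)]
        ),
        n_graphs=len(graphs),
        edge_src=np.concatenate([g.edge_src + off[i] for i, g in enumerate(graphs)]),
        edge_dst=np.concatenate([g.edge_dst + off[i] for i, g in enumerate(graphs)]),
        edge_attr=np.concatenate([g.edge_attr for g in graphs]),
        aa_index=np.concatenate([g.aa_index for g in graphs]),
        dihedrals=np.concatenate([g.dihedrals for g in graphs]),
        d_com=np.concatenate([g.d_com for g in graphs]),
        ca_positions=np.concatenate([g.ca_positions for g in graphs]),
    )


def batch_atom_graphs(graphs: Sequence[AtomGraph]) -> GraphBatch:
    off = _offsets(graphs)
    return GraphBatch(
        node_graph=np.concatenate(
            [np.full(g.n_nodes, i, dtype=np.intp) for i, g in enumerate(graphs)]
        ),
        n_graphs=len(graphs),
        edge_src=np.concatenate([g.edge_src + off[i] for i, g in enumerate(graphs)]),
        edge_dst=np.concatenate([g.edge_dst + off[i] for i, g in enumerate(graphs)]),
        edge_attr=np.concatenate([g.edge_attr for g in graphs]),
        aa_index=np.concatenate([g.aa_index for g in graphs]),
        atom_type=np.concatenate([g.atom_type for g in graphs]),
        charge=np.concatenate([g.charge for g in graphs]),
        target_ca=np.array([g.target_ca + off[i] for i, g in enumerate(graphs)], dtype=np.intp),
        in_target=np.concatenate([g.in_target for g in graphs]),
    )


# ---------------------------------------------------------------------------
# Networks


class ResidueNet(Module):
    """Residue-level graph transformer producing 150-d node embeddings."""

    WIDTH = 150
    N_LAYERS = 6
    N_HEADS = 1

    def __init__(
        self,
        seed: int = 0,
        aa_emb_dim: int = 64,
        cont_dim: int = 32,
        head_hidden: int = 1024,
    ):
        rng = np.random.default_rng(seed)
        self.config = {
            "kind": "ResidueNet",
            "seed": seed,
            "width": self.WIDTH,
            "n_layers": self.N_LAYERS,
            "n_heads": self.N_HEADS,
            "aa_emb_dim": aa_emb_dim,
            "cont_dim": cont_dim,
            "head_hidden": head_hidden,
            "rbf": {"K": RESIDUE_RBF.K, "r_max": RESIDUE_RBF.r_max},
            "edge_cutoff": RESIDUE_RBF.r_max,
            "com_convention": "mass-weighted over parsed atoms",
        }
        self.aa_emb = Embedding(20, aa_emb_dim, rng)
        self.dihedral_enc = MLP([15, cont_dim, cont_dim], rng)
        self.dcom_enc = MLP([1, cont_dim, cont_dim], rng)
        self.reduce = Linear(aa_emb_dim + 2 * cont_dim, self.WIDTH, rng)
        self.layers = [
            MessagePassingLayer(self.WIDTH, self.N_HEADS, RESIDUE_RBF.K, rng)
            for _ in range(self.N_LAYERS)
        ]
        self.heads = {
            "global": GlobalHead(self.WIDTH, 6, rng, head_hidden),
            "sasa": GlobalHead(self.WIDTH, 1, rng, head_hidden),
            "rsasa": GlobalHead(self.WIDTH, 1, rng, head_hidden),
            "pka": PkaHead(7 * self.WIDTH, rng, head_hidden),
        }
        self.norm_stats: dict[str, dict[str, list[float]]] = {}

    # -- forward --------------------------------------------------------

    def encode_nodes(self, batch: GraphBatch) -> Tensor:
        """Per-node 150-d input features from discrete + continuous inputs."""
        parts = [
            self.aa_emb(batch.aa_index),
            self.dihedral_enc(Tensor(batch.dihedrals)),
            self.dcom_enc(Tensor(batch.d_com[:, None] * DCOM_INPUT_SCALE)),
        ]
        return self.reduce(concat(parts, axis=1))

    def embed(self, batch: GraphBatch) -> Tensor:
        h = self.encode_nodes(batch)
        edge_attr = Tensor(batch.edge_attr)
        for layer in self.layers:
            h = layer(h, batch.edge_src, batch.edge_dst, edge_attr, batch.n_nodes)
        return h

    def forward_task(
        self,
        task: str,
        batch: GraphBatch,
        node_index: np.ndarray | None = None,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Normalized-space predictions for a task.

        ``node_index`` selects target nodes (global ids) for the residue-level
        tasks ("rsasa", "pka"); the global tasks pool over each graph.
        """
        h = self.embed(batch)
        if task in ("global", "sasa"):
            feats = segment_mean(h, batch.node_graph, batch.n_graphs)
        elif task == "rsasa":
            feats = gather(h, node_index)
        elif task == "pka":
            feats = pka_features_residue(h, batch, node_index)
        else:
            raise KeyError(f"unknown task {task!r}")
        return self.heads[task](feats, training=training, rng=rng)

    # -- normalization ---------------------------------------------------

    def set_normalization(self, task: str, mean, std) -> None:
        self.norm_stats[task] = {
            "mean": np.atleast_1d(np.asarray(mean, dtype=float)).tolist(),
            "std": np.atleast_1d(np.asarray(std, dtype=float)).tolist(),
        }

    def denormalize(self, task: str, z: np.ndarray) -> np.ndarray:
        if task not in self.norm_stats:
            raise ValueError(f"no normalization stats stored for task {task!r}")
        st = self.norm_stats[task]
        return np.asarray(z) * np.array(st["std"]) + np.array(st["mean"])


def pka_features_residue(h: Tensor, batch: GraphBatch, node_index: np.ndarray) -> Tensor:
    """Concatenate (h_i, mu_6, mu_8, mu_10, mu_12, mu_15, mu) per target node.

    Radius subsets contain every residue whose Cα lies within r Å of the
    target residue's Cα (inclusive of the target itself).  A subset can
    never be empty — it contains at least the target — but if membership
    degenerates the target embedding itself is the fallback.
    """
    node_index = np.asarray(node_index, dtype=np.intp)
    B = len(node_index)
    h_i = gather(h, node_index)
    mu = segment_mean(h, batch.node_graph, batch.n_graphs)
    mu_rows = gather(mu, batch.node_graph[node_index])
    ca = batch.ca_positions
    parts: list[Tensor] = [h_i]
    target_graph = batch.node_graph[node_index]
    for r in PKA_RADII:
        rows_list = []
        seg_list = []
        for b in range(B):
            g = target_graph[b]
            in_graph = np.nonzero(batch.node_graph == g)[0]
            d = np.linalg.norm(ca[in_graph] - ca[node_index[b]], axis=1)
            members = in_graph[d <= r]
            if members.size == 0:
                members = np.array([node_index[b]], dtype=np.intp)
            rows_list.append(members)
            seg_list.append(np.full(members.size, b, dtype=np.intp))
        rows = np.concatenate(rows_list)
        segs = np.concatenate(seg_list)
        parts.append(segment_mean(gather(h, rows), segs, B))
    parts.append(mu_rows)
    return concat(parts, axis=1)


class LocalChargeNet(Module):
    """Atomic charge-aware graph transformer producing 75-d embeddings."""

    WIDTH = 75
    N_LAYERS = 3
    N_HEADS = 3

    def __init__(
        self,
        seed: int = 0,
        aa_emb_dim: int = 64,
        type_emb_dim: int = 32,
        cont_dim: int = 32,
        head_hidden: int = 1024,
    ):
        rng = np.random.default_rng(seed)
        self.config = {
            "kind": "LocalChargeNet",
            "seed": seed,
            "width": self.WIDTH,
            "n_layers": self.N_LAYERS,
            "n_heads": self.N_HEADS,
            "aa_emb_dim": aa_emb_dim,
            "type_emb_dim": type_emb_dim,
            "cont_dim": cont_dim,
            "head_hidden": head_hidden,
            "rbf": {"K": ATOMIC_RBF.K, "r_max": ATOMIC_RBF.r_max},
            "selection_radius": 10.0,
            "edge_cutoff": ATOMIC_RBF.r_max,
        }
        self.aa_emb = Embedding(20, aa_emb_dim, rng)
        self.type_emb = Embedding(5, type_emb_dim, rng)
        self.charge_enc = MLP([1, cont_dim, cont_dim], rng)
        self.reduce = Linear(aa_emb_dim + type_emb_dim + cont_dim, self.WIDTH, rng)
        self.layers = [
            MessagePassingLayer(self.WIDTH, self.N_HEADS, ATOMIC_RBF.K, rng)
            for _ in range(self.N_LAYERS)
        ]
        self.heads = {"pka": PkaHead(3 * self.WIDTH, rng, head_hidden)}
        self.norm_stats: dict[str, dict[str, list[float]]] = {}

    def encode_nodes(self, batch: GraphBatch) -> Tensor:
        parts = [
            self.aa_emb(batch.aa_index),
            self.type_emb(batch.atom_type),
            self.charge_enc(Tensor(batch.charge[:, None] * CHARGE_INPUT_SCALE)),
        ]
        return self.reduce(concat(parts, axis=1))

    def embed(self, batch: GraphBatch) -> Tensor:
        h = self.encode_nodes(batch)
        edge_attr = Tensor(batch.edge_attr)
        for layer in self.layers:
            h = layer(h, batch.edge_src, batch.edge_dst, edge_attr, batch.n_nodes)
        return h

    def forward_task(
        self,
        task: str,
        batch: GraphBatch,
        node_index: np.ndarray | None = None,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        if task != "pka":
            raise KeyError(f"unknown task {task!r}")
        h = self.embed(batch)
        feats = pka_features_atomic(h, batch)
        return self.heads["pka"](feats, training=training, rng=rng)

    set_normalization = ResidueNet.set_normalization
    denormalize = ResidueNet.denormalize


def pka_features_atomic(h: Tensor, batch: GraphBatch) -> Tensor:
    """Concatenate (h_Ca, mu_aa, mu) per graph (3 x width features)."""
    if batch.in_target is None or not batch.in_target.any():
        raise ValueError("no atom flagged as belonging to the target residue")
    h_ca = gather(h, batch.target_ca)
    rows = np.nonzero(batch.in_target)[0]
    mu_aa = segment_mean(gather(h, rows), batch.node_graph[rows], batch.n_graphs)
    mu = segment_mean(h, batch.node_graph, batch.n_graphs)
    return concat([h_ca, mu_aa, mu], axis=1)


# ---------------------------------------------------------------------------
# Single-graph readouts (inference)


def readout_global(net: ResidueNet, graph: ResidueGraph) -> np.ndarray:
    """De-normalized predictions of the six global targets for one structure."""
    z = net.forward_task("global", batch_residue_graphs([graph])).data[0]
    return net.denormalize("global", z)


def readout_sasa(net: ResidueNet, graph: ResidueGraph) -> float:
    z = net.forward_task("sasa", batch_residue_graphs([graph])).data[0]
    return float(net.denormalize("sasa", z)[0])


def readout_rsasa(net: ResidueNet, graph: ResidueGraph, residue: int) -> float:
    z = net.forward_task(
        "rsasa", batch_residue_graphs([graph]), node_index=np.array([residue])
    ).data[0]
    return float(net.denormalize("rsasa", z)[0])


def readout_pka_residue(net: ResidueNet, graph: ResidueGraph, residue: int) -> float:
    if not 0 <= residue < graph.n_nodes:
        raise IndexError(f"residue index {residue} out of range")
    z = net.forward_task(
        "pka", batch_residue_graphs([graph]), node_index=np.array([residue])
    ).data[0]
    return float(net.denormalize("pka", z)[0])


def readout_pka_atomic(net: LocalChargeNet, graph: AtomGraph) -> float:
    z = net.forward_task("pka", batch_atom_graphs([graph])).data[0]
    return float(net.denormalize("pka", z)[0])


# ---------------------------------------------------------------------------
# Serialization


def save_model(net: ResidueNet | LocalChargeNet, path: str | Path) -> None:
    """Persist parameters, config snapshot and normalization stats (.npz)."""
    header = {
        "format_version": 1,
        "config": net.config,
        "norm_stats": net.norm_stats,
    }
    params = {k: p.data for k, p in net.named_parameters().items()}
    np.savez(path, __header__=np.array(json.dumps(header)), **params)


def load_model(path: str | Path) -> ResidueNet | LocalChargeNet:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["__header__"]))
        params = {k: np.array(data[k]) for k in data.files if k != "__header__"}
    cfg = header["config"]
    if cfg["kind"] == "ResidueNet":
        net = ResidueNet(
            seed=cfg["seed"],
            aa_emb_dim=cfg["aa_emb_dim"],
            cont_dim=cfg["cont_dim"],
            head_hidden=cfg["head_hidden"],
        )
    else:
        net = LocalChargeNet(
            seed=cfg["seed"],
            aa_emb_dim=cfg["aa_emb_dim"],
            type_emb_dim=cfg["type_emb_dim"],
            cont_dim=cfg["cont_dim"],
            head_hidden=cfg["head_hidden"],
        )
    own = net.named_parameters()
    for k, arr in params.items():
        own[k].data[...] = arr
    net.norm_stats = header["norm_stats"]
    return net
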
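"""Multi-task training with masked losses, transfer regimes and selection.

The training protocol mirrors the architecture's published recipe: Adam
with an initial learning rate of 1e-4 stepped to 1e-5 after 50 epochs,
batch size 64, mean-squared-error loss over normalized targets, a binary
mask that zeroes the loss (and hence the gradients) for examples whose
solvation-free-energy reference is missing, early stopping after ten
epochs without validation improvement, and best-epoch checkpointing.

Transfer regimes are expressed through parameter freezing: the "frozen"
regimes update only the readout head while the message-passing trunk and
encoders keep their pre-trained weights bit-for-bit; the "optimized"
regimes fine-tune everything.

Target normalization uses the mean and population standard deviation of
the training rows only, applied identically to every split, and the stats
are stored with the model so predictions de-normalize deterministically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .autodiff import Parameter, Tensor
from .nn import (
    GraphBatch,
    LocalChargeNet,
    ResidueNet,
    batch_atom_graphs,
    batch_residue_graphs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TaskSpec",
    "GraphDataset",
    "TrainResult",
    "DivergenceError",
    "masked_mse",
    "normalize_targets",
    "Adam",
    "train",
    "multi_run_select",
]


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class TrainConfig:
    """Optimizer schedule and stopping rules."""

    lr_initial: float = 1e-4
    lr_after_step: float = 1e-5
    lr_step_epoch: int = 50
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    seed: int = 0

    def lr_at(self, epoch: int) -> float:
        return self.lr_initial if epoch < self.lr_step_epoch else self.lr_after_step

    @classmethod
    def desk_scale(cls, max_epochs: int = 25, seed: int = 0) -> "TrainConfig":
        """Scaled-down protocol for datasets of a few hundred examples.

        The published schedule (lr 1e-4, batch 64) presumes tens of
        thousands of optimizer steps per epoch; with a few hundred
        examples an epoch is a handful of steps, so the desk-scale
        protocol keeps the step budget meaningful with batch 16 and a
        proportionally larger initial learning rate (3e-4, stepped down
        by 10x on the same schedule shape).
        """
        return cls(
            lr_initial=3e-4,
            lr_after_step=3e-5,
            lr_step_epoch=50,
            batch_size=16,
            max_epochs=max_epochs,
            patience=10,
            seed=seed,
        )


@dataclass
class TaskSpec:
    """Which head is trained and whether the trunk is frozen."""

    name: str
    head: str                      # head key on the network ("global", "pka", ...)
    frozen_gnn: bool = False
    target_columns: tuple[str, ...] = ()
    mask_column: str | None = None


@dataclass
class GraphDataset:
    """Featurized examples for one task.

    For graph-level tasks each example is one graph; for residue-level
    tasks ``node_index`` holds the local index of the target node within
    its graph.
    """

    graphs: list
    targets: np.ndarray            # (N, T) in native units
    mask: np.ndarray | None = None  # (N, T) in {0,1}
    node_index: np.ndarray | None = None
    kind: str = "residue"          # "residue" | "atom"

    def __post_init__(self):
        self.targets = np.atleast_2d(np.asarray(self.targets, dtype=float))
        if self.targets.shape[0] != len(self.graphs):
            self.targets = self.targets.T
        if self.mask is not None:
            self.mask = np.atleast_2d(np.asarray(self.mask, dtype=float))
            if self.mask.shape != self.targets.shape:
                self.mask = self.mask.T

    def __len__(self) -> int:
        return len(self.graphs)

    def batch(self, idx: np.ndarray) -> tuple[GraphBatch, np.ndarray | None]:
        graphs = [self.graphs[i] for i in idx]
        if self.kind == "atom":
            gb = batch_atom_graphs(graphs)
        else:
            gb = batch_residue_graphs(graphs)
        node_index = None
        if self.node_index is not None:
            sizes = np.array([g.n_nodes for g in graphs])
            offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
            node_index = self.node_index[idx] + offsets
        return gb, node_index


def masked_mse(pred: Tensor, target: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
    """MSE over unmasked entries; exactly-zero gradient for masked ones."""
    target = np.asarray(target, dtype=float)
    diff = pred - Tensor(target)
    sq = diff * diff
    if mask is None:
        return sq.mean()
    mask = np.asarray(mask, dtype=float)
    n = mask.sum()
    if n == 0:
        logger.warning("all entries masked: loss is 0 with zero gradient")
        return Tensor(0.0)
    return (sq * Tensor(mask)).sum() * (1.0 / n)


def normalize_targets(
    targets: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column mean/std (population, over unmasked training rows only).

    Returns (mean, std, normalized) where masked entries normalize with the
    same stats (their loss contribution is removed by the mask, not here).
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if mask is None:
        mask = np.ones_like(targets)
    mean = np.empty(targets.shape[1])
    std = np.empty(targets.shape[1])
    for j in range(targets.shape[1]):
        rows = mask[:, j] > 0
        if not rows.any():
            # a task with no references at all: neutral stats; every loss
            # contribution for this column is masked out anyway
            logger.warning("target column %d has no unmasked training rows", j)
            mean[j], std[j] = 0.0, 1.0
            continue
        col = targets[rows, j]
        mean[j] = col.mean()
        std[j] = col.std()  # population convention (divide by N)
        if std[j] == 0:
            raise ValueError(f"target column {j} has zero variance in the training set")
    return mean, std, (targets - mean) / std


class Adam(object):
    """Adam over a named parameter dict, with an external lr schedule."""

    def __init__(
        self,
        params: dict[str, Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            p.data -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _trainable_parameters(net, task: TaskSpec) -> dict[str, Parameter]:
    params = net.named_parameters()
    if not task.frozen_gnn:
        return params
    return {k: p for k, p in params.items() if k.startswith(f"heads.{task.head}.")}


@dataclass
class TrainResult:
    net: ResidueNet | LocalChargeNet
    task: TaskSpec
    config: TrainConfig
    log: pd.DataFrame = field(repr=False)
    best_epoch: int = -1
    best_val_loss: float = math.inf

    @property
    def best_val_rmse(self) -> float:
        return math.sqrt(self.best_val_loss)


def _forward(net, task, gb, node_index, training, rng):
    return net.forward_task(task.head, gb, node_index=node_index, training=training, rng=rng)


def _eval_loss(net, task, dataset, norm_targets, batch_size=256) -> float:
    total, count = 0.0, 0.0
    for start in range(0, len(dataset), batch_size):
        idx = np.arange(start, min(start + batch_size, len(dataset)))
        gb, node_index = dataset.batch(idx)
        pred = _forward(net, task, gb, node_index, training=False, rng=None)
        mask = dataset.mask[idx] if dataset.mask is not None else np.ones_like(norm_targets[idx])
        total += float(((pred.data - norm_targets[idx]) ** 2 * mask).sum())
        count += float(mask.sum())
    return total / max(count, 1.0)


def train(
    net: ResidueNet | LocalChargeNet,
    task: TaskSpec,
    train_set: GraphDataset,
    val_set: GraphDataset,
    config: TrainConfig,
) -> TrainResult:
    """Train one head (optionally the full network) on a dataset.

    Honors the learning-rate step, early stopping with patience, NaN abort,
    best-epoch checkpointing, and the frozen-trunk regime (frozen
    parameters are bit-identical before and after).
    """
    rng = np.random.default_rng(config.seed)
    mean, std, ytrain = normalize_targets(train_set.targets, train_set.mask)
    net.set_normalization(task.head, mean, std)
    yval = (val_set.targets - mean) / std

    trainable = _trainable_parameters(net, task)
    opt = Adam(trainable, lr=config.lr_initial, betas=config.adam_betas, eps=config.adam_eps)

    rows = []
    best_val = math.inf
    best_epoch = -1
    best_state: dict[str, np.ndarray] | None = None
    stale = 0
    n = len(train_set)
    for epoch in range(config.max_epochs):
        opt.lr = config.lr_at(epoch)
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            gb, node_index = train_set.batch(idx)
            pred = _forward(net, task, gb, node_index, training=True, rng=rng)
            mask = train_set.mask[idx] if train_set.mask is not None else None
            loss = masked_mse(pred, ytrain[idx], mask)
            if not np.isfinite(loss.data):
                raise DivergenceError(f"loss became {loss.data} at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            seen += len(idx)
        val_loss = _eval_loss(net, task, val_set, yval)
        rows.append(
            {"epoch": epoch, "lr": opt.lr, "train_loss": epoch_loss / max(seen, 1), "val_loss": val_loss}
        )
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_state = {k: p.data.copy() for k, p in trainable.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_state is not None:
        for k, arr in best_state.items():
            trainable[k].data[...] = arr
    return TrainResult(
        net=net,
        task=task,
        config=config,
        log=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_val_loss=best_val,
    )


def multi_run_select(
    run_fn: Callable[[int], TrainResult],
    seeds: Sequence[int],
    rule: str = "best",
    top_k: int = 10,
) -> list[TrainResult]:
    """Run ``run_fn`` once per seed and select by validation performance.

    ``rule="best"`` returns the single run with the lowest validation MSE;
    ``rule="top_k"`` returns the ``top_k`` runs ranked by validation RMSE.
    Ties break by seed order (stable sort over input order).
    """
    results = [run_fn(seed) for seed in seeds]
    order = sorted(range(len(results)), key=lambda i: (results[i].best_val_loss, i))
    if rule == "best":
        return [results[order[0]]]
    if rule == "top_k":
        return [results[i] for i in order[:top_k]]
    raise ValueError(f"unknown selection rule {rule!r}")


def parameter_fingerprint(net, prefix: str = "") -> dict[str, float]:
    """Cheap audit hash (sums) of parameter blocks, e.g. to verify freezing."""
    out = {}
    for k, p in net.named_parameters().items():
        if k.startswith(prefix):
            out[k] = float(np.sum(p.data)) + float(np.sum(np.abs(p.data)))
    return out
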
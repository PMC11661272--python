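"""Masked loss, normalization, schedules, freezing and model selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protembed.autodiff import Parameter, Tensor
from protembed.featurize import build_residue_graph
from protembed.nn import ResidueNet
from protembed.synthetic import generate_mini_protein
from protembed.training import (
    Adam,
    DivergenceError,
    GraphDataset,
    TaskSpec,
    TrainConfig,
    masked_mse,
    multi_run_select,
    normalize_targets,
    parameter_fingerprint,
    train,
)


def test_masked_mse_examples():
    pred = Tensor(np.array([[1.0], [2.0]]))
    target = np.array([[0.0], [0.0]])
    assert masked_mse(pred, target).item() == pytest.approx(2.5)
    assert masked_mse(pred, target, np.ones((2, 1))).item() == pytest.approx(2.5)
    assert masked_mse(pred, target, np.zeros((2, 1))).item() == 0.0
    assert masked_mse(pred, target, np.array([[1.0], [0.0]])).item() == pytest.approx(1.0)


def test_masked_gradients_are_exactly_zero():
    p = Parameter(np.array([[1.0, 3.0], [2.0, -1.0]]))
    mask = np.array([[1.0, 0.0], [0.0, 1.0]])
    loss = masked_mse(p, np.zeros((2, 2)), mask)
    loss.backward()
    assert p.grad[0, 1] == 0.0 and p.grad[1, 0] == 0.0
    assert p.grad[0, 0] != 0.0 and p.grad[1, 1] != 0.0


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**32 - 1))
def test_masked_mse_equals_plain_mse_on_unmasked_rows(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 20))
    pred = rng.normal(size=(n, 3))
    target = rng.normal(size=(n, 3))
    mask = (rng.random((n, 3)) < 0.6).astype(float)
    if mask.sum() == 0:
        mask[0, 0] = 1.0
    got = masked_mse(Tensor(pred), target, mask).item()
    expected = np.mean((pred[mask > 0] - target[mask > 0]) ** 2)
    assert got == pytest.approx(expected, rel=1e-12)


def test_normalize_targets_population_convention():
    mean, std, normed = normalize_targets(np.array([[1.0], [2.0], [3.0]]))
    assert mean[0] == pytest.approx(2.0)
    assert std[0] == pytest.approx(np.sqrt(2.0 / 3.0))  # divide by N
    np.testing.assert_allclose(normed.mean(axis=0), 0.0, atol=1e-12)


def test_normalize_targets_affine_invariance_and_errors():
    x = np.random.default_rng(0).normal(size=(20, 2))
    _, _, n1 = normalize_targets(x)
    _, _, n2 = normalize_targets(x + 100.0)
    np.testing.assert_allclose(n1, n2, atol=1e-9)
    with pytest.raises(ValueError, match="zero variance"):
        normalize_targets(np.ones((5, 1)))


def test_normalization_uses_only_unmasked_rows():
    x = np.array([[1.0], [2.0], [3.0], [999.0]])
    mask = np.array([[1.0], [1.0], [1.0], [0.0]])
    mean, std, _ = normalize_targets(x, mask)
    assert mean[0] == pytest.approx(2.0)


def test_fully_masked_column_gets_neutral_stats():
    x = np.array([[1.0, 5.0], [2.0, 7.0], [3.0, 9.0]])
    mask = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
    mean, std, _ = normalize_targets(x, mask)
    assert (mean[1], std[1]) == (0.0, 1.0)


def _tiny_dataset(n, seed):
    rng = np.random.default_rng(seed)
    graphs, targets = [], []
    for _ in range(n):
        s, _ = generate_mini_protein(int(rng.integers(6, 10)), 0.5, rng)
        graphs.append(build_residue_graph(s))
        targets.append(rng.normal(size=6))
    return GraphDataset(graphs, np.array(targets))


@pytest.fixture(scope="module")
def tiny_net_and_data():
    return ResidueNet(seed=0, head_hidden=32), _tiny_dataset(8, 0), _tiny_dataset(4, 1)


def test_frozen_regime_leaves_trunk_bit_identical(tiny_net_and_data):
    net, train_set, val_set = tiny_net_and_data
    import copy

    before = {k: p.data.copy() for k, p in net.named_parameters().items()}
    cfg = TrainConfig(max_epochs=2, batch_size=4, seed=0)
    task = TaskSpec(name="t", head="global", frozen_gnn=True)
    train(net, task, train_set, val_set, cfg)
    after = net.named_parameters()
    for k, arr in before.items():
        if k.startswith("heads.global."):
            continue
        assert np.array_equal(arr, after[k].data), f"frozen parameter {k} changed"
    assert any(
        not np.array_equal(before[k], after[k].data)
        for k in before
        if k.startswith("heads.global.")
    )


def test_training_is_bit_reproducible(tiny_net_and_data):
    _, train_set, val_set = tiny_net_and_data
    cfg = TrainConfig(max_epochs=2, batch_size=4, seed=3)
    task = TaskSpec(name="t", head="global")
    nets = []
    for _ in range(2):
        net = ResidueNet(seed=9, head_hidden=32)
        train(net, task, train_set, val_set, cfg)
        nets.append(net)
    p1, p2 = (n.named_parameters() for n in nets)
    for k in p1:
        assert np.array_equal(p1[k].data, p2[k].data)


def test_learning_rate_schedule_steps_at_epoch_50():
    cfg = TrainConfig()
    assert cfg.lr_at(0) == 1e-4
    assert cfg.lr_at(49) == 1e-4
    assert cfg.lr_at(50) == 1e-5


def test_early_stopping_and_best_epoch_checkpointing(tiny_net_and_data, monkeypatch):
    _, train_set, val_set = tiny_net_and_data
    net = ResidueNet(seed=1, head_hidden=32)
    # force strictly worsening validation after epoch 0
    losses = iter([1.0] + [2.0 + i for i in range(30)])
    import protembed.training as T

    monkeypatch.setattr(T, "_eval_loss", lambda *a, **k: next(losses))
    cfg = TrainConfig(max_epochs=40, batch_size=4, patience=10, seed=0)
    result = T.train(net, TaskSpec(name="t", head="global"), train_set, val_set, cfg)
    assert result.best_epoch == 0
    assert len(result.log) == 11  # best epoch + ten stale epochs


def test_multi_run_select_rules():
    class Stub:
        def __init__(self, seed, loss):
            self.best_val_loss = loss
            self.seed = seed

    losses = {0: 0.5, 1: 0.2, 2: 0.9, 3: 0.2}
    runs = {s: Stub(s, l) for s, l in losses.items()}
    best = multi_run_select(lambda s: runs[s], seeds=[0, 1, 2, 3], rule="best")
    assert len(best) == 1 and best[0].seed == 1  # tie at 0.2 broken by seed order
    top = multi_run_select(lambda s: runs[s], seeds=[0, 1, 2, 3], rule="top_k", top_k=3)
    assert [r.seed for r in top] == [1, 3, 0]
    single = multi_run_select(lambda s: runs[s], seeds=[2], rule="best")
    assert single[0].seed == 2


@pytest.mark.filterwarnings("ignore:overflow")
def test_divergent_loss_aborts(tiny_net_and_data):
    _, train_set, val_set = tiny_net_and_data
    net = ResidueNet(seed=2, head_hidden=32)
    for p in net.heads["global"].mlp.layers[0].W.data,:
        p[...] = 1e300
    with pytest.raises(DivergenceError):
        train(net, TaskSpec(name="t", head="global"), train_set, val_set,
              TrainConfig(max_epochs=1, batch_size=4, seed=0))


def test_adam_moves_parameters_toward_minimum():
    p = Parameter(np.array([5.0]))
    opt = Adam({"p": p}, lr=0.1)
    for _ in range(200):
        loss = (p * p).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert abs(p.data[0]) < 0.1
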
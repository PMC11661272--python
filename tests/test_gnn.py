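"""Network forward semantics: attention, residual updates, readouts."""

import math

import numpy as np
import pytest

from conftest import random_rotation, rigid_transform
from protembed.autodiff import Tensor, layer_norm, relu, shifted_softplus
from protembed.featurize import ResidueGraph, build_atom_graph, build_residue_graph
from protembed.nn import (
    LocalChargeNet,
    MessagePassingLayer,
    ResidueNet,
    batch_atom_graphs,
    batch_residue_graphs,
    load_model,
    pka_features_atomic,
    pka_features_residue,
    readout_global,
    readout_pka_atomic,
    readout_pka_residue,
    readout_rsasa,
    save_model,
)
from protembed.synthetic import generate_atomic_environment, generate_mini_protein


def ssp(x):
    return np.log1p(np.exp(x)) - math.log(2)


def test_shifted_softplus_reference_values():
    f = lambda v: float(shifted_softplus(Tensor(np.array([v]))).data[0])
    assert f(0.0) == pytest.approx(0.0, abs=1e-12)
    assert f(-40.0) == pytest.approx(-math.log(2), abs=1e-6)
    assert f(1.0) == pytest.approx(math.log(1 + math.e) - math.log(2), abs=1e-9)


def test_edge_transform_shapes_and_zero_case():
    rng = np.random.default_rng(0)
    layer = MessagePassingLayer(150, 1, 300, rng)
    e = Tensor(np.random.default_rng(1).random((7, 300)))
    assert layer.transform_edges(e).shape == (7, 150)
    for p in (layer.edge1.W, layer.edge1.b, layer.edge2.W, layer.edge2.b):
        p.data[...] = 0.0
    np.testing.assert_allclose(layer.transform_edges(e).data, 0.0)


def test_edge_transform_matches_hand_computed_scalar_path():
    rng = np.random.default_rng(0)
    layer = MessagePassingLayer(2, 1, 4, rng)
    for p in (layer.edge1.W, layer.edge1.b, layer.edge2.W, layer.edge2.b):
        p.data[...] = 0.0
    layer.edge1.W.data[0, 0] = 1.5
    layer.edge1.b.data[0] = 0.2
    layer.edge2.W.data[0, 0] = -2.0
    layer.edge2.b.data[0] = 0.7
    e = np.zeros((1, 4))
    e[0, 0] = 0.9
    out = layer.transform_edges(Tensor(e)).data
    assert out[0, 0] == pytest.approx(-2.0 * ssp(1.5 * 0.9 + 0.2) + 0.7, abs=1e-12)
    assert out[0, 1] == pytest.approx(0.7 * 0.0, abs=1e-12)


def _dense_layer_oracle(layer, h, edges, edge_attr):
    """Brute-force re-computation of one message-passing layer in plain numpy."""
    n, width = h.shape
    H, D = layer.n_heads, layer.head_dim
    ec = (
        ssp(edge_attr @ layer.edge1.W.data + layer.edge1.b.data) @ layer.edge2.W.data
        + layer.edge2.b.data
    ).reshape(len(edges), H, D)
    q = (h @ layer.query.W.data + layer.query.b.data).reshape(n, H, D)
    k = (h @ layer.key.W.data + layer.key.b.data).reshape(n, H, D)
    v = (h @ layer.value.W.data + layer.value.b.data).reshape(n, H, D)
    hhat = np.zeros((n, H, D))
    for i in range(n):
        incoming = [e for e in range(len(edges)) if edges[e][1] == i]
        if not incoming:
            continue
        for c in range(H):
            logits = np.array(
                [q[i, c] @ (k[edges[e][0], c] + ec[e, c]) / math.sqrt(D) for e in incoming]
            )
            w = np.exp(logits - logits.max())
            w /= w.sum()
            hhat[i, c] = sum(
                we * (v[edges[e][0], c] + ec[e, c]) for we, e in zip(w, incoming)
            )
    hhat = hhat.reshape(n, width)
    pre = ssp(hhat) @ layer.residual.W.data + layer.residual.b.data
    mu = pre.mean(axis=-1, keepdims=True)
    var = pre.var(axis=-1, keepdims=True)
    ln = layer.ln_gain.data * (pre - mu) / np.sqrt(var + 1e-5) + layer.ln_bias.data
    return h + np.maximum(ln, 0.0)


@pytest.mark.parametrize("heads", [1, 2])
def test_attention_layer_matches_dense_oracle(heads):
    rng = np.random.default_rng(4)
    width = 4
    layer = MessagePassingLayer(width, heads, 6, rng)
    h = rng.normal(size=(3, width))
    edges = [(0, 1), (1, 0), (2, 1), (1, 2)]
    edge_attr = rng.random((len(edges), 6))
    src = np.array([e[0] for e in edges])
    dst = np.array([e[1] for e in edges])
    out = layer(Tensor(h), src, dst, Tensor(edge_attr), 3).data
    np.testing.assert_allclose(out, _dense_layer_oracle(layer, h, edges, edge_attr), atol=1e-10)


def test_attention_weights_sum_to_one(residue_graph):
    net = ResidueNet(seed=0)
    b = batch_residue_graphs([residue_graph])
    h = net.encode_nodes(b)
    w = net.layers[0].attention_weights(h, b.edge_src, b.edge_dst, Tensor(b.edge_attr), b.n_nodes)
    sums = np.zeros((b.n_nodes, w.shape[1]))
    np.add.at(sums, b.edge_dst, w)
    has_in = np.isin(np.arange(b.n_nodes), b.edge_dst)
    np.testing.assert_allclose(sums[has_in], 1.0, atol=1e-6)


def test_isolated_node_keeps_residual_path():
    rng = np.random.default_rng(1)
    layer = MessagePassingLayer(4, 1, 6, rng)
    h = rng.normal(size=(1, 4))
    out = layer(Tensor(h), np.array([], dtype=int), np.array([], dtype=int),
                Tensor(np.zeros((0, 6))), 1).data
    manual = (
        h
        + relu(
            layer_norm(
                Tensor(np.zeros((1, 4))) @ Tensor(np.eye(4)) + layer.residual.b,
                layer.ln_gain,
                layer.ln_bias,
            )
        ).data
    )
    np.testing.assert_allclose(out, manual, atol=1e-12)


def test_residual_relu_gate_blocks_negative_updates():
    rng = np.random.default_rng(2)
    layer = MessagePassingLayer(4, 1, 6, rng)
    layer.ln_bias.data[...] = -5.0  # push pre-ReLU negative everywhere
    h = rng.normal(size=(2, 4))
    src = np.array([0, 1])
    dst = np.array([1, 0])
    out = layer(Tensor(h), src, dst, Tensor(rng.random((2, 6))), 2).data
    np.testing.assert_allclose(out, h)


def test_symmetric_nodes_get_equal_messages():
    rng = np.random.default_rng(3)
    layer = MessagePassingLayer(4, 1, 6, rng)
    h = np.tile(rng.normal(size=(1, 4)), (2, 1))
    attr = np.tile(rng.random((1, 6)), (2, 1))
    out = layer(Tensor(h), np.array([0, 1]), np.array([1, 0]), Tensor(attr), 2).data
    np.testing.assert_allclose(out[0], out[1], atol=1e-12)


def test_network_widths_and_readout_lengths(residue_graph, atom_graph):
    net = ResidueNet(seed=0)
    b = batch_residue_graphs([residue_graph])
    h = net.encode_nodes(b)
    assert h.shape == (residue_graph.n_nodes, 150)
    assert len(net.layers) == 6
    emb = net.embed(b)
    assert emb.shape == (residue_graph.n_nodes, 150)
    feats = pka_features_residue(emb, b, np.array([2]))
    assert feats.shape == (1, 1050)
    assert net.forward_task("global", b).shape == (1, 6)

    anet = LocalChargeNet(seed=0)
    ab = batch_atom_graphs([atom_graph])
    ah = anet.encode_nodes(ab)
    assert ah.shape == (atom_graph.n_nodes, 75)
    assert len(anet.layers) == 3
    assert all(l.n_heads == 3 for l in anet.layers)
    afeat = pka_features_atomic(anet.embed(ab), ab)
    assert afeat.shape == (1, 225)


def test_encoding_is_deterministic_for_identical_inputs(residue_graph):
    net = ResidueNet(seed=0)
    g = residue_graph
    dup = ResidueGraph(
        aa_index=np.array([g.aa_index[0], g.aa_index[0]]),
        dihedrals=np.tile(g.dihedrals[:1], (2, 1)),
        d_com=np.array([g.d_com[0], g.d_com[0]]),
        ca_positions=np.zeros((2, 3)),
        edge_src=np.array([], dtype=int),
        edge_dst=np.array([], dtype=int),
        edge_attr=np.zeros((0, 300)),
    )
    h = net.encode_nodes(batch_residue_graphs([dup])).data
    np.testing.assert_allclose(h[0], h[1])
    with pytest.raises(ValueError, match="unknown"):
        net.aa_emb(np.array([25]))


def _zeroed(net, head, bias_value):
    for p in net.named_parameters().values():
        p.data[...] = 0.0
    net.heads[head].layers[-1].b.data[...] = bias_value if head == "pka" else bias_value
    return net


def test_zero_weight_network_returns_denormalized_head_bias(residue_graph, atom_graph):
    net = ResidueNet(seed=0)
    for p in net.named_parameters().values():
        p.data[...] = 0.0
    net.heads["global"].mlp.layers[-1].b.data[...] = 0.25
    net.set_normalization("global", np.arange(6.0), 2.0 * np.ones(6))
    np.testing.assert_allclose(
        readout_global(net, residue_graph), 0.25 * 2.0 + np.arange(6.0), atol=1e-12
    )
    anet = LocalChargeNet(seed=0)
    for p in anet.named_parameters().values():
        p.data[...] = 0.0
    anet.heads["pka"].layers[-1].b.data[...] = -0.5
    anet.set_normalization("pka", [7.0], [3.0])
    assert readout_pka_atomic(anet, atom_graph) == pytest.approx(7.0 - 0.5 * 3.0, abs=1e-12)


def test_missing_normalization_stats_raise(residue_graph):
    net = ResidueNet(seed=0)
    with pytest.raises(ValueError, match="normalization"):
        readout_global(net, residue_graph)


def test_radius_subsets_saturate_for_tiny_structures():
    # a structure whose Calpha diameter is < 6 A: every mu_r equals mu
    g = ResidueGraph(
        aa_index=np.array([0, 1, 2]),
        dihedrals=np.zeros((3, 15)),
        d_com=np.array([1.0, 0.5, 1.0]),
        ca_positions=np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0]], dtype=float),
        edge_src=np.array([0, 1, 0, 2, 1, 2]),
        edge_dst=np.array([1, 0, 2, 0, 2, 1]),
        edge_attr=np.random.default_rng(0).random((6, 300)),
    )
    net = ResidueNet(seed=1)
    b = batch_residue_graphs([g])
    h = net.embed(b)
    feats = pka_features_residue(h, b, np.array([0])).data[0]
    mu = h.data.mean(axis=0)
    for k in range(1, 7):  # mu_6 ... mu_15 and mu all equal the global mean
        np.testing.assert_allclose(feats[k * 150 : (k + 1) * 150], mu, atol=1e-12)


def test_radius_subsets_match_brute_force(residue_graph):
    net = ResidueNet(seed=0)
    b = batch_residue_graphs([residue_graph])
    h = net.embed(b)
    target = 5
    feats = pka_features_residue(h, b, np.array([target])).data[0]
    ca = residue_graph.ca_positions
    for k, r in enumerate((6.0, 8.0, 10.0, 12.0, 15.0), start=1):
        members = np.linalg.norm(ca - ca[target], axis=1) <= r
        np.testing.assert_allclose(
            feats[k * 150 : (k + 1) * 150], h.data[members].mean(axis=0), atol=1e-10
        )


def test_predictions_are_rigid_motion_invariant(rng):
    s, _ = generate_mini_protein(14, 0.5, np.random.default_rng(6))
    net = ResidueNet(seed=2)
    net.set_normalization("global", np.zeros(6), np.ones(6))
    net.set_normalization("rsasa", [0.0], [1.0])
    net.set_normalization("pka", [0.0], [1.0])
    g1 = build_residue_graph(s)
    ref_global = readout_global(net, g1)
    ref_rsasa = readout_rsasa(net, g1, 3)
    ref_pka = readout_pka_residue(net, g1, 3)
    rigid_transform(s, random_rotation(rng), rng.normal(size=3) * 10)
    g2 = build_residue_graph(s)
    np.testing.assert_allclose(readout_global(net, g2), ref_global, atol=1e-6)
    assert readout_rsasa(net, g2, 3) == pytest.approx(ref_rsasa, abs=1e-6)
    assert readout_pka_residue(net, g2, 3) == pytest.approx(ref_pka, abs=1e-6)

    env, t = generate_atomic_environment(np.random.default_rng(8), n_surround=20)
    anet = LocalChargeNet(seed=3)
    anet.set_normalization("pka", [5.0], [2.0])
    ref = readout_pka_atomic(anet, build_atom_graph(env, t))
    rigid_transform(env, random_rotation(rng), rng.normal(size=3))
    assert readout_pka_atomic(anet, build_atom_graph(env, t)) == pytest.approx(ref, abs=1e-6)


def test_node_permutation_leaves_predictions_unchanged(residue_graph):
    g = residue_graph
    rng = np.random.default_rng(9)
    perm = rng.permutation(g.n_nodes)
    inv = np.argsort(perm)
    permuted = ResidueGraph(
        aa_index=g.aa_index[perm],
        dihedrals=g.dihedrals[perm],
        d_com=g.d_com[perm],
        ca_positions=g.ca_positions[perm],
        edge_src=inv[g.edge_src],
        edge_dst=inv[g.edge_dst],
        edge_attr=g.edge_attr,
    )
    net = ResidueNet(seed=4)
    net.set_normalization("global", np.zeros(6), np.ones(6))
    np.testing.assert_allclose(
        readout_global(net, permuted), readout_global(net, g), atol=1e-8
    )


def test_pka_head_dropout_only_in_training_mode(atom_graph):
    net = LocalChargeNet(seed=5)
    net.set_normalization("pka", [0.0], [1.0])
    a = readout_pka_atomic(net, atom_graph)
    b = readout_pka_atomic(net, atom_graph)
    assert a == b  # inference is deterministic
    batch = batch_atom_graphs([atom_graph])
    z1 = net.forward_task("pka", batch, training=True, rng=np.random.default_rng(0)).data
    z2 = net.forward_task("pka", batch, training=True, rng=np.random.default_rng(1)).data
    assert not np.allclose(z1, z2)  # dropout active under training


def test_model_save_load_round_trip(tmp_path, residue_graph):
    net = ResidueNet(seed=6)
    net.set_normalization("global", np.arange(6.0), np.ones(6))
    ref = readout_global(net, residue_graph)
    path = tmp_path / "model.npz"
    save_model(net, path)
    back = load_model(path)
    np.testing.assert_allclose(readout_global(back, residue_graph), ref, atol=1e-12)
    assert back.config == net.config
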
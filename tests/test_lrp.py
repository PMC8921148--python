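import numpy as np
import pytest

from relspect.cnn import CnnSpec, build_cnn
from relspect.lrp import (
    Rule,
    RuleAssignment,
    RuleConfigError,
    compute_relevance_map,
    conservation_report,
    default_rules,
    propagate_alphabeta_conv,
    propagate_alphabeta_dense,
    propagate_epsilon_conv,
    propagate_epsilon_dense,
    propagate_flat_conv,
)

import lrp_oracle as oracle

TINY = CnnSpec(conv_filters=(2, 2, 2, 2), fc_sizes=(6, 4), dropout=0.0)


def _tiny_model(init_seed):
    """Untrained tiny model with a randomized (non-zero) softmax head, so
    relevance propagation acts on non-degenerate scores."""
    model = build_cnn(TINY, (9, 9, 9), init_seed=init_seed)
    head = model.layers[-1]
    head.W = np.random.default_rng(init_seed + 500).normal(
        0.0, 0.3, head.W.shape
    ).astype(np.float32)
    return model


# ---------------------------------------------------------------------------
# hand-worked examples

def test_epsilon_symmetric_split():
    W = np.array([[0.5], [0.5]])
    R = propagate_epsilon_dense(W, a=np.array([1.0, 1.0]), R=np.array([1.0]),
                                eps=1e-12)
    np.testing.assert_allclose(R, [0.5, 0.5], atol=1e-10)


def test_epsilon_weighted_split_with_small_deficit():
    a = np.array([1.0, 2.0])
    W = np.array([[0.6], [0.2]])
    eps = 1e-4
    R = propagate_epsilon_dense(W, a, np.array([1.0]), eps=eps)
    np.testing.assert_allclose(R, oracle.eps_rule(W, a, [1.0], eps), atol=1e-12)
    np.testing.assert_allclose(R, [0.6, 0.4], atol=1e-3)
    z_sum = float((a @ W)[0])
    deficit = 1.0 - R.sum()
    assert 0 < deficit <= eps / z_sum + 1e-12


def test_epsilon_zero_activations_give_zero_relevance():
    W = np.array([[0.3, -0.2], [0.7, 0.1]])
    R = propagate_epsilon_dense(W, np.zeros(2), np.array([1.0, 2.0]))
    np.testing.assert_array_equal(R, 0.0)


def test_alphabeta_hand_example_conserves_signed_parts():
    a = np.array([1.0, 1.0])
    W = np.array([[1.0], [-1.0]])
    R = propagate_alphabeta_dense(W, a, np.array([1.0]), alpha=2.0)
    np.testing.assert_allclose(R, [2.0, -1.0], atol=1e-12)
    assert R.sum() == pytest.approx(1.0)


def test_alphabeta_collapses_to_epsilon_without_negative_weights(rng):
    a = rng.random(6)
    W = rng.random((6, 3))  # all weights >= 0
    R_out = rng.random(3)
    ab = propagate_alphabeta_dense(W, a, R_out, alpha=2.0)
    eps0 = propagate_epsilon_dense(W, a, R_out, eps=1e-300)
    np.testing.assert_allclose(ab, eps0, atol=1e-10)


def test_flat_1d_analog_three_wide_kernel():
    # single output neuron with relevance 3 over a 3-voxel field
    model = build_cnn(CnnSpec(conv_filters=(1,), fc_sizes=(2,), dropout=0.0),
                      (3, 3, 3), init_seed=0)
    conv = model.layers[0]
    R_in = propagate_flat_conv(conv, np.zeros((3, 3, 3, 1)), np.array([[3.0]]))
    assert R_in.shape == (3, 3, 3, 1)
    np.testing.assert_allclose(R_in, 3.0 / 27.0)
    assert R_in.sum() == pytest.approx(3.0, abs=1e-12)


def test_flat_overlapping_fields_sum_equal_shares(rng):
    # a (5,3,3) input gives 3 overlapping receptive fields along x
    model = build_cnn(CnnSpec(conv_filters=(1,), fc_sizes=(2,), dropout=0.0),
                      (5, 3, 3), init_seed=0)
    conv = model.layers[0]
    R_out = rng.random((3, 1, 1, 1))
    R_in = propagate_flat_conv(conv, np.zeros((5, 3, 3, 1)), R_out)
    fields = oracle.conv_receptive_fields(conv, (5, 3, 3, 1))
    expected = oracle.flat_rule(fields, 45, R_out.reshape(-1)).reshape(5, 3, 3, 1)
    np.testing.assert_allclose(R_in, expected, atol=1e-12)
    assert R_in.sum() == pytest.approx(R_out.sum(), abs=1e-12)


# ---------------------------------------------------------------------------
# oracle equivalence on random instances

@pytest.mark.parametrize("trial", range(10))
def test_dense_rules_match_scalar_oracle(trial):
    rng = np.random.default_rng(100 + trial)
    n_in, n_out = rng.integers(2, 12), rng.integers(1, 8)
    W = rng.standard_normal((n_in, n_out))
    a = np.maximum(rng.standard_normal(n_in), 0.0)  # post-ReLU activations
    R = rng.standard_normal(n_out)
    np.testing.assert_allclose(
        propagate_epsilon_dense(W, a, R, 1e-4),
        oracle.eps_rule(W, a, R, 1e-4), atol=1e-10,
    )
    np.testing.assert_allclose(
        propagate_alphabeta_dense(W, a, R, 2.0),
        oracle.alphabeta_rule(W, a, R, 2.0), atol=1e-10,
    )


@pytest.mark.parametrize("trial", range(6))
def test_conv_rules_match_scalar_oracle_on_dense_equivalent(trial):
    # a 3x3x3 single-window conv: 27 input neurons, cout outputs
    rng = np.random.default_rng(200 + trial)
    cout = int(rng.integers(1, 4))
    model = build_cnn(CnnSpec(conv_filters=(cout,), fc_sizes=(2,), dropout=0.0),
                      (3, 3, 3), init_seed=trial)
    conv = model.layers[0]
    a_in = rng.random((3, 3, 3, 1))  # non-negative uptake-like input
    R_out = rng.standard_normal((1, 1, 1, cout))
    M = oracle.conv_as_dense(conv, (3, 3, 3, 1))
    a_flat = a_in.reshape(-1)
    R_flat = R_out.reshape(-1)

    got = propagate_epsilon_conv(conv, a_in, R_out, 1e-4).reshape(-1)
    np.testing.assert_allclose(got, oracle.eps_rule(M, a_flat, R_flat, 1e-4),
                               atol=1e-10)
    got = propagate_alphabeta_conv(conv, a_in, R_out, 2.0).reshape(-1)
    np.testing.assert_allclose(got, oracle.alphabeta_rule(M, a_flat, R_flat, 2.0),
                               atol=1e-10)
    got = propagate_flat_conv(conv, a_in, R_out).reshape(-1)
    fields = oracle.conv_receptive_fields(conv, (3, 3, 3, 1))
    np.testing.assert_allclose(got, oracle.flat_rule(fields, 27, R_flat),
                               atol=1e-12)


@pytest.mark.parametrize("trial", range(4))
def test_overlapping_conv_rules_match_oracle(trial):
    # (5,3,3) input -> overlapping receptive fields, signed activations
    rng = np.random.default_rng(300 + trial)
    model = build_cnn(CnnSpec(conv_filters=(2,), fc_sizes=(2,), dropout=0.0),
                      (5, 3, 3), init_seed=trial)
    conv = model.layers[0]
    a_in = rng.standard_normal((5, 3, 3, 1))  # signed: exercises slow path
    R_out = rng.standard_normal((3, 1, 1, 2))
    M = oracle.conv_as_dense(conv, (5, 3, 3, 1))
    np.testing.assert_allclose(
        propagate_epsilon_conv(conv, a_in, R_out, 1e-4).reshape(-1),
        oracle.eps_rule(M, a_in.reshape(-1), R_out.reshape(-1), 1e-4), atol=1e-10,
    )
    np.testing.assert_allclose(
        propagate_alphabeta_conv(conv, a_in, R_out, 2.0).reshape(-1),
        oracle.alphabeta_rule(M, a_in.reshape(-1), R_out.reshape(-1), 2.0),
        atol=1e-10,
    )


def test_small_network_epsilon_backprojection_matches_oracle():
    # hand-built 2-2-2 bias-free stack, epsilon rule everywhere
    rng = np.random.default_rng(7)
    layers = [
        (rng.standard_normal((2, 2)), np.zeros(2), True),
        (rng.standard_normal((2, 2)), np.zeros(2), False),
    ]
    x = rng.random(2)
    acts = oracle.forward_dense_stack(layers, x)
    expected = oracle.backproject_dense_stack(
        layers, acts, rules=[("eps", 1e-4), ("eps", 1e-4)]
    )
    R = np.zeros(2)
    j0 = int(np.argmax(acts[-1]))
    R[j0] = acts[-1][j0]
    R = propagate_epsilon_dense(layers[1][0], acts[1], R, 1e-4)
    R = propagate_epsilon_dense(layers[0][0], acts[0], R, 1e-4)
    np.testing.assert_allclose(R, expected, atol=1e-10)


# ---------------------------------------------------------------------------
# conservation

def test_flat_rule_conserves_exactly(rng):
    model = _tiny_model(1)
    conv = model.layers[1]
    a_in = rng.random((7, 7, 7, 2))
    R_out = rng.standard_normal((5, 5, 5, 2))
    R_in = propagate_flat_conv(conv, a_in, R_out)
    assert R_in.sum() == pytest.approx(R_out.sum(), rel=1e-12)


def test_alphabeta_conserves_on_bias_free_layers(rng):
    model = _tiny_model(2)
    conv = model.layers[2]
    a_in = np.maximum(rng.standard_normal((5, 5, 5, 2)), 0)
    R_out = rng.standard_normal((3, 3, 3, 2))
    R_in = propagate_alphabeta_conv(conv, a_in, R_out, alpha=2.0)
    assert R_in.sum() == pytest.approx(R_out.sum(), rel=1e-6)


def test_epsilon_dissipation_respects_bound(rng):
    W = rng.standard_normal((8, 4))
    a = np.maximum(rng.standard_normal(8), 0)
    R_out = rng.standard_normal(4)
    eps = 1e-4
    R_in = propagate_epsilon_dense(W, a, R_out, eps)
    denom = a @ W
    denom_eps = np.abs(denom + eps * np.where(denom >= 0, 1, -1))
    bound = eps * np.abs(R_out).sum() / denom_eps.min()
    assert abs(R_in.sum() - R_out.sum()) <= bound + 1e-12


def test_total_input_relevance_matches_score_in_eps_limit(rng):
    # bias-free network, eps -> 0: exact conservation down to the input
    model = _tiny_model(3)
    for layer in model.weighted_layers:
        layer.b[:] = 0.0
    rules = RuleAssignment(tuple(
        (l.name, Rule("epsilon", epsilon=1e-10)) for l in model.weighted_layers
    ))
    vol = rng.random((9, 9, 9)).astype(np.float32)
    rmap = compute_relevance_map(model, vol, rules, sign_harmonize=False)
    assert rmap.data.sum() == pytest.approx(rmap.start_score, rel=1e-6)


def test_conservation_report_structure(rng):
    model = _tiny_model(4)
    rmap = compute_relevance_map(model, rng.random((9, 9, 9)).astype(np.float32))
    rep = conservation_report(rmap)
    assert rep["finite"]
    assert rep["stages"][0] == "output_score"
    assert len(rep["sums"]) == len(model.weighted_layers) + 1
    # flat and alphabeta stages conserve on this default assignment except
    # where epsilon-rule layers with biases leak
    flat_stages = {"conv1", "conv2"}
    for i, stage in enumerate(rep["stages"]):
        if stage in flat_stages:
            assert rep["sums"][i] == pytest.approx(rep["sums"][i - 1], rel=1e-10)


# ---------------------------------------------------------------------------
# full map behaviour

def test_default_rule_assignment_covers_all_layers():
    model = build_cnn(input_shape=(12, 12, 12), init_seed=0)
    rules = default_rules(model)
    names = [n for n, _ in rules.rules]
    assert names == ["conv1", "conv2", "conv3", "conv4", "fc1", "fc2", "output"]
    assert rules.rule_for("conv1").name == "flat"
    assert rules.rule_for("conv3").name == "alphabeta"
    assert rules.rule_for("fc1").name == "epsilon"
    assert rules.rule_for("output").name == "epsilon"


def test_missing_rule_raises_config_error(rng):
    model = _tiny_model(5)
    partial = RuleAssignment((("conv1", Rule("flat")),))
    with pytest.raises(RuleConfigError):
        compute_relevance_map(model, rng.random((9, 9, 9)).astype(np.float32),
                              partial)


def test_invalid_rule_parameters_rejected():
    with pytest.raises(RuleConfigError):
        Rule("epsilon", epsilon=0.0)
    with pytest.raises(RuleConfigError):
        Rule("alphabeta", alpha=0.5)
    with pytest.raises(RuleConfigError):
        Rule("gamma")


def test_sign_harmonization_flips_predicted_negative_maps(rng):
    model = _tiny_model(6)
    vol = rng.random((9, 9, 9)).astype(np.float32)
    raw = compute_relevance_map(model, vol, sign_harmonize=False)
    harm = compute_relevance_map(model, vol, sign_harmonize=True)
    if harm.predicted_label == "negative":
        assert harm.sign_harmonized
        np.testing.assert_allclose(harm.data, -raw.data, atol=1e-12)
    else:
        assert not harm.sign_harmonized
        np.testing.assert_allclose(harm.data, raw.data, atol=1e-12)
    assert harm.start_neuron == int(np.argmax(model.predict(vol)["scores"]))


def test_symmetric_input_with_symmetrized_weights_gives_symmetric_map(rng):
    model = _tiny_model(8)
    # symmetrize conv kernels along x and fc weights along the x axis of the
    # flattened grid so the network commutes with the left-right flip
    for layer in model.layers:
        if layer.kind == "conv":
            W = layer.W.reshape(layer.cin, 3, 3, 3, layer.cout)
            layer.W = ((W + W[:, ::-1]) / 2).reshape(layer.W.shape)
    fc1 = next(l for l in model.layers if getattr(l, "name", "") == "fc1")
    sp = model.conv_out_shape
    Wg = fc1.W.reshape(sp + (fc1.W.shape[1],))
    fc1.W = ((Wg + Wg[::-1]) / 2).reshape(fc1.W.shape)

    vol = rng.random((9, 9, 9)).astype(np.float32)
    vol = (vol + vol[::-1]) / 2
    rmap = compute_relevance_map(model, vol)
    np.testing.assert_allclose(rmap.data, rmap.data[::-1], atol=1e-6)
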
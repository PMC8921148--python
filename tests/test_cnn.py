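import numpy as np
import pytest

from relspect.cnn import (
    CnnSpec,
    Cnn3dClassifier,
    DivergenceError,
    ShapeError,
    TrainConfig,
    _cross_entropy,
    build_cnn,
    train,
)

TINY = CnnSpec(conv_filters=(2, 2, 2, 2), fc_sizes=(6, 4), dropout=0.0)


def _tiny_model(seed=0, shape=(9, 10, 11)):
    return build_cnn(TINY, shape, init_seed=seed)


@pytest.mark.parametrize("shape", [(9, 9, 9), (12, 14, 10), (15, 9, 13)])
def test_each_valid_conv_shrinks_every_dim_by_two(shape):
    model = _tiny_model(shape=shape)
    x = np.zeros(shape, dtype=np.float32)
    trace = model.forward_trace(x)
    expected = np.array(shape)
    for name, act in zip(trace.names, trace.activations):
        if name.startswith("conv"):
            expected = expected - 2
            assert act.shape[:3] == tuple(expected)
    assert model.conv_out_shape[:3] == tuple(np.array(shape) - 8)


def test_flatten_size_matches_closed_form_at_full_grid():
    model = build_cnn(input_shape=(48, 56, 44), init_seed=0)
    fc1 = next(l for l in model.layers if getattr(l, "name", "") == "fc1")
    assert fc1.W.shape == (16 * 40 * 48 * 36, 32)
    assert fc1.W.shape[0] == 1_105_920


def test_same_seed_gives_identical_initial_weights():
    a = _tiny_model(seed=5)
    b = _tiny_model(seed=5)
    for (ka, _, _, wa), (kb, _, _, wb) in zip(a.parameters(), b.parameters()):
        assert ka == kb
        np.testing.assert_array_equal(wa, wb)
    c = _tiny_model(seed=6)
    assert any(
        not np.array_equal(wa, wc)
        for (_, _, _, wa), (_, _, _, wc) in zip(a.parameters(), c.parameters())
    )


def test_too_small_input_raises_shape_error():
    with pytest.raises(ShapeError):
        build_cnn(CnnSpec(), (8, 8, 8))
    model = _tiny_model()
    with pytest.raises(ShapeError):
        model.predict(np.zeros((7, 7, 7), dtype=np.float32))


def test_softmax_probabilities_sum_to_one(rng):
    model = _tiny_model()
    out = model.predict(rng.random((9, 10, 11)).astype(np.float32))
    assert np.abs(out["probabilities"].sum() - 1.0) < 1e-6
    assert out["label"] in ("negative", "positive")


def test_prediction_identical_across_calls(rng):
    # dropout must be inactive at inference
    model = build_cnn(CnnSpec(conv_filters=(2,) * 4, fc_sizes=(6, 4), dropout=0.5),
                      (9, 9, 9), init_seed=1)
    x = rng.random((9, 9, 9)).astype(np.float32)
    np.testing.assert_array_equal(model.predict(x)["scores"], model.predict(x)["scores"])


def test_trace_consistency_with_predict(rng):
    model = _tiny_model(seed=2)
    x = rng.random((9, 10, 11)).astype(np.float32)
    trace = model.forward_trace(x)
    np.testing.assert_array_equal(trace.scores, model.predict(x)["scores"])
    for name, kind, act in zip(trace.names, trace.kinds, trace.activations):
        assert np.all(np.isfinite(act))
        if kind in ("conv", "dense") and name != "output":
            assert act.min() >= 0.0  # rectified hidden layers


def test_zero_input_propagates_rectified_biases(rng):
    model = _tiny_model(seed=3)
    conv1 = model.layers[0]
    conv1.b = rng.normal(0, 1, conv1.b.shape).astype(np.float32)
    trace = model.forward_trace(np.zeros((9, 10, 11), dtype=np.float32))
    first = trace.activations[trace.names.index("conv1")]
    expected = np.maximum(conv1.b, 0.0)
    np.testing.assert_allclose(first, np.broadcast_to(expected, first.shape),
                               rtol=1e-6)


def test_backprop_matches_finite_differences(rng):
    model = _tiny_model(seed=4, shape=(9, 9, 9))
    X = rng.random((2, 9, 9, 9, 1)).astype(np.float64)
    y = np.array([0, 1])

    def loss_at():
        h = X.astype(np.float32)
        for layer in model.layers:
            h = layer.forward(h, train=False)
        return _cross_entropy(h, y)[0]

    h = X.astype(np.float32)
    for layer in model.layers:
        h = layer.forward(h, train=True)
    _, grad = _cross_entropy(h, y)
    g = grad
    for layer in reversed(model.layers):
        g = layer.backward(g)

    checks = 0
    for layer in (model.layers[0], model.layers[6]):  # conv1 and fc1
        W, dW = layer.W, layer.dW
        flat = np.argsort(-np.abs(dW), axis=None)[:3]  # probe large gradients
        for fi in flat:
            ii = np.unravel_index(fi, W.shape)
            eps = 1e-2
            old = W[ii]
            W[ii] = old + eps
            lp = loss_at()
            W[ii] = old - eps
            lm = loss_at()
            W[ii] = old
            numeric = (lp - lm) / (2 * eps)
            assert numeric == pytest.approx(float(dW[ii]), rel=0.05, abs=1e-4)
            checks += 1
    assert checks == 6


def test_memorizes_a_single_duplicated_case(rng):
    model = _tiny_model(seed=7, shape=(9, 9, 9))
    x = rng.random((9, 9, 9)).astype(np.float32)
    X = np.stack([x, x, x, x])[..., None]
    y = np.array([1, 1, 1, 1])
    history = train(
        model, X, y, config=TrainConfig(epochs=250, batch_size=4, learning_rate=3e-2)
    )
    assert history["train_loss"][-1] < 0.05
    assert model.predict(x)["label"] == "positive"


def test_training_is_deterministic(rng):
    X = rng.random((8, 9, 9, 9, 1)).astype(np.float32)
    y = np.array([0, 1] * 4)
    results = []
    for _ in range(2):
        model = _tiny_model(seed=8, shape=(9, 9, 9))
        train(model, X, y, X, y, TrainConfig(epochs=2, seed=3))
        results.append(model.get_weights())
    for key in results[0]:
        np.testing.assert_array_equal(results[0][key], results[1][key])


def test_empty_training_set_rejected():
    model = _tiny_model(shape=(9, 9, 9))
    with pytest.raises(ValueError):
        train(model, np.zeros((0, 9, 9, 9, 1), np.float32), np.zeros(0, np.int64))


def test_divergent_loss_raises(rng):
    model = _tiny_model(seed=9, shape=(9, 9, 9))
    model.layers[-1].W += np.inf
    X = rng.random((4, 9, 9, 9, 1)).astype(np.float32)
    with pytest.raises(DivergenceError):
        train(model, X, np.array([0, 1, 0, 1]),
              config=TrainConfig(epochs=1, batch_size=4))


def test_save_load_round_trip(tmp_path, rng):
    model = _tiny_model(seed=10)
    x = rng.random((9, 10, 11)).astype(np.float32)
    path = tmp_path / "model.npz"
    model.save(path)
    back = Cnn3dClassifier.load(path)
    np.testing.assert_array_equal(
        back.predict(x)["scores"], model.predict(x)["scores"]
    )
    assert back.spec == model.spec
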
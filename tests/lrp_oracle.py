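"""Independent scalar-loop oracle for the relevance propagation rules.

Everything here is written as explicit Python loops over neuron indices,
directly transcribing the redistribution formulas, and is deliberately kept
free of the vectorized code paths it is used to check.
"""

import numpy as np


def eps_rule(W, a, R, eps=1e-4):
    """Epsilon rule on an explicit dense layer: W is (n_in, n_out)."""
    W = np.asarray(W, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    R = np.asarray(R, dtype=np.float64)
    n_in, n_out = W.shape
    R_in = np.zeros(n_in)
    for j in range(n_out):
        denom = 0.0
        for i in range(n_in):
            denom += a[i] * W[i, j]
        denom = denom + eps * (1.0 if denom >= 0.0 else -1.0)
        for i in range(n_in):
            R_in[i] += a[i] * W[i, j] / denom * R[j]
    return R_in


def alphabeta_rule(W, a, R, alpha=2.0):
    """Alpha-beta rule (beta = alpha - 1) on an explicit dense layer.

    Degenerate-neuron convention (shared with the implementation under
    test): a neuron with only positive (or only negative) contributions
    redistributes its full relevance through that single channel, so the
    layer conserves relevance and collapses onto plain proportional
    redistribution when no negative weights exist.
    """
    W = np.asarray(W, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    R = np.asarray(R, dtype=np.float64)
    n_in, n_out = W.shape
    R_in = np.zeros(n_in)
    for j in range(n_out):
        zp_sum = 0.0
        zn_sum = 0.0
        for i in range(n_in):
            z = a[i] * W[i, j]
            if z > 0:
                zp_sum += z
            elif z < 0:
                zn_sum += z
        c_pos = alpha if zn_sum != 0.0 else 1.0
        c_neg = (alpha - 1.0) if zp_sum != 0.0 else -1.0
        for i in range(n_in):
            z = a[i] * W[i, j]
            zp = z if z > 0 else 0.0
            zn = z if z < 0 else 0.0
            term = 0.0
            if zp_sum != 0.0:
                term += c_pos * zp / zp_sum
            if zn_sum != 0.0:
                term -= c_neg * zn / zn_sum
            R_in[i] += term * R[j]
    return R_in


def flat_rule(fields, n_in, R):
    """Uniform backprojection over explicit receptive fields.

    ``fields[j]`` lists the input indices feeding output neuron j; each
    output's relevance is split equally among them.
    """
    R = np.asarray(R, dtype=np.float64)
    R_in = np.zeros(n_in)
    for j, members in enumerate(fields):
        share = R[j] / len(members)
        for i in members:
            R_in[i] += share
    return R_in


def forward_dense_stack(layers, x):
    """Forward pass through [(W, b, relu), ...]; returns all activations."""
    acts = [np.asarray(x, dtype=np.float64)]
    for W, b, relu in layers:
        h = acts[-1] @ np.asarray(W, dtype=np.float64) + np.asarray(b, np.float64)
        if relu:
            h = np.maximum(h, 0.0)
        acts.append(h)
    return acts


def backproject_dense_stack(layers, acts, rules, start_neuron=None):
    """Full backprojection through a dense stack with per-layer rules.

    ``rules[k]`` is ("eps", eps) or ("ab", alpha) or ("flat",) for layer k.
    The initial relevance is the raw score of the most activated output
    neuron (or ``start_neuron``).
    """
    scores = acts[-1]
    j0 = int(np.argmax(scores)) if start_neuron is None else start_neuron
    R = np.zeros_like(scores)
    R[j0] = scores[j0]
    for k in reversed(range(len(layers))):
        W, b, relu = layers[k]
        a = acts[k]
        kind = rules[k][0]
        if kind == "eps":
            R = eps_rule(W, a, R, rules[k][1])
        elif kind == "ab":
            R = alphabeta_rule(W, a, R, rules[k][1])
        elif kind == "flat":
            n_in = np.asarray(W).shape[0]
            fields = [list(range(n_in)) for _ in range(np.asarray(W).shape[1])]
            R = flat_rule(fields, n_in, R)
        else:  # pragma: no cover
            raise ValueError(kind)
    return R


def conv_as_dense(layer, in_shape):
    """Equivalent dense weight matrix of a conv layer, by basis probing."""
    n_in = int(np.prod(in_shape))
    basis = np.eye(n_in, dtype=np.float64).reshape((n_in,) + tuple(in_shape))
    b, relu = layer.b.copy(), layer.relu
    layer.b = np.zeros_like(layer.b)
    layer.relu = False
    try:
        out = layer.forward(basis.astype(np.float32), train=False)
    finally:
        layer.b, layer.relu = b, relu
    return np.asarray(out, dtype=np.float64).reshape(n_in, -1)


def conv_receptive_fields(layer, in_shape):
    """Structural receptive fields (input index lists) of a conv layer."""
    W_saved = layer.W.copy()
    layer.W = np.ones_like(layer.W)
    try:
        M = conv_as_dense(layer, in_shape)
    finally:
        layer.W = W_saved
    return [list(np.flatnonzero(M[:, j] != 0.0)) for j in range(M.shape[1])]
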
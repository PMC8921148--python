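"""Layer-wise relevance propagation with a per-layer rule combination.

The pre-softmax score of the most activated output neuron is redistributed
backward through the network, layer by layer, down to the input voxels.
With ``z_ij = a_i * w_ij`` (activation of sending neuron i times trained
weight into receiving neuron j), the rules are:

``epsilon``  (output and fully connected layers)
    R_i = sum_j  z_ij / (sum_i z_ij + eps * sign(sum_i z_ij)) * R_j,
    with sign(0) = +1 and eps = 1e-4 by default.  The eps term damps noise
    amplification from near-zero denominators; it is the only rule that can
    dissipate relevance (bounded by eps * sum_j |R_j| / min_j |denom_j|).

``alphabeta``  (the two convolutional layers nearest the output; alpha = 2)
    R_i = sum_j [ alpha * z+_ij / sum_i z+_ij
                  - (alpha - 1) * z-_ij / sum_i z-_ij ] * R_j,
    where z+/z- are the positive/negative parts of z_ij.  Written in the
    standard alpha/beta form with beta = alpha - 1, this conserves relevance
    on bias-free layers and lets features that oppose the decision carry
    negative relevance.  Degenerate neurons are handled so that
    conservation survives: a neuron with no negative contributions at all
    redistributes its relevance purely proportionally (coefficient 1, the
    alpha weighting only arbitrates *between* the two channels when both
    exist), and symmetrically for a neuron with no positive contributions;
    a neuron with neither contributes nothing.  This also makes the rule
    collapse exactly onto the epsilon rule at eps -> 0 on layers without
    negative weights.

``flat``  (the two convolutional layers nearest the input)
    uniform backprojection: each neuron's relevance is split equally over
    its receptive field (z_ij = 1), controlling the resolution and
    semantics of the final map.  Conservation is exact.

Biases participate in the forward pass but absorb no relevance; the
resulting leak at epsilon-rule layers is surfaced by the conservation
report rather than redistributed.  Maps of predicted-normal scans are
sign-flipped ("sign harmonization") so positive relevance always reads as
evidence for reduced uptake; the flag is recorded and the raw-sign map is
recoverable by negating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .cnn import Cnn3dClassifier, _col2im, _im2col
from .io_volumes import SpectVolume

__all__ = [
    "Rule",
    "RuleAssignment",
    "RelevanceMap",
    "propagate_epsilon_dense",
    "propagate_alphabeta_dense",
    "propagate_epsilon_conv",
    "propagate_alphabeta_conv",
    "propagate_flat_conv",
    "compute_relevance_map",
    "conservation_report",
    "default_rules",
]


class RuleConfigError(ValueError):
    """Rule assignment does not match the classifier's layer stack."""


@dataclass(frozen=True)
class Rule:
    """One propagation rule: name in {'epsilon', 'alphabeta', 'flat'}."""

    name: str
    epsilon: float = 1e-4
    alpha: float = 2.0

    def __post_init__(self):
        if self.name not in ("epsilon", "alphabeta", "flat"):
            raise RuleConfigError(f"unknown rule {self.name!r}")
        if self.name == "epsilon" and not self.epsilon > 0:
            raise RuleConfigError("epsilon must be > 0")
        if self.name == "alphabeta" and not self.alpha >= 1:
            raise RuleConfigError("alpha must be >= 1")


@dataclass(frozen=True)
class RuleAssignment:
    """Ordered map layer-name -> rule covering every weighted layer."""

    rules: tuple  # of (layer_name, Rule)

    def rule_for(self, layer_name: str) -> Rule:
        for name, rule in self.rules:
            if name == layer_name:
                return rule
        raise RuleConfigError(f"no rule assigned to layer '{layer_name}'")

    @classmethod
    def from_dict(cls, mapping) -> "RuleAssignment":
        return cls(tuple((k, v) for k, v in mapping.items()))


def default_rules(model: Cnn3dClassifier) -> RuleAssignment:
    """The default combination: epsilon at the dense layers, alpha-beta
    (alpha=2) at the two conv layers nearest the output, flat at the two
    conv layers nearest the input."""
    convs = [l.name for l in model.weighted_layers if l.kind == "conv"]
    denses = [l.name for l in model.weighted_layers if l.kind == "dense"]
    n_flat = min(2, len(convs))
    assignment = []
    for i, name in enumerate(convs):
        rule = Rule("flat") if i < n_flat else Rule("alphabeta", alpha=2.0)
        assignment.append((name, rule))
    for name in denses:
        assignment.append((name, Rule("epsilon", epsilon=1e-4)))
    return RuleAssignment(tuple(assignment))


@dataclass
class RelevanceMap:
    """Signed voxel relevance aligned to the input volume.

    ``conservation`` records the total relevance after each propagation
    step, from the start score at the output down to the input layer.
    """

    data: np.ndarray
    voxel_size: tuple
    start_neuron: int
    start_score: float
    predicted_label: str
    sign_harmonized: bool
    conservation: list = field(default_factory=list)  # [(stage, sum R)]

    @property
    def shape(self):
        return self.data.shape

    def as_volume(self) -> SpectVolume:
        """Wrap as a volume for NIfTI serialization."""
        return SpectVolume(
            self.data,
            self.voxel_size,
            metadata={
                "kind": "relevance_map",
                "start_neuron": self.start_neuron,
                "start_score": self.start_score,
                "predicted_label": self.predicted_label,
                "sign_harmonized": self.sign_harmonized,
                "conservation": [[s, float(v)] for s, v in self.conservation],
            },
        )


def _sign(x):
    """sign with sign(0) = +1, per the epsilon-rule convention."""
    return np.where(np.asarray(x) >= 0, 1.0, -1.0)


# ---------------------------------------------------------------------------
# dense-layer rules

def propagate_epsilon_dense(W, a, R, eps=1e-4):
    """Epsilon rule through a dense layer (weights ``W``: in x out)."""
    a = np.asarray(a, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    R = np.asarray(R, dtype=np.float64)
    denom = a @ W  # sum_i z_ij, biases excluded
    s = R / (denom + eps * _sign(denom))
    return a * (W @ s)


def _alphabeta_coefficients(zp_sum, zn_sum, R, alpha):
    """Per-neuron scale factors of the two channels, conservation-safe.

    Normal neurons use (alpha, alpha-1); a neuron missing one channel
    redistributes fully through the other (coefficient 1, resp. -1 so the
    subtracted negative term carries the full relevance)."""
    has_p = zp_sum != 0.0
    has_n = zn_sum != 0.0
    cp = np.where(has_n, alpha, 1.0)
    cn = np.where(has_p, alpha - 1.0, -1.0)
    sp = np.where(has_p, cp * R / np.where(has_p, zp_sum, 1.0), 0.0)
    sn = np.where(has_n, cn * R / np.where(has_n, zn_sum, 1.0), 0.0)
    return sp, sn


def propagate_alphabeta_dense(W, a, R, alpha=2.0):
    """Alpha-beta rule (beta = alpha - 1) through a dense layer."""
    a = np.asarray(a, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    R = np.asarray(R, dtype=np.float64)
    ap, an = np.maximum(a, 0.0), np.minimum(a, 0.0)
    Wp, Wn = np.maximum(W, 0.0), np.minimum(W, 0.0)
    zp_sum = ap @ Wp + an @ Wn
    zn_sum = ap @ Wn + an @ Wp
    sp, sn = _alphabeta_coefficients(zp_sum, zn_sum, R, alpha)
    r_pos = ap * (Wp @ sp) + an * (Wn @ sp)
    r_neg = ap * (Wn @ sn) + an * (Wp @ sn)
    return r_pos - r_neg


# ---------------------------------------------------------------------------
# conv-layer rules (im2col route, shared with the forward pass)

def propagate_epsilon_conv(layer, a_in, R_out, eps=1e-4):
    """Epsilon rule through a 3x3x3 valid conv layer."""
    x = np.asarray(a_in, dtype=np.float64)[None]
    cols, sp = _im2col(x)
    W = np.asarray(layer.W, dtype=np.float64)
    Rf = np.asarray(R_out, dtype=np.float64).reshape(-1, layer.cout)
    denom = cols @ W
    s = Rf / (denom + eps * _sign(denom))
    rcols = cols * (s @ W.T)
    return _col2im(rcols, x.shape)[0]


def propagate_alphabeta_conv(layer, a_in, R_out, alpha=2.0):
    """Alpha-beta rule (beta = alpha - 1) through a 3x3x3 valid conv layer."""
    x = np.asarray(a_in, dtype=np.float64)[None]
    cols, sp = _im2col(x)
    W = np.asarray(layer.W, dtype=np.float64)
    Rf = np.asarray(R_out, dtype=np.float64).reshape(-1, layer.cout)
    Wp, Wn = np.maximum(W, 0.0), np.minimum(W, 0.0)
    nonneg = bool(cols.min() >= 0.0)  # true for post-ReLU / uptake inputs
    if nonneg:
        zp_sum = cols @ Wp
        zn_sum = cols @ Wn
    else:
        colsp, colsn = np.maximum(cols, 0.0), np.minimum(cols, 0.0)
        zp_sum = colsp @ Wp + colsn @ Wn
        zn_sum = colsp @ Wn + colsn @ Wp
    sp_, sn_ = _alphabeta_coefficients(zp_sum, zn_sum, Rf, alpha)
    if nonneg:
        rcols = cols * (sp_ @ Wp.T - sn_ @ Wn.T)
    else:
        rcols = colsp * (sp_ @ Wp.T) + colsn * (sp_ @ Wn.T)
        rcols -= colsp * (sn_ @ Wn.T) + colsn * (sn_ @ Wp.T)
    return _col2im(rcols, x.shape)[0]


def propagate_flat_conv(layer, a_in, R_out):
    """Uniform backprojection: R_j split equally over the receptive field.

    Each output neuron covers ``cin * 27`` input neurons; overlapping
    fields sum their equal shares.  Conservation is exact.
    """
    x_shape = (1,) + tuple(np.asarray(a_in).shape)
    cin = x_shape[-1]
    Rf = np.asarray(R_out, dtype=np.float64).reshape(-1, layer.cout)
    share = Rf.sum(axis=1) / (cin * 27)
    rcols = np.repeat(share[:, None], cin * 27, axis=1)
    return _col2im(rcols, x_shape)[0]


# ---------------------------------------------------------------------------
# full backprojection

def compute_relevance_map(
    model: Cnn3dClassifier,
    vol,
    rules: Optional[RuleAssignment] = None,
    sign_harmonize: bool = True,
) -> RelevanceMap:
    """Backproject the most activated output neuron's score to the voxels.

    The initial relevance is the pre-softmax score of the argmax output
    neuron; each weighted layer applies its assigned rule in reverse order
    (the flatten step is a pure reshape).  If the predicted class is
    "negative" and ``sign_harmonize`` is set, the final map is negated so
    that positive relevance uniformly denotes evidence for reduced uptake.
    """
    if isinstance(vol, SpectVolume):
        data, voxel_size = vol.data, vol.voxel_size
    else:
        data = np.asarray(vol)
        voxel_size = (1.0, 1.0, 1.0)
    rules = rules or default_rules(model)
    # validate coverage before any work
    for layer in model.weighted_layers:
        rules.rule_for(layer.name)

    trace = model.forward_trace(data)
    scores = trace.scores
    start_neuron = int(np.argmax(scores))
    start_score = float(scores[start_neuron])
    predicted_label = ("negative", "positive")[start_neuron]

    R = np.zeros_like(scores, dtype=np.float64)
    R[start_neuron] = start_score
    conservation = [("output_score", float(R.sum()))]

    # walk the layer stack backwards; trace.activations[i] is the input of
    # weighted layer i in model order (dropout entries are skipped in traces)
    weighted = model.weighted_layers
    for layer in reversed(weighted):
        rule = rules.rule_for(layer.name)
        pos = trace.names.index(layer.name)
        a_in = trace.activations[pos - 1]
        if layer.kind == "dense":
            a_vec = a_in.reshape(-1)
            if rule.name == "epsilon":
                R = propagate_epsilon_dense(layer.W, a_vec, R, rule.epsilon)
            elif rule.name == "alphabeta":
                R = propagate_alphabeta_dense(layer.W, a_vec, R, rule.alpha)
            else:
                raise RuleConfigError(
                    f"flat rule is defined on conv receptive fields, not '{layer.name}'"
                )
            if trace.names[pos - 1] == "flatten":
                R = R.reshape(model.conv_out_shape)
        else:
            if rule.name == "epsilon":
                R = propagate_epsilon_conv(layer, a_in, R, rule.epsilon)
            elif rule.name == "alphabeta":
                R = propagate_alphabeta_conv(layer, a_in, R, rule.alpha)
            else:
                R = propagate_flat_conv(layer, a_in, R)
        conservation.append((layer.name, float(R.sum())))

    R_map = R[..., 0]  # drop the channel axis of the input layer
    sign_flipped = False
    if sign_harmonize and predicted_label == "negative":
        R_map = -R_map
        sign_flipped = True
    return RelevanceMap(
        data=R_map,
        voxel_size=tuple(voxel_size),
        start_neuron=start_neuron,
        start_score=start_score,
        predicted_label=predicted_label,
        sign_harmonized=sign_flipped,
        conservation=conservation,
    )


def conservation_report(rmap: RelevanceMap, tolerance: float = 0.01) -> dict:
    """Per-step relevance sums and flags for steps that leak > ``tolerance``.

    Leaks are expected only at epsilon-rule layers with biases; flat and
    alpha-beta steps on bias-free layers conserve to numerical precision.
    """
    sums = [float(v) for _, v in rmap.conservation]
    stages = [s for s, _ in rmap.conservation]
    flags = []
    for i in range(1, len(sums)):
        ref = max(abs(sums[i - 1]), np.finfo(float).tiny)
        rel = abs(sums[i] - sums[i - 1]) / ref
        if rel > tolerance:
            flags.append({"stage": stages[i], "relative_change": rel})
    return {
        "stages": stages,
        "sums": sums,
        "finite": bool(np.all(np.isfinite(sums))),
        "flagged": flags,
    }
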
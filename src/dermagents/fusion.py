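"""Team-value fusion and joint action selection.

The default decision rule is VDN summation: the team value of a
classification action is the sum of the two agents' values for that class,
while navigation team values are agent 1's alone (agent 2 has no navigation
actions). Ablation variants behind the same interface: a fixed 0.5:0.5
average, attention weighting (a learned softmax over the two agents' state
summaries), and a learned linear head over the concatenated class-value
vectors.
"""

from __future__ import annotations

import numpy as np
from scipy.special import softmax

from .errors import ConfigurationError, ContractError, DomainError
from .nn import Dense, Module

N_NAV_ACTIONS = 4

FUSION_KINDS = ("vdn-sum", "fixed-average", "attention", "concat-head")


class FusionRule(Module):
    """Base fusion rule; parameter-free rules are plain pass-throughs."""

    kind: str = ""
    has_summaries = False

    def fuse(self, q1_class: np.ndarray, q2: np.ndarray, summaries=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Gradient of the fused values w.r.t. (q1_class, q2)."""
        raise NotImplementedError


class VDNSum(FusionRule):
    kind = "vdn-sum"

    def fuse(self, q1_class, q2, summaries=None):
        return q1_class + q2

    def backward(self, dout):
        return dout, dout


class FixedAverage(FusionRule):
    kind = "fixed-average"

    def fuse(self, q1_class, q2, summaries=None):
        return 0.5 * q1_class + 0.5 * q2

    def backward(self, dout):
        return 0.5 * dout, 0.5 * dout


class AttentionFusion(FusionRule):
    """Convex combination alpha1*q1 + alpha2*q2 with alpha = softmax of
    learned linear scores over the agents' state summaries (spatial pooled
    features, temporal hidden state). Gradients flow to the scorer and the
    Q-vectors; the summaries are treated as constants here."""

    kind = "attention"
    has_summaries = True

    def __init__(self, d_spatial: int, d_temporal: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.w1 = self.add_param("w1", rng.normal(0, 0.1, size=d_spatial))
        self.w2 = self.add_param("w2", rng.normal(0, 0.1, size=d_temporal))
        self.b = self.add_param("b", np.zeros(2))
        self._cache = None

    def alphas(self, summaries) -> np.ndarray:
        f, h = summaries
        f = np.atleast_2d(f)
        h = np.atleast_2d(h)
        scores = np.stack([f @ self.w1 + self.b[0], h @ self.w2 + self.b[1]], axis=1)
        return softmax(scores, axis=1)  # (N, 2), rows sum to 1, nonnegative

    def fuse(self, q1_class, q2, summaries=None):
        if summaries is None:
            raise ContractError("attention fusion needs (spatial, temporal) summaries")
        q1c = np.atleast_2d(q1_class)
        q2m = np.atleast_2d(q2)
        a = self.alphas(summaries)
        self._cache = (q1c, q2m, a, summaries)
        out = a[:, :1] * q1c + a[:, 1:] * q2m
        return out[0] if np.ndim(q1_class) == 1 else out

    def backward(self, dout):
        q1c, q2m, a, summaries = self._cache
        dout = np.atleast_2d(dout)
        dq1 = a[:, :1] * dout
        dq2 = a[:, 1:] * dout
        # d alpha_i = sum_c dout_c * q_i[c]; softmax jacobian over the 2 scores
        dv1 = (dout * q1c).sum(axis=1)
        dv2 = (dout * q2m).sum(axis=1)
        common = a[:, 0] * a[:, 1]
        ds1 = common * (dv1 - dv2)
        ds2 = -ds1
        f = np.atleast_2d(summaries[0])
        h = np.atleast_2d(summaries[1])
        self._grads["w1"] += ds1 @ f
        self._grads["w2"] += ds2 @ h
        self._grads["b"] += np.array([ds1.sum(), ds2.sum()])
        return dq1, dq2


class ConcatHead(FusionRule):
    """Learned linear map of the concatenated per-agent class-value vectors."""

    kind = "concat-head"

    def __init__(self, n_classes: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.n_classes = n_classes
        head = Dense(2 * n_classes, n_classes, rng)
        # start at the VDN sum so the rule is sane before training
        head.W[...] = np.vstack([np.eye(n_classes), np.eye(n_classes)])
        self.head = self.add_child("head", head)

    def fuse(self, q1_class, q2, summaries=None):
        q1c = np.atleast_2d(q1_class)
        q2m = np.atleast_2d(q2)
        out = self.head.forward(np.concatenate([q1c, q2m], axis=1))
        return out[0] if np.ndim(q1_class) == 1 else out

    def backward(self, dout):
        dz = self.head.backward(np.atleast_2d(dout))
        k = self.n_classes
        return dz[:, :k], dz[:, k:]


def make_fusion(
    kind: str,
    n_classes: int,
    rng: np.random.Generator | None = None,
    d_spatial: int = 64,
    d_temporal: int = 64,
) -> FusionRule:
    if kind == "vdn-sum":
        return VDNSum()
    if kind == "fixed-average":
        return FixedAverage()
    if kind == "attention":
        return AttentionFusion(d_spatial, d_temporal, rng or np.random.default_rng(0))
    if kind == "concat-head":
        return ConcatHead(n_classes, rng or np.random.default_rng(0))
    raise ConfigurationError(f"unknown fusion rule {kind!r}")


def fuse_class_values(
    q1: np.ndarray, q2: np.ndarray, rule: FusionRule, summaries=None
) -> np.ndarray:
    """Per-class team values from the two agents' Q-vectors.

    ``q1`` spans the full joint action space (nav + classes); ``q2`` spans
    classes only.
    """
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    if q1.shape[-1] != q2.shape[-1] + N_NAV_ACTIONS:
        raise ContractError(
            f"arity mismatch: |A1|={q1.shape[-1]} vs |A2|+4={q2.shape[-1] + N_NAV_ACTIONS}"
        )
    return rule.fuse(q1[..., N_NAV_ACTIONS:], q2, summaries=summaries)


def team_values(
    q1: np.ndarray, q2: np.ndarray, rule: FusionRule, summaries=None
) -> np.ndarray:
    """Team values over all K+4 joint actions (nav values are agent 1's own)."""
    fused = fuse_class_values(q1, q2, rule, summaries=summaries)
    return np.concatenate([np.asarray(q1, dtype=float)[..., :N_NAV_ACTIONS], fused], axis=-1)


def select_joint_action(
    q1: np.ndarray,
    q2: np.ndarray,
    rule: FusionRule,
    epsilon: float,
    rng: np.random.Generator,
    allowed: np.ndarray | None = None,
    summaries=None,
) -> int:
    """Epsilon-greedy argmax over team values; ties break to the lowest index.

    ``allowed`` optionally masks actions (used when the decision is forced
    at the horizon); exploration is uniform over the allowed actions.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise DomainError("epsilon must lie in [0, 1]")
    values = team_values(q1, q2, rule, summaries=summaries)
    if values.ndim != 1:
        raise ContractError("select_joint_action works on a single state")
    if allowed is None:
        allowed = np.ones(values.shape[0], dtype=bool)
    idx = np.flatnonzero(allowed)
    if epsilon > 0.0 and rng.random() < epsilon:
        return int(rng.choice(idx))
    masked = np.where(allowed, values, -np.inf)
    return int(np.argmax(masked))


def class_probabilities(fused_class_values: np.ndarray, tau: float = 1.0) -> np.ndarray:
    """Temperature softmax over per-class team values (shift invariant)."""
    if tau <= 0:
        raise DomainError("temperature tau must be positive")
    return softmax(np.asarray(fused_class_values, dtype=float) / tau, axis=-1)
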
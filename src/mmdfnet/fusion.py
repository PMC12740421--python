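"""Dynamic gated fusion of modality embeddings and the joint objective.

A two-layer gate MLP maps the patient's encoded clinical attributes to three
logits u = W2·ReLU(W1·x + b1) + b2, softmax-normalized into a weight simplex
w = (w_CT, w_LungFunction, w_Environment).  The fused representation is the
convex combination

    f_fusion = w_CT · f_CT + w_LF · f_LF + w_Env · f_Env

followed by a linear classification head (sigmoid for binary risk, softmax
for the optional 3-stage mode).  The joint objective is

    L_total = L_cls + lambda1 · L_contrast + lambda2 · L_WGAN

with default weights lambda1 = 0.5, lambda2 = 0.2 and gate width h = 128.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, logsumexp
from ._nn import MLP

__all__ = ["GatingNetwork", "LossBreakdown", "gating_weights",
           "fuse_features", "classify", "total_loss"]

MODALITIES = ("CT", "lung_function", "environment")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class GatingNetwork:
    """Gate MLP: clinical vector -> softmax weights over the 3 modalities."""

    def __init__(self, rng: np.random.Generator, input_dim: int,
                 hidden: int = 128):
        if hidden < 1:
            raise ValueError("gate hidden width must be >= 1")
        self.mlp = MLP(rng, input_dim, [hidden], 3, zero_final=True)

    def __call__(self, x) -> Tensor:
        return gating_weights(x, self.mlp)

    def parameters(self, prefix: str = "gate") -> dict[str, Tensor]:
        return self.mlp.parameters(prefix)


def gating_weights(x, gate: MLP) -> Tensor:
    """Softmax of the gate-MLP logits; rows are positive and sum to 1."""
    x = _as_tensor(x)
    if x.ndim == 1:
        x = x.reshape(1, x.shape[0])
    logits = gate(x)
    if logits.shape[1] != 3:
        raise ValueError("gate must emit 3 logits (CT, lung function, environment)")
    lse = logsumexp(logits, axis=1, keepdims=True)
    return (logits - lse).exp()


def softmax_weights(logits) -> np.ndarray:
    """Plain softmax for raw logit arrays (no network)."""
    logits = np.asarray(logits, dtype=np.float64)
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def fuse_features(f_ct, f_lung, f_env, weights) -> Tensor:
    """Convex combination of three aligned d-dim modality feature batches.

    ``weights`` has shape (B, 3) (or (3,) for a single record); the result
    lies in the convex hull of the inputs row-wise.
    """
    f_ct, f_lung, f_env = map(_as_tensor, (f_ct, f_lung, f_env))
    w = _as_tensor(weights)
    if w.ndim == 1:
        w = w.reshape(1, 3)
    if not (f_ct.shape == f_lung.shape == f_env.shape):
        raise ValueError("modality features must share one shape")
    w0 = w.take_cols([0])
    w1 = w.take_cols([1])
    w2 = w.take_cols([2])
    return f_ct * w0 + f_lung * w1 + f_env * w2


def classify(fused, head: MLP) -> Tensor:
    """Risk probability from the fused embedding.

    Binary heads (1 logit) return sigmoid probabilities of shape (B,);
    3-class heads return softmax rows over stages.
    """
    fused = _as_tensor(fused)
    logits = head(fused)
    if logits.shape[1] == 1:
        return logits.sigmoid().reshape(logits.shape[0])
    lse = logsumexp(logits, axis=1, keepdims=True)
    return (logits - lse).exp()


@dataclass(frozen=True)
class LossBreakdown:
    """Joint-objective components; total is the exact linear combination."""

    classification: float
    contrastive: float
    adversarial: float
    lambda_contrast: float = 0.5
    lambda_wgan: float = 0.2

    @property
    def total(self) -> float:
        return (self.classification
                + self.lambda_contrast * self.contrastive
                + self.lambda_wgan * self.adversarial)


def total_loss(l_cls: float, l_contrast: float, l_wgan: float,
               lambda1: float = 0.5, lambda2: float = 0.2) -> LossBreakdown:
    """Combine the three objective components, refusing non-finite inputs."""
    for name, v in (("classification", l_cls), ("contrastive", l_contrast),
                    ("adversarial", l_wgan)):
        if not math.isfinite(float(v)):
            raise ValueError(f"non-finite {name} loss component: {v!r}")
    return LossBreakdown(float(l_cls), float(l_contrast), float(l_wgan),
                         lambda_contrast=lambda1, lambda_wgan=lambda2)


def binary_cross_entropy(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of sigmoid probabilities against 0/1 labels."""
    y = np.asarray(labels, dtype=np.float64)
    eps = 1e-12
    p = probs * (1 - 2 * eps) + eps
    return -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()).mean()
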
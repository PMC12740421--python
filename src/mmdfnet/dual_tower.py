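"""Dual-tower cross-modal alignment.

An image tower (small CNN) and a tabular tower (3-layer perceptron) are
projected into a shared d-dimensional space and L2-normalized; matched
image/tabular pairs in a batch form the diagonal of an NxN cosine-similarity
matrix, trained with the symmetric temperature-scaled InfoNCE objective:

    loss_I = mean_i -log( exp(S_ii/T) / sum_j exp(S_ij/T) )
    loss_T = mean_j -log( exp(S_jj/T) / sum_i exp(S_ij/T) )
    loss   = (loss_I + loss_T) / 2

with positives on the diagonal and all other batch entries as negatives.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, logsumexp
from ._nn import MLP, ConvTower

__all__ = ["DualTower", "project_normalize", "similarity_matrix",
           "contrastive_loss"]

_NORM_EPS = 1e-12


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def project_normalize(features, projection=None) -> Tensor:
    """Project a feature batch and L2-normalize each row onto the unit sphere.

    ``projection`` may be None (normalize as-is), a numpy matrix, or a
    parameter Tensor.  A row whose projection has zero norm cannot be
    normalized and raises ValueError.
    """
    feats = _as_tensor(features)
    if projection is not None:
        feats = feats @ _as_tensor(projection)
    norms_sq = (feats * feats).sum(axis=1, keepdims=True)
    if np.any(norms_sq.data <= _NORM_EPS):
        raise ValueError("cannot L2-normalize a zero-norm projected row")
    return feats * (norms_sq ** -0.5)


def similarity_matrix(image_emb, tab_emb) -> Tensor:
    """NxN cosine similarities S[i][j] = <I_i, T_j> for unit-norm rows.

    Row i is the i-th image embedding, column j the j-th tabular embedding;
    matched patient pairs sit on the diagonal.
    """
    a, b = _as_tensor(image_emb), _as_tensor(tab_emb)
    if a.shape != b.shape:
        raise ValueError("embedding batches must have identical shapes")
    return a @ b.T


def contrastive_loss(S, temperature: float = 0.05) -> Tensor:
    """Symmetric InfoNCE over a square similarity matrix.

    Invariant under simultaneous identical permutation of rows and columns;
    zero for N = 1 (a single positive with no negatives).
    """
    S = _as_tensor(S)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    n = S.shape[0]
    logits = S * (1.0 / temperature)
    diag = (logits * Tensor(np.eye(n))).sum(axis=1)
    loss_i = (logsumexp(logits, axis=1) - diag).mean()
    loss_t = (logsumexp(logits, axis=0) - diag).mean()
    return (loss_i + loss_t) * 0.5


class DualTower:
    """Image and tabular encoders with shared-space projections.

    The tabular tower is a 3-layer perceptron with ReLU activations
    (hidden widths default (64, 64)); the image tower is a small CNN
    (preset "tiny") or a residual tower (preset "resnet"/"resnet50").
    Projections map each tower's feature width into the shared dimension
    ``embed_dim``; the tabular projection is square when the tower is asked
    to emit ``embed_dim`` features, matching a learnable d x d map.
    """

    def __init__(self, rng: np.random.Generator, tab_dim: int,
                 embed_dim: int = 64, image_tower: str = "tiny",
                 tab_hidden: tuple[int, int] = (64, 64)):
        if embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        self.embed_dim = embed_dim
        self.image_tower = ConvTower(rng, image_tower)
        self.tab_tower = MLP(rng, tab_dim, list(tab_hidden), embed_dim)
        feat = self.image_tower.feature_dim
        self.W_img = Tensor(
            rng.normal(0, 1.0 / np.sqrt(feat), (feat, embed_dim)),
            requires_grad=True)
        self.W_tab = Tensor(
            rng.normal(0, 1.0 / np.sqrt(embed_dim), (embed_dim, embed_dim)),
            requires_grad=True)

    def encode_image(self, images) -> Tensor:
        """Images (B, H, W) standardized floats -> unit-norm (B, d)."""
        return project_normalize(self.image_tower(images), self.W_img)

    def encode_tabular(self, x) -> Tensor:
        """Encoded clinical matrix (B, p) -> unit-norm (B, d)."""
        return project_normalize(self.tab_tower(x), self.W_tab)

    def image_features(self, images) -> Tensor:
        """Projected (pre-normalization direction preserved) image features."""
        return self.encode_image(images)

    def alignment_loss(self, images, x, temperature: float = 0.05) -> Tensor:
        S = similarity_matrix(self.encode_image(images), self.encode_tabular(x))
        return contrastive_loss(S, temperature)

    def parameters(self, prefix: str = "dual") -> dict[str, Tensor]:
        out = self.image_tower.parameters(f"{prefix}.img")
        out.update(self.tab_tower.parameters(f"{prefix}.tab"))
        out[f"{prefix}.W_img"] = self.W_img
        out[f"{prefix}.W_tab"] = self.W_tab
        return out
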
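"""Small neural-network building blocks on top of the autograd core.

Layers hold their parameters as named ``Tensor`` objects so whole models can
be flattened to a ``{name: array}`` dict for checkpointing.  Initialization is
deterministic given a ``numpy.random.Generator``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ._autograd import Tensor

__all__ = ["Dense", "MLP", "ConvTower", "Adam", "conv2d", "mean_pool2"]


def he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape)


class Dense:
    """Affine layer y = x @ W + b with W of shape (in, out)."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W = Tensor(he_init(rng, n_in, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self, prefix: str) -> dict[str, Tensor]:
        return {f"{prefix}.W": self.W, f"{prefix}.b": self.b}


class MLP:
    """Fully connected network with ReLU hidden activations and linear output.

    ``widths`` lists the hidden layer sizes; an empty sequence gives a single
    affine map.  ``input_gradient_graph`` builds, as an autograd expression in
    the weights, the network's gradient with respect to its *input* at a fixed
    point — the quantity the WGAN-GP penalty constrains.  ReLU derivative masks
    are evaluated at the fixed input and treated as constants, which is exact
    almost everywhere (ReLU is piecewise linear).
    """

    def __init__(self, rng: np.random.Generator, n_in: int,
                 widths: Sequence[int], n_out: int,
                 final_bias: float = 0.0, zero_final: bool = False):
        self.n_in = n_in
        self.n_out = n_out
        sizes = [n_in, *widths, n_out]
        self.layers = [Dense(rng, sizes[i], sizes[i + 1])
                       for i in range(len(sizes) - 1)]
        if final_bias:
            # keeps degenerate (all-zero) inputs off the normalization pole
            self.layers[-1].b.data[:] = final_bias
        if zero_final:
            # start the map at a constant (e.g. a uniform softmax gate)
            self.layers[-1].W.data[:] = 0.0

    def __call__(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        for layer in self.layers[:-1]:
            x = layer(x).relu()
        return self.layers[-1](x)

    def parameters(self, prefix: str = "mlp") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for i, layer in enumerate(self.layers):
            out.update(layer.parameters(f"{prefix}.{i}"))
        return out

    def input_gradient_graph(self, x: np.ndarray) -> Tensor:
        """d(output)/d(input) rows for each sample in ``x`` (n_out must be 1).

        Returns a Tensor of shape (batch, n_in) that is differentiable with
        respect to the layer weights.
        """
        if self.n_out != 1:
            raise ValueError("input gradient chain requires scalar output")
        x = np.asarray(x, dtype=np.float64)
        # forward pass in plain numpy to collect ReLU masks
        masks = []
        a = x
        for layer in self.layers[:-1]:
            z = a @ layer.W.data + layer.b.data
            masks.append((z > 0).astype(np.float64))
            a = z * masks[-1]
        batch = x.shape[0]
        # backward chain as a graph in the weights
        g = Tensor(np.ones((batch, 1)))
        for layer, mask in zip(reversed(self.layers[1:]), reversed(masks)):
            g = (g @ layer.W.T) * Tensor(mask)
        return g @ self.layers[0].W.T


# -- convolutions ---------------------------------------------------------

_COL_INDEX_CACHE: dict[tuple, tuple] = {}


def _im2col_indices(C: int, H: int, W: int, kh: int, kw: int, pad: int):
    key = (C, H, W, kh, kw, pad)
    if key not in _COL_INDEX_CACHE:
        out_h = H + 2 * pad - kh + 1
        out_w = W + 2 * pad - kw + 1
        i0 = np.repeat(np.arange(kh), kw)
        i0 = np.tile(i0, C)
        i1 = np.repeat(np.arange(out_h), out_w)
        j0 = np.tile(np.arange(kw), kh * C)
        j1 = np.tile(np.arange(out_w), out_h)
        i = i0.reshape(-1, 1) + i1.reshape(1, -1)
        j = j0.reshape(-1, 1) + j1.reshape(1, -1)
        k = np.repeat(np.arange(C), kh * kw).reshape(-1, 1)
        _COL_INDEX_CACHE[key] = (k, i, j, out_h, out_w)
    return _COL_INDEX_CACHE[key]


def conv2d(x: Tensor, W: Tensor, b: Tensor, pad: int = 1) -> Tensor:
    """Stride-1 2-D convolution; x (B,C,H,W), W (outC, C*kh*kw), b (outC,)."""
    B, C, H, Wd = x.shape
    out_c = W.shape[0]
    ksq = W.shape[1] // C
    kh = kw = int(round(np.sqrt(ksq)))
    k, i, j, out_h, out_w = _im2col_indices(C, H, Wd, kh, kw, pad)
    if pad:
        padded_data = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        xp = Tensor(padded_data)
        if x.requires_grad:
            xp.requires_grad = True
            xp._parents = (x,)

            def backward(g):
                x._acc(g[:, :, pad:-pad, pad:-pad])

            xp._backward = backward
    else:
        xp = x
    cols = xp.gather((slice(None), k, i, j))      # (B, C*kh*kw, L)
    out = W @ cols                                 # (B, outC, L)
    out = out + b.reshape(1, out_c, 1)
    return out.reshape(B, out_c, out_h, out_w)


def mean_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling; spatial dims must be even."""
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError("mean_pool2 requires even spatial dimensions")
    return x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))


class ConvTower:
    """Convolutional image encoder producing a flat feature vector per image.

    preset "tiny": three conv(3x3)+ReLU+pool2 blocks, channels (8, 16, 32),
    then global average pooling — a few thousand parameters, fast on one CPU.
    preset "resnet" (alias "resnet50"): residual tower with four stages of
    identity-skip conv blocks, channels (16, 32, 64, 128).  Input height and
    width must be divisible by 2**n_stages.
    """

    PRESETS = {"tiny": (8, 16, 32), "resnet": (16, 32, 64, 128),
               "resnet50": (16, 32, 64, 128)}

    def __init__(self, rng: np.random.Generator, preset: str = "tiny",
                 in_channels: int = 1):
        if preset not in self.PRESETS:
            raise ValueError(f"unknown image tower preset: {preset!r}")
        self.preset = preset
        self.residual = preset in ("resnet", "resnet50")
        chans = self.PRESETS[preset]
        self.feature_dim = chans[-1]
        self.blocks = []
        c_in = in_channels
        for c_out in chans:
            block = {
                "W": Tensor(he_init(rng, c_in * 9, (c_out, c_in * 9)),
                            requires_grad=True),
                "b": Tensor(np.zeros(c_out), requires_grad=True),
            }
            if self.residual:
                block["W2"] = Tensor(he_init(rng, c_out * 9, (c_out, c_out * 9)),
                                     requires_grad=True)
                block["b2"] = Tensor(np.zeros(c_out), requires_grad=True)
            self.blocks.append(block)
            c_in = c_out

    def __call__(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim == 3:
            x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
        for block in self.blocks:
            h = conv2d(x, block["W"], block["b"]).relu()
            if self.residual:
                h2 = conv2d(h, block["W2"], block["b2"])
                h = (h2 + h).relu()
            x = mean_pool2(h)
        return x.mean(axis=(2, 3))  # global average pool -> (B, C_last)

    def parameters(self, prefix: str = "image_tower") -> dict[str, Tensor]:
        out = {}
        for i, block in enumerate(self.blocks):
            for name, t in block.items():
                out[f"{prefix}.{i}.{name}"] = t
        return out


class Adam:
    """Adam optimizer over a {name: Tensor} parameter dict (in-place steps)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def flatten_params(params: dict[str, Tensor]) -> dict[str, np.ndarray]:
    return {k: p.data.copy() for k, p in params.items()}


def load_params(params: dict[str, Tensor], state: dict[str, np.ndarray]) -> None:
    for k, p in params.items():
        p.data[...] = state[k]
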
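"""Conditional WGAN-GP for environmental exposure synthesis and imputation.

A generator MLP maps (clinical condition vector, Gaussian noise) to the
environmental variables (PM2.5 and exposure years, jointly, in standardized
space); a critic MLP scores (condition, environment) pairs.  Training uses
the Wasserstein surrogate with gradient penalty

    L_critic = E[D(c, G(c, z))] - E[D(c, x)] + phi_gp * GP
    GP       = E[ (|| grad_xhat D(c, xhat) ||_2 - 1)^2 ],
    xhat     = eps * x + (1 - eps) * G(c, z),  eps ~ U(0, 1)

(minimization form), with several critic updates per generator update.
The penalty gradient is taken with respect to the environmental input at
fixed condition.  Generated values are de-standardized and clamped to the
physical range [0, inf) when written back into a cohort.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autograd import Tensor
from ._nn import MLP, Adam, flatten_params, load_params

logger = logging.getLogger(__name__)

__all__ = ["GanParams", "EnvCGAN", "gradient_penalty", "critic_loss",
           "generator_loss", "train_cgan", "impute_environment"]


@dataclass
class GanParams:
    """Architecture and objective hyperparameters for the conditional GAN."""

    cond_dim: int
    env_dim: int = 2
    noise_dim: int = 8
    gen_hidden: tuple[int, ...] = (64, 64)
    critic_hidden: tuple[int, ...] = (64, 64)
    phi_gp: float = 10.0
    n_critic: int = 5
    lr: float = 1e-3
    betas: tuple[float, float] = (0.0, 0.9)

    def validate(self) -> None:
        if self.phi_gp <= 0:
            raise ValueError("phi_gp must be > 0")
        if self.n_critic < 1:
            raise ValueError("n_critic must be >= 1")
        if self.env_dim < 1 or self.cond_dim < 0 or self.noise_dim < 1:
            raise ValueError("dimensions must be positive")


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite values in {name}")


def interpolate(x_real: np.ndarray, x_gen: np.ndarray,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample random convex combination of real and generated points."""
    eps = rng.uniform(0.0, 1.0, size=(x_real.shape[0], 1))
    return eps * x_real + (1.0 - eps) * x_gen, eps


def gradient_penalty(critic: MLP, x_real: np.ndarray, x_gen: np.ndarray,
                     condition: np.ndarray, rng: np.random.Generator,
                     env_cols: np.ndarray | None = None) -> Tensor:
    """Mean over the batch of (||grad_xhat D(c, xhat)||_2 - 1)^2.

    ``critic`` takes the concatenation [condition, environment]; the
    gradient is taken with respect to the environment block only
    (``env_cols`` defaults to the trailing x columns).
    """
    x_real = np.asarray(x_real, dtype=np.float64)
    x_gen = np.asarray(x_gen, dtype=np.float64)
    condition = np.asarray(condition, dtype=np.float64)
    if x_real.shape[0] == 0:
        raise ValueError("gradient penalty requires a non-empty batch")
    xhat, _ = interpolate(x_real, x_gen, rng)
    inp = np.concatenate([condition, xhat], axis=1)
    if env_cols is None:
        env_cols = np.arange(condition.shape[1], inp.shape[1])
    grad_full = critic.input_gradient_graph(inp)      # (B, cond+env)
    grad_env = grad_full.take_cols(env_cols)
    norms = ((grad_env * grad_env).sum(axis=1) + 1e-12) ** 0.5
    return ((norms - 1.0) ** 2.0).mean()


def critic_loss(critic: MLP, generator: MLP, x_real: np.ndarray,
                condition: np.ndarray, noise: np.ndarray,
                phi_gp: float, rng: np.random.Generator) -> Tensor:
    """Minimization-form critic objective: score gap + phi_gp * GP."""
    _check_finite("x_real", x_real)
    _check_finite("condition", condition)
    x_gen = generator(np.concatenate([condition, noise], axis=1)).data
    d_real = critic(np.concatenate([condition, x_real], axis=1)).mean()
    d_gen = critic(np.concatenate([condition, x_gen], axis=1)).mean()
    gp = gradient_penalty(critic, x_real, x_gen, condition, rng)
    return d_gen - d_real + phi_gp * gp


def generator_loss(critic: MLP, generator: MLP, condition: np.ndarray,
                   noise: np.ndarray) -> Tensor:
    """Generator objective: -E[D(c, G(c, z))]."""
    _check_finite("condition", condition)
    x_gen = generator(Tensor(np.concatenate([condition, noise], axis=1)))
    from ._autograd import concat
    score = critic(concat([Tensor(condition), x_gen], axis=1))
    return -score.mean()


class EnvCGAN:
    """Trained conditional generator/critic pair with its schema moments.

    ``env_mu`` / ``env_sd`` standardize the environmental variables during
    training; draws are de-standardized (and clamped to >= 0) on the way out.
    """

    def __init__(self, params: GanParams, seed: int = 0):
        params.validate()
        self.params = params
        rng = np.random.default_rng(seed)
        self.generator = MLP(rng, params.cond_dim + params.noise_dim,
                             list(params.gen_hidden), params.env_dim)
        self.critic = MLP(rng, params.cond_dim + params.env_dim,
                          list(params.critic_hidden), 1)
        self.env_mu = np.zeros(params.env_dim)
        self.env_sd = np.ones(params.env_dim)
        self.loss_trace: list[dict] = []

    def parameters(self) -> dict[str, Tensor]:
        out = self.generator.parameters("gen")
        out.update(self.critic.parameters("critic"))
        return out

    def state_dict(self) -> dict:
        return {"params": flatten_params(self.parameters()),
                "env_mu": self.env_mu.copy(), "env_sd": self.env_sd.copy(),
                "gan": dataclasses.asdict(self.params)}

    def load_state_dict(self, state: dict) -> None:
        load_params(self.parameters(), state["params"])
        self.env_mu = np.asarray(state["env_mu"], dtype=float)
        self.env_sd = np.asarray(state["env_sd"], dtype=float)

    def sample(self, condition: np.ndarray, rng: np.random.Generator,
               n_draws: int = 1) -> np.ndarray:
        """Draws (n_draws, B, env_dim) on the original (de-standardized) scale."""
        condition = np.atleast_2d(np.asarray(condition, dtype=np.float64))
        out = np.empty((n_draws, condition.shape[0], self.params.env_dim))
        for k in range(n_draws):
            z = rng.normal(size=(condition.shape[0], self.params.noise_dim))
            g = self.generator(np.concatenate([condition, z], axis=1)).data
            out[k] = np.maximum(g * self.env_sd + self.env_mu, 0.0)
        return out


def train_cgan(conditions: np.ndarray, env: np.ndarray, params: GanParams,
               epochs: int = 200, batch_size: int = 64, seed: int = 0
               ) -> EnvCGAN:
    """Train the conditional WGAN-GP on observed (condition, environment) rows.

    Deterministic given ``seed``; returns the trained model with a per-epoch
    loss trace (mean critic and generator objectives).
    """
    conditions = np.asarray(conditions, dtype=np.float64)
    env = np.atleast_2d(np.asarray(env, dtype=np.float64))
    if env.shape[0] != conditions.shape[0]:
        raise ValueError("conditions and env must have equal row counts")
    n = env.shape[0]
    if n == 0:
        raise ValueError("no observed environmental data to train on")
    if n == 1:
        warnings.warn("training C-GAN on a single observed record; "
                      "the generator will collapse to that record")

    params = dataclasses.replace(params, cond_dim=conditions.shape[1],
                                 env_dim=env.shape[1])
    model = EnvCGAN(params, seed=seed)
    model.env_mu = env.mean(axis=0)
    model.env_sd = env.std(axis=0)
    model.env_sd[model.env_sd <= 0] = 1.0
    env_z = (env - model.env_mu) / model.env_sd

    rng = np.random.default_rng(seed + 1)
    opt_c = Adam(model.critic.parameters("c"), lr=params.lr, betas=params.betas)
    opt_g = Adam(model.generator.parameters("g"), lr=params.lr,
                 betas=params.betas)
    bs = min(batch_size, n)
    for epoch in range(epochs):
        order = rng.permutation(n)
        c_losses, g_losses = [], []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            cond_b, env_b = conditions[idx], env_z[idx]
            for _ in range(params.n_critic):
                noise = rng.normal(size=(len(idx), params.noise_dim))
                opt_c.zero_grad()
                lc = critic_loss(model.critic, model.generator, env_b,
                                 cond_b, noise, params.phi_gp, rng)
                lc.backward()
                opt_c.step()
            noise = rng.normal(size=(len(idx), params.noise_dim))
            opt_g.zero_grad()
            lg = generator_loss(model.critic, model.generator, cond_b, noise)
            lg.backward()
            opt_g.step()
            c_losses.append(lc.item())
            g_losses.append(lg.item())
        model.loss_trace.append({"epoch": epoch,
                                 "critic_loss": float(np.mean(c_losses)),
                                 "generator_loss": float(np.mean(g_losses))})
    return model


def impute_environment(cohort: pd.DataFrame, model: EnvCGAN,
                       conditions: np.ndarray, n_draws: int = 1,
                       seed: int = 0,
                       env_cols: tuple[str, str] = ("pm25", "exposure_years")
                       ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Fill masked environmental cells with conditional generator draws.

    Masked rows (``env_missing`` True) are filled with the mean of
    ``n_draws`` conditional draws; observed rows are returned bit-identical.
    With ``n_draws > 1`` a sidecar long-format DataFrame of all draws is also
    returned (multiple imputation), else None.
    """
    if model.params.env_dim != len(env_cols):
        raise ValueError("checkpoint env dimension does not match cohort schema")
    if conditions.shape[0] != len(cohort):
        raise ValueError("condition matrix does not match cohort length")
    out = cohort.copy()
    masked = out["env_missing"].to_numpy().astype(bool)
    if not masked.any():
        return out, None
    rng = np.random.default_rng(seed)
    draws = model.sample(conditions[masked], rng, n_draws=n_draws)
    fill = draws.mean(axis=0)
    for j, col in enumerate(env_cols):
        vals = out[col].to_numpy(dtype=float)
        vals[masked] = fill[:, j]
        out[col] = vals
    sidecar = None
    if n_draws > 1:
        rows = []
        ids = out.loc[masked, "id"].to_numpy()
        for k in range(n_draws):
            for i, pid in enumerate(ids):
                row = {"id": pid, "draw": k}
                for j, col in enumerate(env_cols):
                    row[col] = draws[k, i, j]
                rows.append(row)
        sidecar = pd.DataFrame(rows)
    return out, sidecar
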
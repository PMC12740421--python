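"""Conditional WGAN-GP: penalty closed forms, training, imputation."""

import numpy as np
import pandas as pd
import pytest

from mmdfnet._nn import MLP
from mmdfnet.env_cgan import (EnvCGAN, GanParams, critic_loss,
                              generator_loss, gradient_penalty,
                              impute_environment, train_cgan)


def _linear_critic(rng, cond_dim, env_weights, cond_weights=None):
    critic = MLP(rng, cond_dim + len(env_weights), [], 1)
    w = np.zeros((cond_dim + len(env_weights), 1))
    if cond_weights is not None:
        w[:cond_dim, 0] = cond_weights
    w[cond_dim:, 0] = env_weights
    critic.layers[0].W.data[:] = w
    critic.layers[0].b.data[:] = 0.0
    return critic


class TestGradientPenalty:
    def test_unit_slope_linear_critic_zero_penalty(self, rng):
        """D(x) = w.x with ||w|| = 1 has gradient norm 1 everywhere."""
        critic = _linear_critic(rng, 1, [0.6, 0.8], cond_weights=[0.3])
        gp = gradient_penalty(critic, rng.normal(size=(8, 2)),
                              rng.normal(size=(8, 2)),
                              rng.normal(size=(8, 1)), rng)
        assert gp.item() == pytest.approx(0.0, abs=1e-10)

    def test_constant_critic_penalty_one(self, rng):
        critic = _linear_critic(rng, 1, [0.0, 0.0])
        gp = gradient_penalty(critic, rng.normal(size=(8, 2)),
                              rng.normal(size=(8, 2)),
                              rng.normal(size=(8, 1)), rng)
        assert gp.item() == pytest.approx(1.0, abs=1e-5)

    def test_slope_two_penalty_one(self, rng):
        """D(x) = 2 x1: gradient norm 2, penalty (2-1)^2 = 1."""
        critic = _linear_critic(rng, 1, [2.0, 0.0])
        gp = gradient_penalty(critic, rng.normal(size=(8, 2)),
                              rng.normal(size=(8, 2)),
                              rng.normal(size=(8, 1)), rng)
        assert gp.item() == pytest.approx(1.0, abs=1e-9)

    def test_empty_batch_rejected(self, rng):
        critic = _linear_critic(rng, 1, [1.0, 0.0])
        with pytest.raises(ValueError):
            gradient_penalty(critic, np.empty((0, 2)), np.empty((0, 2)),
                             np.empty((0, 1)), rng)


class TestCriticAndGeneratorLoss:
    def test_identical_real_and_generated_unit_slope(self, rng):
        """Generator reproducing the real batch with a unit-slope critic:
        score gap 0 and zero penalty."""
        gen = MLP(rng, 3, [], 2)  # cond 1 + noise 2 -> env 2
        gen.layers[0].W.data[:] = 0.0
        gen.layers[0].b.data[:] = 0.0
        critic = _linear_critic(rng, 1, [1.0, 0.0])
        cond = rng.normal(size=(6, 1))
        x_real = np.zeros((6, 2))  # equals generator output
        noise = rng.normal(size=(6, 2))
        loss = critic_loss(critic, gen, x_real, cond, noise, phi_gp=10.0,
                           rng=rng)
        assert loss.item() == pytest.approx(0.0, abs=1e-10)

    def test_constant_critic_loss_is_phi_gp(self, rng):
        gen = MLP(rng, 3, [], 2)
        critic = _linear_critic(rng, 1, [0.0, 0.0])
        cond = rng.normal(size=(6, 1))
        loss = critic_loss(critic, gen, rng.normal(size=(6, 2)), cond,
                           rng.normal(size=(6, 2)), phi_gp=10.0, rng=rng)
        assert loss.item() == pytest.approx(10.0, rel=1e-4)

    def test_zero_phi_gp_reduces_to_wasserstein_gap(self, rng):
        gen = MLP(rng, 3, [8], 2)
        critic = _linear_critic(rng, 1, [1.5, -0.5])
        cond = rng.normal(size=(6, 1))
        noise = rng.normal(size=(6, 2))
        x_real = rng.normal(size=(6, 2))
        loss = critic_loss(critic, gen, x_real, cond, noise, phi_gp=0.0,
                           rng=rng)
        x_gen = gen(np.concatenate([cond, noise], 1)).data
        gap = (critic(np.concatenate([cond, x_gen], 1)).data.mean()
               - critic(np.concatenate([cond, x_real], 1)).data.mean())
        assert loss.item() == pytest.approx(gap, rel=1e-10)

    def test_non_finite_input_rejected(self, rng):
        gen = MLP(rng, 3, [], 2)
        critic = _linear_critic(rng, 1, [1.0, 0.0])
        bad = np.full((3, 2), np.nan)
        with pytest.raises(ValueError, match="x_real"):
            critic_loss(critic, gen, bad, np.zeros((3, 1)),
                        np.zeros((3, 2)), 10.0, rng)

    def test_generator_loss_is_negated_mean_score(self, rng):
        gen = MLP(rng, 3, [8], 2)
        critic = _linear_critic(rng, 1, [1.0, 1.0])
        cond = rng.normal(size=(5, 1))
        noise = rng.normal(size=(5, 2))
        loss = generator_loss(critic, gen, cond, noise)
        x_gen = gen(np.concatenate([cond, noise], 1)).data
        score = critic(np.concatenate([cond, x_gen], 1)).data.mean()
        assert loss.item() == pytest.approx(-score, rel=1e-10)


@pytest.fixture(scope="module")
def recovery_gan():
    """GAN trained on env = 30 + 10 * smoker + N(0, 2^2)."""
    rng = np.random.default_rng(5)
    n = 400
    smoker = (rng.random(n) < 0.5).astype(float)
    env = 30 + 10 * smoker + rng.normal(0, 2, n)
    params = GanParams(cond_dim=1, env_dim=1, noise_dim=4,
                       gen_hidden=(32, 32), critic_hidden=(32, 32))
    return train_cgan(smoker.reshape(-1, 1), env.reshape(-1, 1), params,
                      epochs=80, batch_size=128, seed=0)


class TestTrainCgan:
    def test_conditional_mean_recovery(self, recovery_gan):
        """Monte-Carlo conditional means of the generator recover the
        data-generating process within 1.5 units."""
        m0 = recovery_gan.sample(np.zeros((1500, 1)),
                                 np.random.default_rng(1)).mean()
        m1 = recovery_gan.sample(np.ones((1500, 1)),
                                 np.random.default_rng(2)).mean()
        assert abs(m0 - 30.0) < 1.5
        assert abs(m1 - 40.0) < 1.5

    def test_training_determinism(self):
        rng = np.random.default_rng(2)
        cond = rng.normal(size=(30, 2))
        env = rng.normal(30, 3, size=(30, 1))
        params = GanParams(cond_dim=2, env_dim=1, gen_hidden=(8,),
                           critic_hidden=(8,))
        a = train_cgan(cond, env, params, epochs=1, seed=4)
        b = train_cgan(cond, env, params, epochs=1, seed=4)
        for k, p in a.parameters().items():
            assert np.array_equal(p.data, b.parameters()[k].data), k

    def test_single_record_warns_but_runs(self):
        params = GanParams(cond_dim=1, env_dim=1, gen_hidden=(4,),
                           critic_hidden=(4,))
        with pytest.warns(UserWarning, match="single observed record"):
            model = train_cgan(np.zeros((1, 1)), np.full((1, 1), 35.0),
                               params, epochs=1, seed=0)
        assert np.isfinite(model.loss_trace[-1]["critic_loss"])

    def test_no_data_rejected(self):
        params = GanParams(cond_dim=1, env_dim=1)
        with pytest.raises(ValueError):
            train_cgan(np.empty((0, 1)), np.empty((0, 1)), params)

    def test_energy_distance_drops_during_training(self):
        """Two-component conditional Gaussian: generated samples move
        toward held-out real samples under the energy distance."""
        from scipy.stats import energy_distance
        rng = np.random.default_rng(9)
        n = 300
        cond = (rng.random(n) < 0.5).astype(float)
        env = np.where(cond == 1, rng.normal(45, 3, n), rng.normal(25, 3, n))
        held_cond = (np.arange(200) % 2).astype(float)
        held_env = np.where(held_cond == 1,
                            np.random.default_rng(10).normal(45, 3, 200),
                            np.random.default_rng(11).normal(25, 3, 200))
        params = GanParams(cond_dim=1, env_dim=1, noise_dim=4,
                           gen_hidden=(32, 32), critic_hidden=(32, 32))

        def gen_dist(model):
            draws = model.sample(held_cond.reshape(-1, 1),
                                 np.random.default_rng(3)).ravel()
            return energy_distance(draws, held_env)

        init = EnvCGAN(params, seed=0)
        init.env_mu = np.array([env.mean()])
        init.env_sd = np.array([env.std()])
        trained = train_cgan(cond.reshape(-1, 1), env.reshape(-1, 1), params,
                             epochs=60, batch_size=128, seed=0)
        assert gen_dist(trained) < gen_dist(init)


class TestImputeEnvironment:
    def _cohort_df(self, n=10, n_masked=3):
        df = pd.DataFrame({
            "id": [f"P{i}" for i in range(n)],
            "pm25": np.linspace(20, 50, n),
            "exposure_years": np.linspace(5, 20, n),
            "env_missing": [i < n_masked for i in range(n)],
        })
        df.loc[df.env_missing, ["pm25", "exposure_years"]] = np.nan
        return df

    def _gan(self, cond_dim=2):
        params = GanParams(cond_dim=cond_dim, env_dim=2, gen_hidden=(8,),
                           critic_hidden=(8,))
        return EnvCGAN(params, seed=0)

    def test_no_masked_records_returned_bitwise_identical(self, rng):
        df = self._cohort_df(n_masked=0)
        out, sidecar = impute_environment(df, self._gan(), rng.normal(size=(10, 2)),
                                          seed=0)
        pd.testing.assert_frame_equal(out, df)
        assert sidecar is None

    def test_observed_cells_never_modified(self, rng):
        df = self._cohort_df()
        out, _ = impute_environment(df, self._gan(), rng.normal(size=(10, 2)),
                                    n_draws=3, seed=0)
        obs = ~df.env_missing
        assert np.array_equal(out.loc[obs, "pm25"], df.loc[obs, "pm25"])
        assert np.array_equal(out.loc[obs, "exposure_years"],
                              df.loc[obs, "exposure_years"])

    def test_multiple_imputation_draws_contract(self, rng):
        """n_draws = 5: all draws retained, finite, and >= 0 after clamping."""
        df = self._cohort_df()
        out, sidecar = impute_environment(df, self._gan(),
                                          rng.normal(size=(10, 2)),
                                          n_draws=5, seed=0)
        assert len(sidecar) == 5 * df.env_missing.sum()
        assert np.all(np.isfinite(sidecar[["pm25", "exposure_years"]]))
        assert np.all(sidecar[["pm25", "exposure_years"]].to_numpy() >= 0)
        assert np.all(np.isfinite(out[["pm25", "exposure_years"]]))

    def test_imputed_conditional_mean_recovery(self, recovery_gan):
        """A masked smoker record is imputed near the true conditional
        mean of 40."""
        df = pd.DataFrame({"id": ["P0"], "pm25": [np.nan],
                           "exposure_years": [np.nan],
                           "env_missing": [True]})
        # recovery GAN generates a single env variable conditioned on smoker
        out, sidecar = impute_environment(
            df, recovery_gan, np.ones((1, 1)), n_draws=1000, seed=1,
            env_cols=("pm25",))
        assert abs(sidecar["pm25"].mean() - 40.0) < 1.5

    def test_schema_mismatch_rejected(self, rng):
        df = self._cohort_df()
        with pytest.raises(ValueError, match="env dimension"):
            impute_environment(df, self._gan(), rng.normal(size=(10, 2)),
                               env_cols=("pm25",))
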
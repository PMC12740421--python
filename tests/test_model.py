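"""Joint training loop, results object, ablation runner, reports, CV."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mmdfnet.cohort import (CohortSpec, SyntheticImageParams,
                            generate_cohort, mask_environment,
                            render_cohort_images)
from mmdfnet.model import (MMDFModel, TrainConfig, cross_validate,
                           run_ablation, subgroup_weight_report, train_mmdf)
from mmdfnet.scenarios import partial_signal_cohort

FAST = dict(epochs=2, gan_epochs=3, batch_size=16)


@pytest.fixture(scope="module")
def small_cohort():
    spec = CohortSpec(n_copd=40, n_control=24, seed=5, env_missing_rate=0.2)
    records = generate_cohort(spec)
    params = SyntheticImageParams(height=16, width=16)
    images = render_cohort_images(records, params, seed=5)
    return records, images, params


@pytest.fixture(scope="module")
def fast_results(small_cohort):
    records, images, params = small_cohort
    cfg = TrainConfig(seed=3, **FAST)
    return train_mmdf(records, cfg, images=images, image_params=params)


class TestTrainMmdf:
    def test_identical_checkpoints_for_identical_seeds(self, small_cohort):
        records, images, params = small_cohort
        cfg = TrainConfig(seed=3, **FAST)
        a = train_mmdf(records, cfg, images=images, image_params=params)
        b = train_mmdf(records, cfg, images=images, image_params=params)
        for k, p in a.dual.parameters().items():
            assert np.array_equal(p.data, b.dual.parameters()[k].data), k
        assert np.array_equal(a.predict(), b.predict())
        assert a.threshold == b.threshold

    def test_trace_totals_are_exact_linear_combinations(self, fast_results):
        for b in fast_results.trace:
            assert b.total == (b.classification
                               + b.lambda_contrast * b.contrastive
                               + b.lambda_wgan * b.adversarial)
        frame = fast_results.loss_trace_frame()
        assert list(frame.columns) == ["epoch", "classification",
                                       "contrastive", "adversarial", "total"]

    def test_learning_progress_on_separable_cohort(self):
        """Training improves discrimination on a strongly separable cohort."""
        records, params = partial_signal_cohort(n_cases=40, n_controls=40,
                                                seed=2, env_shift=15,
                                                fev_shift=12)
        images = render_cohort_images(records, params, seed=2)
        cfg = TrainConfig(seed=1, epochs=12, gan_epochs=3, batch_size=16)
        res = train_mmdf(records, cfg, images=images, image_params=params)
        assert res.trace[-1].classification < res.trace[0].classification
        assert res.evaluate("train").auc > 0.8

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            MMDFModel([], TrainConfig())

    def test_batch_size_invariant(self, small_cohort):
        records, images, params = small_cohort
        cfg = TrainConfig(batch_size=1000, epochs=1)
        with pytest.raises(ValueError, match="batch_size"):
            MMDFModel(records, cfg, images=images, image_params=params)

    def test_unknown_ablation_component_rejected(self):
        with pytest.raises(ValueError, match="unknown ablation"):
            TrainConfig(disable=("dropout",)).validate()

    def test_summary_mentions_key_hyperparameters(self, fast_results):
        text = fast_results.summary()
        assert "T: 0.05" in text
        assert "lambda1: 0.5" in text
        assert "AUC" in text

    def test_save_checkpoint(self, fast_results, tmp_path):
        fast_results.save(tmp_path / "ckpt.npz")
        state = np.load(tmp_path / "ckpt.npz", allow_pickle=False)
        assert "__threshold" in state
        assert any(k.startswith("dual::") for k in state.files)

    def test_predict_on_new_records(self, fast_results):
        records, params = partial_signal_cohort(n_cases=5, n_controls=5,
                                                seed=9)
        images = render_cohort_images(records, fast_results.image_params,
                                      seed=9)
        scores = fast_results.predict(records, images)
        assert scores.shape == (10,)
        assert np.all((scores >= 0) & (scores <= 1))


class TestGatingWeightsOutputs:
    def test_weights_frame_rows_sum_to_one(self, fast_results):
        wf = fast_results.weights_frame()
        w = wf[["w_CT", "w_lung_function", "w_environment"]].to_numpy()
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_subgroup_report_group_means_sum_to_one(self, fast_results):
        for grouping in ("smoking", "stage", "pm25"):
            rep = subgroup_weight_report(fast_results, grouping=grouping)
            total = (rep["CT_mean"] + rep["lung_function_mean"]
                     + rep["environment_mean"])
            assert np.allclose(total, 1.0, atol=1e-6)
            assert (rep["n"] > 0).all()

    def test_pm25_threshold_splits_reference_cohort(self, default_cohort):
        """Table-style means (42.5 vs 28.6) straddle the 40 ug/m3 cut."""
        pm = np.array([r.pm25 for r in default_cohort])
        assert (pm >= 40).sum() > 0 and (pm < 40).sum() > 0

    def test_single_group_cohort_single_row(self, small_cohort):
        records, images, params = small_cohort
        cfg = TrainConfig(seed=3, **FAST)
        res = train_mmdf(records, cfg, images=images, image_params=params)
        rep = subgroup_weight_report(res, grouping="smoking")
        assert set(rep["group"]) <= {"smoker", "nonsmoker"}

    def test_unknown_grouping_rejected(self, fast_results):
        with pytest.raises(ValueError, match="grouping"):
            subgroup_weight_report(fast_results, grouping="age")


class TestRunAblation:
    def test_empty_disable_set_matches_full_model(self, small_cohort):
        records, images, params = small_cohort
        cfg = TrainConfig(seed=3, **FAST)
        table = run_ablation(records, cfg, components=(), images=images,
                             image_params=params)
        res = train_mmdf(records, cfg, images=images, image_params=params)
        assert len(table) == 1
        assert table.iloc[0]["auc"] == res.evaluate("test").auc

    def test_disable_all_three_still_runs(self, small_cohort):
        records, images, params = small_cohort
        cfg = TrainConfig(seed=3, **FAST)
        table = run_ablation(
            records, cfg, components=[("contrastive", "cgan", "gating")],
            images=images, image_params=params)
        assert len(table) == 2
        assert table["configuration"].tolist()[1] == "-contrastive+cgan+gating"
        assert np.isfinite(table["auc"]).all()


class TestCrossValidation:
    def test_folds_disjoint_cover_and_stratified(self, small_cohort):
        records, images, params = small_cohort
        y = np.array([r.label == "COPD" for r in records], dtype=int)
        from sklearn.model_selection import StratifiedKFold
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=3)
        seen = []
        for _, te in skf.split(np.zeros(len(y)), y):
            seen += te.tolist()
            balance = y[te].mean() * len(te)
            target = y.mean() * len(te)
            assert abs(balance - target) <= 1.0
        assert sorted(seen) == list(range(len(y)))

    def test_threefold_reports_one_row_per_fold(self, small_cohort):
        records, images, params = small_cohort
        cfg = TrainConfig(seed=3, **FAST)
        table = cross_validate(records, cfg, k=3, images=images,
                               image_params=params)
        assert len(table) == 3
        assert np.isfinite(table["auc"]).all()


class TestNoiseSuppression:
    def test_pure_noise_environment_downweighted(self):
        """With a pure-noise environment modality, its mean learned gate
        weight drops below the uniform 1/3."""
        records, params = partial_signal_cohort(n_cases=80, n_controls=80,
                                                seed=6, env_shift=0.0,
                                                fev_shift=10.0)
        images = render_cohort_images(records, params, seed=6)
        cfg = TrainConfig(seed=1, epochs=25, gan_epochs=10)
        res = train_mmdf(records, cfg, images=images, image_params=params)
        assert res.gating_weights().mean(axis=0)[2] < 1.0 / 3.0


class TestResidualTowerPreset:
    def test_forward_backward_and_alias(self):
        from mmdfnet._nn import ConvTower
        rng = np.random.default_rng(0)
        for preset in ("resnet", "resnet50"):
            tower = ConvTower(rng, preset)
            feats = tower(rng.normal(size=(2, 16, 16)))
            assert feats.shape == (2, tower.feature_dim)
            (feats * feats).mean().backward()
            grads = [p.grad for p in tower.parameters().values()]
            assert all(g is not None for g in grads)

    def test_fine_tune_policy_filters_image_blocks(self, small_cohort):
        records, images, params = small_cohort
        cfg = TrainConfig(seed=3, fine_tune="freeze-features", **FAST)
        res = train_mmdf(records, cfg, images=images, image_params=params)
        assert np.isfinite(res.trace[-1].total)

    def test_unknown_preset_rejected(self):
        from mmdfnet._nn import ConvTower
        with pytest.raises(ValueError, match="preset"):
            ConvTower(np.random.default_rng(0), "vgg")
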
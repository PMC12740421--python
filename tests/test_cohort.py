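"""Synthetic cohort generator: counts, moments, masking, image rendering."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mmdfnet.cohort import (CohortSpec, CohortSpecError, PatientRecord,
                            SyntheticImageParams, cohort_to_dataframe,
                            generate_cohort, mask_environment,
                            read_cohort_csv, render_image,
                            render_cohort_images, write_cohort_csv,
                            read_image_png)


def _record(stage="severe", label="COPD", rid="X1", **kw):
    base = dict(id=rid, label=label, stage=stage, age=65.0, sex="male",
                smoker=True, smoking_years=30.0, fev1_fvc=55.0, pm25=40.0,
                exposure_years=15.0, gene_variant=False)
    base.update(kw)
    return PatientRecord(**base)


class TestGenerateCohort:
    def test_reference_group_sizes(self, default_cohort):
        labels = [r.label for r in default_cohort]
        assert labels.count("COPD") == 358
        assert labels.count("control") == 200

    def test_empty_cohort(self, tmp_path):
        spec = CohortSpec(n_copd=0, n_control=0)
        records = generate_cohort(spec, out_dir=tmp_path)
        assert records == []
        df = pd.read_csv(tmp_path / "cohort.csv")
        assert len(df) == 0 and "fev1_fvc" in df.columns

    def test_determinism_under_fixed_seed(self):
        a = generate_cohort(CohortSpec(seed=7))
        b = generate_cohort(CohortSpec(seed=7))
        assert a == b

    def test_seed_changes_samples(self):
        a = generate_cohort(CohortSpec(seed=7))
        b = generate_cohort(CohortSpec(seed=8))
        assert a != b

    @pytest.mark.parametrize("field, value", [
        ("n_copd", -1),
        ("env_missing_rate", 1.5),
        ("stage_mix", (0.5, 0.5, 0.5)),
    ])
    def test_invalid_spec_raises_naming_field(self, field, value):
        spec = dataclasses.replace(CohortSpec(), **{field: value})
        with pytest.raises(CohortSpecError, match=field.split("_")[0]):
            generate_cohort(spec)

    def test_invalid_group_sd(self):
        bad = dataclasses.replace(CohortSpec().copd, fev1_fvc_sd=0.0)
        with pytest.raises(CohortSpecError, match="fev1_fvc_sd"):
            generate_cohort(dataclasses.replace(CohortSpec(), copd=bad))

    def test_group_means_within_three_se(self, default_cohort):
        """Group-conditional sample moments track the spec parameters."""
        df = cohort_to_dataframe(default_cohort)
        spec = CohortSpec()
        for label, grp in (("COPD", spec.copd), ("control", spec.control)):
            sub = df[df.label == label]
            n = len(sub)
            for col, mean, sd in [
                    ("fev1_fvc", grp.fev1_fvc_mean, grp.fev1_fvc_sd),
                    ("pm25", grp.pm25_mean, grp.pm25_sd),
                    ("age", grp.age_mean, grp.age_sd)]:
                se = sd / np.sqrt(n)
                assert abs(sub[col].mean() - mean) < 3 * se, (label, col)
            for col, p in [("smoker", grp.smoking_prevalence),
                           ("gene_variant", grp.gene_variant_prevalence)]:
                se = np.sqrt(p * (1 - p) / n)
                assert abs(sub[col].mean() - p) < 3 * se, (label, col)

    def test_stage_only_for_cases(self, default_cohort):
        for r in default_cohort:
            assert (r.stage == "none") == (r.label == "control")

    def test_fev1_shift_centering_preserves_group_mean(self):
        """Large stage shifts leave the case-group mean at the spec value."""
        spec = dataclasses.replace(CohortSpec(seed=3),
                                   stage_fev1_shift=(8.0, 0.0, -12.0))
        df = cohort_to_dataframe(generate_cohort(spec))
        sub = df[df.label == "COPD"]
        se = spec.copd.fev1_fvc_sd / np.sqrt(len(sub))
        assert abs(sub.fev1_fvc.mean() - spec.copd.fev1_fvc_mean) < 3 * se

    def test_csv_roundtrip(self, tmp_path, default_cohort):
        path = tmp_path / "cohort.csv"
        write_cohort_csv(default_cohort[:20], path)
        back = read_cohort_csv(path)
        assert back == default_cohort[:20]


class TestMaskEnvironment:
    def test_rate_zero_masks_nothing(self, default_cohort):
        out = mask_environment(default_cohort, 0.0, seed=1)
        assert out == default_cohort

    def test_rate_one_masks_everything(self, default_cohort):
        out = mask_environment(default_cohort, 1.0, seed=1)
        assert all(r.env_missing and r.pm25 is None for r in out)

    def test_exact_masked_count(self, default_cohort):
        out = mask_environment(default_cohort, 0.3, seed=5)
        assert sum(r.env_missing for r in out) == round(0.3 * 558) == 167

    def test_observed_records_untouched(self, default_cohort):
        out = mask_environment(default_cohort, 0.3, seed=5)
        for orig, new in zip(default_cohort, out):
            if not new.env_missing:
                assert new == orig

    def test_rate_out_of_range(self, default_cohort):
        with pytest.raises(ValueError):
            mask_environment(default_cohort, 1.2, seed=0)


class TestRenderImage:
    def test_requested_size_and_dtype(self):
        img = render_image(_record(), SyntheticImageParams(height=48, width=40),
                           seed=0)
        assert img.shape == (48, 40) and img.dtype == np.uint16

    def test_minimum_size_boundary(self):
        img = render_image(_record(), SyntheticImageParams(height=16, width=16),
                           seed=0)
        assert img.shape == (16, 16)

    def test_below_minimum_rejected(self):
        with pytest.raises(CohortSpecError):
            render_image(_record(), SyntheticImageParams(height=8, width=16))

    def test_deterministic_given_seed(self):
        a = render_image(_record(), seed=3)
        b = render_image(_record(), seed=3)
        assert np.array_equal(a, b)

    def test_severity_monotone_lesion_mass(self):
        """Same subject id and seed: total intensity grows with severity."""
        totals = [
            int(render_image(_record(stage=s, label=lab), seed=3).sum())
            for s, lab in [("none", "control"), ("mild", "COPD"),
                           ("moderate", "COPD"), ("severe", "COPD")]]
        assert totals == sorted(totals)
        assert totals[-1] > totals[0]

    def test_non_monotone_intensity_rejected(self):
        params = SyntheticImageParams(lesion_intensity={
            "none": 0.0, "mild": 0.4, "moderate": 0.3, "severe": 0.5})
        with pytest.raises(CohortSpecError, match="monotone"):
            render_image(_record(), params)

    def test_png_roundtrip(self, tmp_path):
        recs = [_record(rid=f"R{i}") for i in range(3)]
        imgs = render_cohort_images(recs, SyntheticImageParams(height=16, width=16),
                                    seed=1, out_dir=tmp_path)
        for rec, img in zip(recs, imgs):
            assert rec.image_path is not None
            assert np.array_equal(read_image_png(rec.image_path), img)
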
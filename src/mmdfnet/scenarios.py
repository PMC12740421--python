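"""Purpose-built synthetic cohorts for fusion and gating experiments.

Each builder constructs a cohort whose per-modality informativeness is known
by design, so qualitative behaviours of the fusion model (which modality the
gate upweights for which subgroup, whether fusing helps over single
modalities) can be checked against ground truth:

* ``gating_recovery_cohort`` — for smokers only the image modality separates
  cases from controls (stage-driven lesions, neutral PM2.5); for nonsmokers
  only the environmental modality does (elevated PM2.5 in cases, lesion
  rendering switched off via ``lesion_scale``).  A well-trained gate should
  give smokers a higher mean CT weight and nonsmokers a higher mean
  environment weight.
* ``stage_informativeness_cohort`` — lesion load is flat across stages while
  FEV1/FVC is near-control for mild cases and strongly depressed for severe
  cases, so lung function dominates discrimination only for severe disease.
* ``partial_signal_cohort`` — each modality carries an independent, partial
  signal (moderately shifted FEV1/FVC, low-amplitude lesions under heavy
  image noise, moderately shifted PM2.5), so the fused model can exceed
  every single modality but none saturates on its own.
"""

from __future__ import annotations

import numpy as np

from .cohort import PatientRecord, SyntheticImageParams, STAGES

__all__ = ["gating_recovery_cohort", "stage_informativeness_cohort",
           "partial_signal_cohort", "ablation_cohort"]


def _base_record(i: int, label: str, stage: str, rng: np.random.Generator,
                 smoker: bool, fev1: float, pm25: float,
                 lesion_scale: float = 1.0) -> PatientRecord:
    rec = PatientRecord(
        id=f"S{i:04d}", label=label, stage=stage,
        age=float(rng.normal(62, 8)),
        sex="male" if rng.random() < 0.5 else "female",
        smoker=smoker,
        smoking_years=float(max(rng.normal(30, 8), 0.0)) if smoker else 0.0,
        fev1_fvc=float(np.clip(fev1, 1.0, 100.0)),
        pm25=float(max(pm25, 0.0)),
        exposure_years=float(max(rng.normal(12, 4), 0.0)),
        gene_variant=bool(rng.random() < 0.10),
        lesion_scale=lesion_scale)
    rec.validate()
    return rec


def _case_stage(rng: np.random.Generator) -> str:
    return str(rng.choice(STAGES, p=[0.4, 0.4, 0.2]))


def gating_recovery_cohort(n_per_cell: int = 60, seed: int = 0
                           ) -> tuple[list[PatientRecord], SyntheticImageParams]:
    """Smoker x label balanced cohort with modality-specific signal.

    FEV1/FVC is uninformative (same distribution in all cells).  Smokers'
    labels are encoded only in the image (lesions for cases); nonsmokers'
    labels only in PM2.5 (cases ~55, controls ~30 ug/m3; their lesions are
    disabled with ``lesion_scale`` 0).
    """
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    i = 0
    for smoker in (True, False):
        for label in ("COPD", "control"):
            for _ in range(n_per_cell):
                stage = _case_stage(rng) if label == "COPD" else "none"
                if smoker:
                    pm25 = rng.normal(35, 6)
                    lesion_scale = 1.0
                else:
                    pm25 = rng.normal(55 if label == "COPD" else 30, 6)
                    lesion_scale = 0.0
                records.append(_base_record(
                    i, label, stage, rng, smoker,
                    fev1=rng.normal(70, 5), pm25=pm25,
                    lesion_scale=lesion_scale))
                i += 1
    params = SyntheticImageParams(
        height=32, width=32,
        lesion_intensity={"none": 0.0, "mild": 0.35, "moderate": 0.40,
                          "severe": 0.45})
    return records, params


def stage_informativeness_cohort(n_cases_per_stage: int = 50,
                                 n_controls: int = 100, seed: int = 0
                                 ) -> tuple[list[PatientRecord],
                                            SyntheticImageParams]:
    """Cohort where lung function dominates only for severe disease.

    FEV1/FVC means: controls 76, mild 74 (overlapping controls), moderate 65,
    severe 50.  Mild and moderate cases carry clear lesions while severe
    cases' lesions are suppressed (``lesion_scale`` 0, mimicking the regime
    where imaging saturates and the compensatory decline in lung function
    becomes the decisive signal), so discriminating severe disease requires
    the lung-function modality.  Severity tracks age and pack-years (all
    subjects are smokers), giving the attribute-driven gate an observable
    handle on the subgroups.
    """
    rng = np.random.default_rng(seed)
    fev_mean = {"mild": 74.0, "moderate": 65.0, "severe": 50.0}
    lesion = {"mild": 1.0, "moderate": 1.0, "severe": 0.0}
    # severity tracks observable history (age, pack-years), so the gate —
    # which reads attributes, not spirometry — can tell the subgroups apart
    age_mean = {"mild": 56.0, "moderate": 63.0, "severe": 72.0}
    pack_mean = {"mild": 15.0, "moderate": 25.0, "severe": 40.0}
    records: list[PatientRecord] = []
    i = 0
    for stage in STAGES:
        for _ in range(n_cases_per_stage):
            rec = _base_record(
                i, "COPD", stage, rng, smoker=True,
                fev1=rng.normal(fev_mean[stage], 4), pm25=rng.normal(32, 6),
                lesion_scale=lesion[stage])
            rec.age = float(rng.normal(age_mean[stage], 5))
            rec.smoking_years = float(max(rng.normal(pack_mean[stage], 6), 0))
            records.append(rec)
            i += 1
    for _ in range(n_controls):
        rec = _base_record(
            i, "control", "none", rng, smoker=True,
            fev1=rng.normal(76, 4), pm25=rng.normal(32, 6))
        rec.age = float(rng.normal(63, 8))
        rec.smoking_years = float(max(rng.normal(25, 10), 0))
        records.append(rec)
        i += 1
    params = SyntheticImageParams(
        height=32, width=32,
        lesion_count={"none": 0, "mild": 4, "moderate": 4, "severe": 4},
        lesion_intensity={"none": 0.0, "mild": 0.35, "moderate": 0.35,
                          "severe": 0.35})
    return records, params


def partial_signal_cohort(n_cases: int = 150, n_controls: int = 150,
                          seed: int = 0, env_shift: float = 8.0,
                          fev_shift: float = 6.0
                          ) -> tuple[list[PatientRecord],
                                     SyntheticImageParams]:
    """Independent partial signal in each modality; none saturates alone.

    Cases: FEV1/FVC ~ N(76 - fev_shift, 5); PM2.5 ~ N(32 + env_shift, 8);
    low-amplitude lesions under strong image noise.  Controls: FEV1/FVC ~
    N(76, 5); PM2.5 ~ N(32, 8); no lesions.
    """
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    i = 0
    for _ in range(n_cases):
        records.append(_base_record(
            i, "COPD", _case_stage(rng), rng,
            smoker=bool(rng.random() < 0.5),
            fev1=rng.normal(76 - fev_shift, 5),
            pm25=rng.normal(32 + env_shift, 8)))
        i += 1
    for _ in range(n_controls):
        records.append(_base_record(
            i, "control", "none", rng, smoker=bool(rng.random() < 0.5),
            fev1=rng.normal(76, 5), pm25=rng.normal(32, 8)))
        i += 1
    params = SyntheticImageParams(
        height=32, width=32, noise_sd=0.12,
        lesion_intensity={"none": 0.0, "mild": 0.08, "moderate": 0.10,
                          "severe": 0.13})
    return records, params


def ablation_cohort(n_per_cell: int = 75, seed: int = 0
                    ) -> tuple[list[PatientRecord], SyntheticImageParams]:
    """Cohort on which every architectural component has work to do.

    Cross-modal, subgroup-dependent signal:

    * Smokers carry a latent disease severity s ~ N(0, 1); the label is
      COPD iff s > 0.  Their images show a graded lesion load for cases
      *and* controls (``lesion_scale`` = 0.5 + 0.3 s, flat per-stage lesion
      tables), so the image reads severity continuously, while the recorded
      FEV1/FVC = 72 - 5 s + N(0, 4) is a noisy measurement of the same
      severity.  Matching images to the multi-bit clinical profile
      (contrastive alignment) is therefore more informative per sample than
      the binary label alone.  Smokers' PM2.5 carries no label signal.
    * Nonsmokers model pollution-driven disease: PM2.5 = 10 + 0.7·age +
      N(0, 3) and the label is COPD iff PM2.5 exceeds a fixed threshold
      (53.4 ug/m3, the population mean), so the exposure itself is the
      decisive modality and — being mostly age-driven — is largely
      *reconstructable from age* when masked.  Their images have
      no lesions and FEV1/FVC is uninformative.  Because age reaches the
      classifier only through the gate, conditional imputation of a masked
      PM2.5 is the only route to recover the signal — a constant fill
      cannot, which is what the generation-module ablation measures.

    The subgroup structure penalizes a uniform gate relative to a learned
    one; apply ``mask_environment`` for the missingness experiments.
    """
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    i = 0
    for smoker in (True, False):
        for label in ("COPD", "control"):
            for _ in range(n_per_cell):
                age = float(rng.normal(62, 8))
                if smoker:
                    pm25 = -15.0 + 0.8 * age + 10.0 + rng.normal(0, 3)
                    s = abs(rng.normal(0.0, 1.0))
                    if label == "control":
                        s = -s
                    stage = ("mild" if s < 0.7 else
                             "moderate" if s < 1.4 else "severe")                         if label == "COPD" else "none"
                    fev1 = 72.0 - 5.0 * s + rng.normal(0, 4)
                    lesion_scale = float(max(0.5 + 0.3 * s, 0.0))
                else:
                    # rejection-sample (age, PM2.5) from the joint model
                    # until the fixed-threshold label matches the cell
                    want_case = label == "COPD"
                    while True:
                        age = float(rng.normal(62, 8))
                        pm25 = 10.0 + 0.7 * age + rng.normal(0, 3)
                        if (pm25 > 53.4) == want_case:
                            break
                    stage = _case_stage(rng) if label == "COPD" else "none"
                    fev1 = rng.normal(72, 5)
                    lesion_scale = 0.0
                rec = _base_record(i, label, stage, rng, smoker,
                                   fev1=fev1, pm25=max(pm25, 0.0),
                                   lesion_scale=lesion_scale)
                rec.age = age
                records.append(rec)
                i += 1
    params = SyntheticImageParams(
        height=32, width=32, noise_sd=0.06, fev1_texture_gain=0.3,
        lesion_count={"none": 4, "mild": 4, "moderate": 4, "severe": 4},
        lesion_intensity={"none": 0.35, "mild": 0.35, "moderate": 0.35,
                          "severe": 0.35})
    return records, params
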
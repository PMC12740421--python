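# mmdfnet

Multimodal dynamic fusion for COPD risk prediction.

Chronic obstructive pulmonary disease hides behind three partial windows:
chest imaging shows structural damage, spirometry (FEV1/FVC) shows airflow
limitation, and environmental exposure history (PM2.5) carries long-term
risk — but no single window suffices, the informative window differs between
patients (smokers vs nonsmokers, mild vs severe disease), and exposure data
are often missing.  `mmdfnet` is a desk-scale reference implementation of a
multimodal dynamic fusion network that addresses all three problems at once:

* a **dual-tower contrastive module** aligns a CNN image encoder and an MLP
  clinical encoder in a shared L2-normalized embedding space with the
  symmetric temperature-scaled InfoNCE loss
  `L = ½(loss_I + loss_T)`, positives on the diagonal of the batch
  cosine-similarity matrix (temperature T = 0.05);
* a **conditional WGAN-GP** (gradient-penalty coefficient φ_gp = 10)
  generates environmental exposures conditioned on the clinical profile and
  imputes them where missing;
* a **dynamic gating network** (hidden width h = 128) maps patient
  attributes to softmax weights (w_CT, w_LungFunction, w_Environment) and
  fuses the modality embeddings as a convex combination, trained jointly
  under `L_total = L_cls + 0.5·L_contrast + 0.2·L_WGAN`.

Because the cohort the method was developed on is not redistributable, the
package ships a **synthetic cohort generator** that reproduces the published
case/control table structure (358 COPD patients / 200 controls; group-wise
FEV1/FVC, smoking, PM2.5 and SERPINA1 distributions) and renders procedural
lung-like images with stage-dependent lesion load, so the complete pipeline
trains and is validated on one CPU.  All networks run on a small
numpy-based reverse-mode autodiff core included in the package.

## Worked example

```python
from mmdfnet import CohortSpec, TrainConfig, generate_cohort, train_mmdf
from mmdfnet import subgroup_weight_report
from mmdfnet.cohort import SyntheticImageParams, render_cohort_images

records = generate_cohort(CohortSpec(n_copd=120, n_control=80, seed=7,
                                     env_missing_rate=0.2))
params = SyntheticImageParams(height=32, width=32)
images = render_cohort_images(records, params, seed=7)

results = train_mmdf(records, TrainConfig(seed=1, epochs=20, gan_epochs=60),
                     images=images, image_params=params)
print(results.summary())
print(subgroup_weight_report(results, grouping="smoking").round(3))
```

prints (numbers from this exact run):

```
Multimodal dynamic fusion model
==============================================
records: 200   (train/val/test: 120/40/40)
epochs: 20   batch: 32   T: 0.05   d: 64   h: 128
lambda1: 0.5   lambda2: 0.2   phi_gp: 10.0
disabled: none   modality: all
final losses: cls=0.3051 con=2.6669 adv=-0.0351 total=1.6315
val: AUC=0.964 sens=95.8% spec=100.0% F1=0.979
test: AUC=0.984 sens=91.7% spec=100.0% F1=0.957
mean weights: CT=0.134 LF=0.856 Env=0.011
    group   n  CT_mean  CT_sd  lung_function_mean  lung_function_sd  environment_mean  environment_sd
nonsmoker  90    0.010  0.004               0.986             0.006             0.004           0.002
   smoker 110    0.235  0.166               0.749             0.169             0.016           0.008
```

Read it as: the joint objective decomposes exactly into
`L_cls + 0.5·L_contrast + 0.2·L_WGAN`; held-out discrimination is near
perfect on this strongly separable cohort (test AUC 0.984, sensitivity
91.7% / specificity 100% at the validation-Youden threshold); and the
learned gate leans on lung function — the dominant signal in the reference
cohort, whose case and control FEV1/FVC distributions are far apart —
while smokers (whose images carry stage-driven lesions) receive a markedly
higher mean CT weight (0.235) than nonsmokers (0.010), with per-patient
weights always on the 3-simplex.

The `MMDFResults` object also exposes `evaluate()`, `predict()`,
`weights_frame()`, `loss_trace_frame()`, `plot_training()` and
`save()`; `run_ablation` and `cross_validate` sit alongside `train_mmdf`.

## Command line

```bash
mmdf generate --out cohort/ --seed 7           # cohort.csv (+ --images PNGs)
mmdf train --cohort cohort/ --out run/         # checkpoint, loss trace, weights
mmdf ablate --cohort cohort/ --disable contrastive,cgan,gating
mmdf report-weights --cohort cohort/ --group smoking
```

Every run writes a JSON manifest (resolved config, seed, versions) next to
its outputs.

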
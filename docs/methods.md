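# Methods

## The model

`mmdfnet` implements a multimodal dynamic fusion network for COPD risk
prediction from three modalities: a chest image, lung-function spirometry
(FEV1/FVC), and environmental exposure (PM2.5 level and exposure years).
Three mechanisms are combined:

**Dual-tower contrastive alignment.** A convolutional image tower and an
MLP clinical tower are projected into a shared d-dimensional space and
L2-normalized.  For a batch of N matched (image, clinical) pairs the NxN
cosine-similarity matrix S is trained with the symmetric temperature-scaled
InfoNCE objective

    loss_I = (1/N) Σ_i −log( exp(S_ii/T) / Σ_j exp(S_ij/T) )
    loss_T = (1/N) Σ_j −log( exp(S_jj/T) / Σ_i exp(S_ij/T) )
    L_contrast = (loss_I + loss_T) / 2

with matched pairs on the diagonal as positives and all other batch entries
as negatives.  The published form of this loss prints the positive-pair term
in both numerator and denominator, which is constant in the parameters; the
implementation uses the standard symmetric InfoNCE that the surrounding
description (maximize positive-pair similarity, minimize negative-pair
similarity) requires.

**Conditional WGAN-GP for environmental data.** A generator MLP maps
(clinical condition vector, Gaussian noise) to the two environmental
variables jointly, in standardized space; a critic MLP scores (condition,
environment) pairs.  The critic minimizes

    E[D(c, G(c,z))] − E[D(c, x)] + φ_gp · E[(‖∇_x̂ D(c, x̂)‖₂ − 1)²]

with x̂ = εx + (1−ε)G(c,z), ε ~ U(0,1), and the generator minimizes
−E[D(c, G(c,z))].  The expectation of the real-data term is taken over the
observed records (the printed objective writes both expectations over the
noise distribution; the definition of x as real data requires the real-data
expectation).  Both generator and critic receive the condition vector: the
model is conditional, so the critic must judge pairs, not marginals.
Masked records are imputed with the mean of 20 conditional draws; with
`n_draws > 1` all draws are retained in a sidecar table (multiple
imputation).  Imputed values are clamped to [0, ∞) after de-standardization.

**Attribute-driven gated fusion.** A two-layer gate MLP
(u = W2·ReLU(W1·x + b1) + b2, hidden width h) maps the encoded clinical
vector to three logits, softmax-normalized into weights
(w_CT, w_LungFunction, w_Environment).  The fused representation is the
convex combination w_CT·f_CT + w_LF·f_LF + w_Env·f_Env of the three aligned
modality features, followed by a linear sigmoid head.  The joint objective is

    L_total = L_cls + λ1·L_contrast + λ2·L_WGAN

where L_cls is the classification cross-entropy and L_WGAN the generator's
adversarial loss (its critic is updated on the side and does not enter the
fused gradient).

## Default hyperparameters

| parameter | default | meaning |
|---|---|---|
| T | 0.05 | contrastive temperature |
| λ1, λ2 | 0.5, 0.2 | loss weights for contrastive / adversarial terms |
| h | 128 | gate hidden width |
| φ_gp | 10 | gradient-penalty coefficient |
| n_critic | 5 | critic updates per generator update (pretraining) |
| d | 64 | shared embedding dimension |
| batch | 32 | batch size (32–64 supported) |
| lr | 1e-3 | Adam step size (β = 0.9/0.999 for the main model, 0.0/0.9 for the GAN) |

T, λ1, λ2, h, φ_gp and the batch range follow the tuned values of the
underlying study; d, the MLP widths and the activation family (ReLU) are
package choices, since no published values exist for them.

## Architectural choices

* **Numerical core.** All networks run on a small reverse-mode autodiff
  layer over numpy (`_autograd.py` / `_nn.py`), sized for desk-scale
  cohorts on a single CPU.  The WGAN-GP penalty needs the gradient of the
  critic's *input* gradient with respect to its weights; this is built as an
  explicit mask-chain expression (ReLU derivative masks evaluated at the
  interpolate and treated as constants — exact almost everywhere, since ReLU
  is piecewise linear), so first-order reverse mode suffices.  Gradients are
  verified against finite differences in the test suite.
* **Image towers.** The default `tiny` preset is a three-block CNN
  (channels 8/16/32, 3x3 kernels, 2x2 mean pooling, global average pooling)
  that trains in seconds on 32x32 rasters.  The `resnet` preset (alias
  `resnet50` in configs) is a residual tower — four stages of identity-skip
  double-conv blocks, channels 16/32/64/128 — for larger experiments; the
  `fine_tune` policy (`freeze-features` / `tune-last-blocks`) applies to it.
* **Separate projection heads.** The classifier's image feature f_CT uses
  its own projection of the tower features; the contrastive head has a
  separate projection pair.  Sharing one projection lets the
  instance-discrimination objective distort the classification geometry;
  keeping projector outputs off the downstream path is the standard practice
  in contrastive representation learning and materially stabilizes joint
  training at small n.
* **Gate initialization.** The gate's output layer starts at zero, so
  gating begins uniform (1/3, 1/3, 1/3) and departs from uniformity only as
  evidence accumulates.  This avoids early winner-take-all collapse against
  the slow-starting image tower.
* **Modality encoders.** Lung function (FEV1/FVC z-score) and environment
  (PM2.5, exposure-years z-scores) pass through separate one-hidden-layer
  encoders into the shared dimension, L2-normalized.  How these two feature
  vectors are produced is the least constrained part of the published
  design; the choice here isolates it behind `MMDFModel._forward`.
* **Gate input** is the encoded patient-attribute vector — age, sex,
  smoking status and years, gene flag — and deliberately excludes the
  FEV1/FVC measurement.  The spirometric value is the lung-function
  modality's content; feeding it to the gate lets the gate classify by
  routing (sending patients it has already recognized as severe to whichever
  feature yields a positive logit), a degenerate optimum that destroys the
  interpretability of the modality weights.  With attributes only, the gate
  must genuinely select among modalities.  The gene variant feeds the gate
  only, not a modality.
* **Alignment pretraining.** Before the joint phase, the towers are trained
  for `align_epochs` (default 20) on the contrastive objective alone.  The
  full-scale design this package mirrors starts its image tower from
  pretrained weights; at desk scale, training randomly initialized towers
  directly under the joint objective lets the alignment term push the
  backbone toward a still-random clinical embedding, which measurably
  degrades the classifier.  Pretraining alignment first recovers the
  intended role of the contrastive module: a backbone that already encodes
  clinically matched image structure when classification starts.  Disabling
  the contrastive component removes this phase and sets λ1 = 0.

## Preprocessing

* **Histogram equalization** uses the midpoint cumulative convention
  q = round((qk − q0)·(cum(p) − H(p)/2)/(M·N)) + q0.  This discretization is
  monotone non-decreasing, maps an exactly uniform histogram through the
  identity ramp, and is exactly idempotent (re-equalizing an equalized
  image is a no-op), which the property suite exercises.  Images are
  equalized over their full 16-bit range, then standardized by scalar
  training-split mean and sd (the published description of standardization
  is ambiguous between scalar and per-pixel moments; "all images in the
  training set" reads most naturally as scalar).
* **Tabular encoding**: Z-score for continuous variables with training-split
  moments; one-hot for categoricals with lexicographically sorted level
  lists frozen in a JSON schema artifact; unseen levels raise.

## The synthetic cohort generator

The generator emulates the case/control structure of the study cohort
(358 COPD / 200 controls): group-conditional truncated Gaussians for age,
FEV1/FVC (truncated to (0, 100]), PM2.5 and exposure years (truncated to
[0, ∞)), smoking years for smokers, and Bernoulli draws for sex, smoking
and the SERPINA1 flag, using the published group means, sds and prevalences
as defaults.  Disease stage for cases follows a configurable
mild/moderate/severe mix, default (0.4, 0.4, 0.2) — no published stage
counts exist.  Two couplings inject cross-variable structure while
preserving the group-level moments exactly: FEV1/FVC shifts by stage
(+5/0/−10, re-centered against the stage mix) and PM2.5 shifts with smoking
status (+5 µg/m³, centered against the smoking prevalence).  Exposure years
are modeled as an independent truncated Gaussian; the source table reports
exposure years without defining the exposure threshold, so no mechanistic
link between PM2.5 level and exposure years is assumed.

Images are procedural lung-like rasters (16-bit grayscale PNG): two darker
elliptical lung fields on a brighter thorax, smoothed multiplicative
texture, additive Gaussian noise, and stage-dependent bright lesion blobs
(count and amplitude monotone in severity).  An optional
`fev1_texture_gain` adds emphysema-like speckle whose amplitude grows with
the FEV1/FVC deficit, giving images a continuous severity signal; a
per-record `lesion_scale` lets experiment cohorts decouple image
informativeness from stage.  The renderer makes no claim of anatomical
realism: passing tests show the pipeline's mechanics (alignment, gating,
imputation) behave as designed under known signal structure, not that the
model reads real CT.

Missingness is completely at random by default (`mask_environment` masks an
exact round(rate·n) subset); covariate-dependent missingness is out of the
default path.

## Experiment cohorts and what the checks mean

`scenarios.py` holds four purpose-built cohorts with known per-modality
signal: `gating_recovery_cohort` (image informative only for smokers,
environment only for nonsmokers), `stage_informativeness_cohort` (lung
function decisive only for severe disease, imaging for mild/moderate),
`partial_signal_cohort` (independent moderate signal in each modality), and
`ablation_cohort` (subgroup-dependent signal plus strongly
clinically-structured PM2.5, so conditional imputation can reconstruct
masked values where a constant fill cannot).  The acceptance suite asserts
directional reproductions on these cohorts — learned gate weights track the
planted subgroup structure, the full model is not beaten by its ablations
or by single-modality variants — always as orderings at a fixed seed, never
as numeric targets.

Problem sizes are chosen for single-CPU runs: 32x32 rasters, cohorts of
150–600 subjects, 60 joint epochs, 150 GAN epochs.  At these sizes one
full fit takes on the order of 10–30 s.

## Numerical notes and edge cases

* Determinism: every stochastic step (splits, init, batch order, GAN noise,
  interpolation ε, imputation draws) derives from `TrainConfig.seed`;
  identical seeds give bit-identical checkpoints.
* Component-wise random-number streams (common random numbers): splits,
  initialization, batch order, alignment pretraining and the GAN's joint-
  phase noise each draw from their own seeded stream, so disabling one
  component in an ablation leaves every other component's draws — and hence
  the paired run's trajectory — unchanged.  Ablation comparisons at a fixed
  seed are therefore paired comparisons, not comparisons of two unrelated
  stochastic runs.
* L2 normalization raises on zero-norm rows rather than dividing by ε;
  modality encoders carry a small constant final bias so degenerate
  (all-zero) inputs cannot produce a zero embedding at initialization.
* The decision threshold is Youden-optimal on the validation split and
  frozen at fit time.
* Single-hidden-layer GAN networks are prone to collapse on bimodal
  conditionals; defaults use two hidden layers of 64.
* The classification AUC is the tie-halved rank statistic
  (scikit-learn); a brute-force pair-counting oracle cross-checks it in the
  tests.

## Known limitations

* The renderer's lesions are Gaussian blobs; real CT texture, slice
  geometry and scanner effects are out of scope, as is DICOM/NIfTI
  ingestion.
* The WGAN-GP is a mediocre conditional-mean estimator when the
  environmental signal is only weakly determined by the conditioning
  clinical variables; mean-fill is then competitive.  The ablation cohort
  documents the regime (strong clinical determination) where conditional
  imputation earns its keep.
* Genetics is a single binary susceptibility flag; there is no natural-
  language branch (structured clinical variables replace free text).
* Cross-validation is supported (stratified threefold) but headline
  metrics default to a single stratified train/validation/test split.
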
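"""Joint training and evaluation of the multimodal dynamic fusion network.

The entry points follow the statsmodels convention: build an ``MMDFModel``
from a cohort (records plus rendered images), call ``fit()`` and work with
the returned ``MMDFResults`` (metrics, per-patient gating weights, subgroup
reports, ``summary()``, plotting, prediction on new records).

Training jointly optimizes

    L_total = L_cls + lambda1 * L_contrast + lambda2 * L_WGAN

where L_cls is the cross-entropy of the gated-fusion classifier, L_contrast
the symmetric InfoNCE alignment loss between the image and clinical towers,
and L_WGAN the conditional generator's adversarial loss (its critic is
updated on the side).  Missing environmental data are imputed with the
pretrained conditional WGAN-GP before the joint phase.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._autograd import Tensor
from ._nn import MLP, Adam, flatten_params
from .cohort import (PatientRecord, SyntheticImageParams, cohort_to_dataframe,
                     render_cohort_images)
from .dual_tower import DualTower, contrastive_loss, project_normalize, \
    similarity_matrix
from .env_cgan import EnvCGAN, GanParams, critic_loss, generator_loss, \
    train_cgan
from .fusion import (GatingNetwork, LossBreakdown, binary_cross_entropy,
                     classify, fuse_features, total_loss)
from .metrics import EvaluationReport, evaluate_metrics, youden_threshold
from .preprocessing import TabularSchema, histogram_equalize

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "MMDFModel", "MMDFResults", "train_mmdf",
           "run_ablation", "subgroup_weight_report", "cross_validate"]

ABLATABLE = ("contrastive", "cgan", "gating")


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the joint training run.

    Defaults follow the tuned values of the underlying study: temperature
    T = 0.05, gate width h = 128, lambda1 = 0.5, lambda2 = 0.2, gradient
    penalty coefficient 10, batch size in [32, 64].
    """

    batch_size: int = 32
    epochs: int = 25
    lr: float = 1e-3
    seed: int = 0
    temperature: float = 0.05
    lambda_contrast: float = 0.5
    lambda_wgan: float = 0.2
    gate_hidden: int = 128
    phi_gp: float = 10.0
    embed_dim: int = 64
    image_tower: str = "tiny"
    fine_tune: str = "all"            # all | freeze-features | tune-last-blocks
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    gan_epochs: int = 80
    #: contrastive alignment pretraining epochs before the joint phase
    #: (stands in for the published pipeline's pretrained image tower)
    align_epochs: int = 20
    #: pretraining step size; default follows lr
    align_lr: float | None = None
    n_critic: int = 5
    disable: tuple[str, ...] = ()     # subset of {contrastive, cgan, gating}
    modality: str | None = None       # force a single modality (CT, lung_function, environment)

    def validate(self, n_records: int | None = None) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if n_records is not None and self.batch_size > max(n_records, 1):
            raise ValueError("batch_size exceeds dataset size")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        for name in ("epochs", "lr", "temperature", "gate_hidden", "phi_gp",
                     "embed_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.disable) - set(ABLATABLE)
        if unknown:
            raise ValueError(f"unknown ablation component(s): {sorted(unknown)}")
        if self.modality is not None and self.modality not in (
                "CT", "lung_function", "environment"):
            raise ValueError(f"unknown modality: {self.modality!r}")
        if self.fine_tune not in ("all", "freeze-features", "tune-last-blocks"):
            raise ValueError(f"unknown fine_tune policy: {self.fine_tune!r}")


def _stratified_split(labels: np.ndarray, fractions, rng: np.random.Generator):
    """Index arrays (train, val, test), stratified by class."""
    idx_sets: list[list[int]] = [[], [], []]
    for cls in np.unique(labels):
        cls_idx = np.flatnonzero(labels == cls)
        cls_idx = rng.permutation(cls_idx)
        n = len(cls_idx)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        idx_sets[0] += cls_idx[:n_train].tolist()
        idx_sets[1] += cls_idx[n_train:n_train + n_val].tolist()
        idx_sets[2] += cls_idx[n_train + n_val:].tolist()
    return tuple(np.sort(np.array(s, dtype=int)) for s in idx_sets)


def _stratified_batches(labels: np.ndarray, batch_size: int,
                        rng: np.random.Generator) -> list[np.ndarray]:
    """Batches whose class composition tracks the overall prevalence."""
    pos = rng.permutation(np.flatnonzero(labels == 1))
    neg = rng.permutation(np.flatnonzero(labels == 0))
    n = len(labels)
    n_batches = max(1, int(np.ceil(n / batch_size)))
    batches = []
    p_splits = np.array_split(pos, n_batches)
    n_splits = np.array_split(neg, n_batches)
    for p, m in zip(p_splits, n_splits):
        b = np.concatenate([p, m])
        if len(b):
            batches.append(rng.permutation(b))
    return batches


class MMDFModel:
    """Multimodal fusion model bound to one cohort.

    Parameters
    ----------
    records : list of PatientRecord
    config : TrainConfig
    images : optional (n, H, W) array of 16-bit rasters; rendered from the
        records with ``image_params`` when omitted.
    image_params : rendering parameters used when ``images`` is None.
    """

    def __init__(self, records: list[PatientRecord], config: TrainConfig,
                 images: np.ndarray | None = None,
                 image_params: SyntheticImageParams | None = None):
        if len(records) == 0:
            raise ValueError("cohort is empty")
        config.validate(len(records))
        self.records = records
        self.config = config
        self.image_params = image_params or SyntheticImageParams(
            height=32, width=32)
        if images is None:
            images = render_cohort_images(records, self.image_params,
                                          seed=config.seed)
        if len(images) != len(records):
            raise ValueError("images and records must align")
        self.images = images

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: TrainConfig,
                       **kwargs) -> "MMDFModel":
        records = []
        for row in df.itertuples(index=False):
            records.append(PatientRecord(
                id=str(row.id), label=str(row.label), stage=str(row.stage),
                age=float(row.age), sex=str(row.sex), smoker=bool(row.smoker),
                smoking_years=float(row.smoking_years),
                fev1_fvc=float(row.fev1_fvc),
                pm25=None if pd.isna(row.pm25) else float(row.pm25),
                exposure_years=(None if pd.isna(row.exposure_years)
                                else float(row.exposure_years)),
                gene_variant=bool(row.gene_variant),
                env_missing=bool(getattr(row, "env_missing", False)),
                lesion_scale=float(getattr(row, "lesion_scale", 1.0))))
        return cls(records, config, **kwargs)

    # -- fitting ----------------------------------------------------------
    def fit(self) -> "MMDFResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        df = cohort_to_dataframe(self.records)
        y = (df["label"] == "COPD").to_numpy().astype(int)
        if y.min() == y.max():
            raise ValueError("cohort must contain both cases and controls")
        tr, va, te = _stratified_split(y, cfg.split_fractions, rng)
        if len(tr) == 0 or len(va) == 0:
            raise ValueError("empty training or validation split")

        # -- preprocessing fitted on the training split only --------------
        imgs_eq = np.stack([histogram_equalize(im, levels=65536)
                            for im in self.images]).astype(np.float64) / 65535.0
        img_mu = float(imgs_eq[tr].mean())
        img_sd = float(imgs_eq[tr].std()) or 1.0
        imgs_std = (imgs_eq - img_mu) / img_sd

        schema = TabularSchema.fit(df.iloc[tr])
        clin = schema.transform(df)

        env_raw = df[["pm25", "exposure_years"]].to_numpy(dtype=float)
        observed = ~df["env_missing"].to_numpy().astype(bool)
        tr_obs = tr[observed[tr]]
        if not tr_obs.size:
            raise ValueError("no observed environmental data in training split")

        cgan = None
        if "cgan" not in cfg.disable:
            gan_params = GanParams(cond_dim=clin.shape[1], env_dim=2,
                                   phi_gp=cfg.phi_gp, n_critic=cfg.n_critic)
            cgan = train_cgan(clin[tr_obs], env_raw[tr_obs], gan_params,
                              epochs=cfg.gan_epochs,
                              batch_size=min(64, len(tr_obs)),
                              seed=cfg.seed + 10)
            env_filled = env_raw.copy()
            if (~observed).any():
                draws = cgan.sample(clin[~observed],
                                    np.random.default_rng(cfg.seed + 11),
                                    n_draws=20)
                env_filled[~observed] = draws.mean(axis=0)
        else:
            env_filled = env_raw.copy()
            env_filled[~observed] = env_raw[tr_obs].mean(axis=0)

        env_mu = env_filled[tr].mean(axis=0)
        env_sd = env_filled[tr].std(axis=0)
        env_sd[env_sd <= 0] = 1.0
        env_z = (env_filled - env_mu) / env_sd

        fev_idx = list(schema.continuous).index("fev1_fvc")
        lf_z = clin[:, [fev_idx]]
        # the gate reads patient attributes (age, sex, smoking history, gene
        # flag) but not the spirometric measurement itself, which is the
        # lung-function modality's content: feeding it to the gate lets the
        # gate classify by routing instead of weighing modalities
        gate_cols = np.array([i for i, name
                              in enumerate(schema.feature_names)
                              if not name.startswith("fev1_fvc")])

        # -- networks ------------------------------------------------------
        init_rng = np.random.default_rng(cfg.seed + 1)
        dual = DualTower(init_rng, tab_dim=clin.shape[1],
                         embed_dim=cfg.embed_dim, image_tower=cfg.image_tower)
        lf_enc = MLP(init_rng, 1, [32], cfg.embed_dim, final_bias=0.01)
        env_enc = MLP(init_rng, 2, [32], cfg.embed_dim, final_bias=0.01)
        gate = GatingNetwork(init_rng, len(gate_cols), hidden=cfg.gate_hidden)
        head = MLP(init_rng, cfg.embed_dim, [], 1)
        feat = dual.image_tower.feature_dim
        # classification uses its own image projection; the alignment head
        # shares only the tower backbone (projector outputs are kept off the
        # downstream path, as is standard for contrastive pretraining)
        w_fuse = Tensor(init_rng.normal(0, 1.0 / np.sqrt(feat),
                                        (feat, cfg.embed_dim)),
                        requires_grad=True)

        params: dict[str, Tensor] = {}
        params.update(self._tower_params(dual, cfg))
        params.update(lf_enc.parameters("lf"))
        params.update(env_enc.parameters("env"))
        if "gating" not in cfg.disable and cfg.modality is None:
            params.update(gate.parameters("gate"))
        params.update(head.parameters("head"))
        params["w_fuse"] = w_fuse
        if cgan is not None:
            params.update(cgan.generator.parameters("gen"))
        opt = Adam(params, lr=cfg.lr)
        opt_critic = (Adam(cgan.critic.parameters("crit"), lr=cfg.lr,
                           betas=(0.0, 0.9)) if cgan is not None else None)

        forced = self._forced_weights(cfg)
        trace: list[LossBreakdown] = []
        # separate streams per component: disabling one component must not
        # perturb the draws of the others (common random numbers)
        train_rng = np.random.default_rng(cfg.seed + 2)
        gan_rng = np.random.default_rng(cfg.seed + 4)

        # contrastive pretraining: align the towers before joint training,
        # standing in for the pretrained image backbone of the full-scale
        # pipeline.  Skipped when the contrastive module is ablated.
        if "contrastive" not in cfg.disable and cfg.align_epochs > 0:
            align_params = dual.parameters()
            opt_align = Adam(align_params, lr=cfg.align_lr or cfg.lr)
            align_rng = np.random.default_rng(cfg.seed + 3)
            for _ in range(cfg.align_epochs):
                for batch_local in _stratified_batches(y[tr], cfg.batch_size,
                                                       align_rng):
                    idx = tr[batch_local]
                    opt_align.zero_grad()
                    loss = dual.alignment_loss(imgs_std[idx], clin[idx],
                                               cfg.temperature)
                    loss.backward()
                    opt_align.step()
            # warm-start the classification projection from the aligned one
            # (pretrain-then-fine-tune: f_CT starts in the aligned space)
            w_fuse.data[...] = dual.W_img.data

        for epoch in range(cfg.epochs):
            comps = np.zeros(3)
            batches = _stratified_batches(y[tr], cfg.batch_size, train_rng)
            for batch_local in batches:
                idx = tr[batch_local]
                probs, l_con = self._forward(
                    imgs_std[idx], clin[idx], lf_z[idx], env_z[idx],
                    dual, lf_enc, env_enc, gate, head, forced, cfg, w_fuse,
                    gate_cols)
                l_cls = binary_cross_entropy(probs, y[idx])

                l_adv = Tensor(0.0)
                if cgan is not None:
                    obs_b = idx[observed[idx]]
                    if obs_b.size >= 2:
                        envb = (env_raw[obs_b] - cgan.env_mu) / cgan.env_sd
                        noise = gan_rng.normal(
                            size=(len(obs_b), cgan.params.noise_dim))
                        opt_critic.zero_grad()
                        lc = critic_loss(cgan.critic, cgan.generator, envb,
                                         clin[obs_b], noise, cfg.phi_gp,
                                         gan_rng)
                        lc.backward()
                        opt_critic.step()
                        noise = gan_rng.normal(
                            size=(len(obs_b), cgan.params.noise_dim))
                        l_adv = generator_loss(cgan.critic, cgan.generator,
                                               clin[obs_b], noise)

                lam1 = 0.0 if "contrastive" in cfg.disable else cfg.lambda_contrast
                lam2 = cfg.lambda_wgan if cgan is not None else 0.0
                total = l_cls + lam1 * l_con + lam2 * l_adv
                opt.zero_grad()
                total.backward()
                opt.step()
                comps += np.array([l_cls.item(), l_con.item(), l_adv.item()])
            comps /= max(len(batches), 1)
            lam1 = 0.0 if "contrastive" in cfg.disable else cfg.lambda_contrast
            lam2 = cfg.lambda_wgan if cgan is not None else 0.0
            trace.append(total_loss(comps[0], comps[1], comps[2], lam1, lam2))
            logger.debug("epoch %d: total=%.4f", epoch, trace[-1].total)

        res = MMDFResults(
            config=cfg, records=self.records, images=self.images,
            image_params=self.image_params, schema=schema,
            img_mu=img_mu, img_sd=img_sd, env_mu=env_mu, env_sd=env_sd,
            dual=dual, lf_enc=lf_enc, env_enc=env_enc, gate=gate, head=head,
            cgan=cgan, w_fuse=w_fuse, gate_cols=gate_cols, trace=trace, split_indices={"train": tr, "val": va,
                                                   "test": te},
            labels=y, env_filled=env_filled)
        scores_val = res._scores(imgs_std[va], clin[va], lf_z[va], env_z[va])
        res.threshold = youden_threshold(scores_val, y[va]) \
            if len(np.unique(y[va])) > 1 else 0.5
        res._cache = (imgs_std, clin, lf_z, env_z)
        return res

    def _tower_params(self, dual: DualTower, cfg: TrainConfig) -> dict:
        params = dual.parameters()
        if cfg.fine_tune == "all":
            return params
        img_keys = [k for k in params if k.startswith("dual.img.")]
        if cfg.fine_tune == "freeze-features":
            drop = set(img_keys)
        else:  # tune-last-blocks: keep the last three conv blocks trainable
            blocks = sorted({int(k.split(".")[2]) for k in img_keys})
            frozen_blocks = set(blocks[:-3])
            drop = {k for k in img_keys if int(k.split(".")[2]) in frozen_blocks}
        return {k: v for k, v in params.items() if k not in drop}

    @staticmethod
    def _forced_weights(cfg: TrainConfig) -> np.ndarray | None:
        if cfg.modality is not None:
            onehot = {"CT": [1.0, 0.0, 0.0], "lung_function": [0.0, 1.0, 0.0],
                      "environment": [0.0, 0.0, 1.0]}[cfg.modality]
            return np.asarray(onehot)
        if "gating" in cfg.disable:
            return np.full(3, 1.0 / 3.0)
        return None

    @staticmethod
    def _forward(images, clin, lf_z, env_z, dual, lf_enc, env_enc, gate,
                 head, forced, cfg, w_fuse, gate_cols):
        img_feats = dual.image_tower(images)
        # joint-phase contrastive term: alignment already shaped the backbone
        # during pretraining; here it fine-tunes the projections and the
        # clinical tower while the backbone is updated by the main task only
        # (the freeze-the-feature-extractor side of the fine-tune policy).
        emb_img = project_normalize(Tensor(img_feats.data), dual.W_img)
        tab_emb = dual.encode_tabular(clin)
        l_con = contrastive_loss(similarity_matrix(emb_img, tab_emb),
                                 cfg.temperature)
        f_ct = project_normalize(img_feats, w_fuse)
        f_lf = project_normalize(lf_enc(lf_z))
        f_env = project_normalize(env_enc(env_z))
        if forced is None:
            w = gate(clin[:, gate_cols] if gate_cols is not None else clin)
        else:
            w = Tensor(np.tile(forced, (len(clin), 1)))
        fused = fuse_features(f_ct, f_lf, f_env, w)
        probs = classify(fused, head)
        return probs, l_con


@dataclass
class MMDFResults:
    """Fitted model state plus evaluation and reporting methods."""

    config: TrainConfig
    records: list
    images: np.ndarray
    image_params: SyntheticImageParams
    schema: TabularSchema
    img_mu: float
    img_sd: float
    env_mu: np.ndarray
    env_sd: np.ndarray
    dual: DualTower
    lf_enc: MLP
    env_enc: MLP
    gate: GatingNetwork
    head: MLP
    cgan: EnvCGAN | None
    w_fuse: Tensor
    gate_cols: np.ndarray
    trace: list
    split_indices: dict
    labels: np.ndarray
    env_filled: np.ndarray
    threshold: float = 0.5
    _cache: tuple = field(default=None, repr=False)

    # -- feature plumbing -------------------------------------------------
    def _prepare(self, records: list[PatientRecord],
                 images: np.ndarray | None):
        df = cohort_to_dataframe(records)
        if images is None:
            images = render_cohort_images(records, self.image_params,
                                          seed=self.config.seed)
        imgs_eq = np.stack([histogram_equalize(im, levels=65536)
                            for im in images]).astype(np.float64) / 65535.0
        imgs_std = (imgs_eq - self.img_mu) / self.img_sd
        clin = self.schema.transform(df)
        env_raw = df[["pm25", "exposure_years"]].to_numpy(dtype=float)
        missing = df["env_missing"].to_numpy().astype(bool)
        if missing.any():
            if self.cgan is not None:
                draws = self.cgan.sample(
                    clin[missing], np.random.default_rng(self.config.seed + 11),
                    n_draws=20)
                env_raw[missing] = draws.mean(axis=0)
            else:
                env_raw[missing] = self.env_mu
        env_z = (env_raw - self.env_mu) / self.env_sd
        fev_idx = list(self.schema.continuous).index("fev1_fvc")
        lf_z = clin[:, [fev_idx]]
        return imgs_std, clin, lf_z, env_z

    def _scores(self, imgs_std, clin, lf_z, env_z) -> np.ndarray:
        forced = MMDFModel._forced_weights(self.config)
        probs, _ = MMDFModel._forward(imgs_std, clin, lf_z, env_z, self.dual,
                                      self.lf_enc, self.env_enc, self.gate,
                                      self.head, forced, self.config,
                                      self.w_fuse, self.gate_cols)
        return probs.data

    def predict(self, records: list[PatientRecord] | None = None,
                images: np.ndarray | None = None) -> np.ndarray:
        """Risk probabilities for ``records`` (default: the fitted cohort)."""
        if records is None:
            imgs_std, clin, lf_z, env_z = self._cache
            return self._scores(imgs_std, clin, lf_z, env_z)
        return self._scores(*self._prepare(records, images))

    def gating_weights(self, records: list[PatientRecord] | None = None
                       ) -> np.ndarray:
        """Per-patient (w_CT, w_LungFunction, w_Environment) rows."""
        forced = MMDFModel._forced_weights(self.config)
        if records is None:
            clin = self._cache[1]
        else:
            clin = self.schema.transform(cohort_to_dataframe(records))
        if forced is not None:
            return np.tile(forced, (len(clin), 1))
        return self.gate(clin[:, self.gate_cols]).data

    # -- evaluation -------------------------------------------------------
    def evaluate(self, split: str = "test",
                 records: list[PatientRecord] | None = None,
                 images: np.ndarray | None = None,
                 threshold: float | None = None) -> EvaluationReport:
        """Metrics on a fitted split or on an external cohort.

        The decision threshold defaults to the Youden-optimal threshold on
        the validation split, frozen at fit time.
        """
        thr = self.threshold if threshold is None else threshold
        if records is not None:
            scores = self.predict(records, images)
            y = np.array([r.label == "COPD" for r in records], dtype=int)
        else:
            idx = self.split_indices[split]
            imgs_std, clin, lf_z, env_z = self._cache
            scores = self._scores(imgs_std[idx], clin[idx], lf_z[idx],
                                  env_z[idx])
            y = self.labels[idx]
        return evaluate_metrics(scores, y, threshold=thr)

    def loss_trace_frame(self) -> pd.DataFrame:
        rows = [{"epoch": i, "classification": b.classification,
                 "contrastive": b.contrastive, "adversarial": b.adversarial,
                 "total": b.total} for i, b in enumerate(self.trace)]
        return pd.DataFrame(rows)

    def weights_frame(self) -> pd.DataFrame:
        """Per-patient gating weights with subgroup attributes, exportable."""
        w = self.gating_weights()
        df = cohort_to_dataframe(self.records)
        out = pd.DataFrame({
            "id": df["id"], "label": df["label"], "stage": df["stage"],
            "smoker": df["smoker"],
            "pm25": self.env_filled[:, 0],
            "w_CT": w[:, 0], "w_lung_function": w[:, 1],
            "w_environment": w[:, 2]})
        return out

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-style text block)."""
        cfg = self.config
        lines = ["Multimodal dynamic fusion model",
                 "=" * 46,
                 f"records: {len(self.records)}   "
                 f"(train/val/test: "
                 f"{len(self.split_indices['train'])}/"
                 f"{len(self.split_indices['val'])}/"
                 f"{len(self.split_indices['test'])})",
                 f"epochs: {cfg.epochs}   batch: {cfg.batch_size}   "
                 f"T: {cfg.temperature}   d: {cfg.embed_dim}   "
                 f"h: {cfg.gate_hidden}",
                 f"lambda1: {cfg.lambda_contrast}   "
                 f"lambda2: {cfg.lambda_wgan}   phi_gp: {cfg.phi_gp}",
                 f"disabled: {list(cfg.disable) or 'none'}   "
                 f"modality: {cfg.modality or 'all'}"]
        final = self.trace[-1]
        lines.append(f"final losses: cls={final.classification:.4f} "
                     f"con={final.contrastive:.4f} adv={final.adversarial:.4f} "
                     f"total={final.total:.4f}")
        for split in ("val", "test"):
            if len(np.unique(self.labels[self.split_indices[split]])) > 1:
                r = self.evaluate(split)
                lines.append(f"{split}: AUC={r.auc:.3f} "
                             f"sens={r.sensitivity:.1f}% "
                             f"spec={r.specificity:.1f}% F1={r.f1:.3f}")
        w = self.gating_weights().mean(axis=0)
        lines.append(f"mean weights: CT={w[0]:.3f} LF={w[1]:.3f} "
                     f"Env={w[2]:.3f}")
        return "\n".join(lines)

    def plot_training(self, path=None):
        """Loss-component trajectories; returns the matplotlib figure."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        df = self.loss_trace_frame()
        fig, ax = plt.subplots(figsize=(6, 4))
        for col in ("classification", "contrastive", "adversarial", "total"):
            ax.plot(df["epoch"], df[col], label=col)
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
        return fig

    def save(self, path) -> None:
        """Checkpoint all parameters plus preprocessing state (npz)."""
        state = {"dual": flatten_params(self.dual.parameters()),
                 "lf": flatten_params(self.lf_enc.parameters("lf")),
                 "env": flatten_params(self.env_enc.parameters("env")),
                 "gate": flatten_params(self.gate.parameters("gate")),
                 "head": flatten_params(self.head.parameters("head")),
                 "fuse": {"w_fuse": self.w_fuse.data.copy()}}
        flat = {f"{g}::{k}": v for g, d in state.items() for k, v in d.items()}
        flat["__img_mu"] = np.array([self.img_mu])
        flat["__img_sd"] = np.array([self.img_sd])
        flat["__env_mu"] = self.env_mu
        flat["__env_sd"] = self.env_sd
        flat["__threshold"] = np.array([self.threshold])
        np.savez(path, schema=self.schema.to_json(),
                 config=_config_json(self.config), **flat)


def _config_json(cfg: TrainConfig) -> str:
    import json
    return json.dumps(dataclasses.asdict(cfg))


def train_mmdf(records: list[PatientRecord], config: TrainConfig,
               images: np.ndarray | None = None,
               image_params: SyntheticImageParams | None = None
               ) -> MMDFResults:
    """Fit the full pipeline on a cohort; deterministic given config.seed."""
    return MMDFModel(records, config, images=images,
                     image_params=image_params).fit()


def run_ablation(records: list[PatientRecord], config: TrainConfig,
                 components=ABLATABLE,
                 images: np.ndarray | None = None,
                 image_params: SyntheticImageParams | None = None,
                 eval_records: list[PatientRecord] | None = None,
                 eval_images: np.ndarray | None = None) -> pd.DataFrame:
    """Ablation table: the full model plus one row per disabled configuration.

    ``components`` lists the configurations to ablate; each element is a
    component name or a tuple of names disabled together.  Semantics:
    "gating" fixes weights at (1/3, 1/3, 1/3), "cgan" replaces imputation
    with training-mean fill, "contrastive" sets lambda1 = 0.  All rows share
    the seed and splits of ``config``.
    """
    rows = []
    configs = [("full", ())]
    for comp in components:
        names = (comp,) if isinstance(comp, str) else tuple(comp)
        configs.append(("-" + "+".join(names), names))
    for name, disable in configs:
        cfg = dataclasses.replace(config, disable=disable)
        res = train_mmdf(records, cfg, images=images,
                         image_params=image_params)
        rep = (res.evaluate(records=eval_records, images=eval_images)
               if eval_records is not None else res.evaluate("test"))
        rows.append({"configuration": name, **rep.as_dict()})
    return pd.DataFrame(rows)


def subgroup_weight_report(results: MMDFResults,
                           grouping: str = "smoking",
                           pm25_threshold: float = 40.0) -> pd.DataFrame:
    """Per-group mean +/- sd of the gating weights.

    ``grouping``: "smoking" (smoker vs nonsmoker), "stage" (disease stage),
    or "pm25" (exposure >= / < ``pm25_threshold`` ug/m3, default 40).
    Empty groups are omitted with a warning.
    """
    wf = results.weights_frame()
    if grouping == "smoking":
        wf["group"] = np.where(wf["smoker"], "smoker", "nonsmoker")
    elif grouping == "stage":
        wf["group"] = wf["stage"]
    elif grouping == "pm25":
        wf["group"] = np.where(wf["pm25"] >= pm25_threshold,
                               f"high (>= {pm25_threshold:g})",
                               f"low (< {pm25_threshold:g})")
    else:
        raise ValueError(f"unknown grouping: {grouping!r}")
    rows = []
    for group, sub in wf.groupby("group", sort=True):
        if len(sub) == 0:  # pragma: no cover - groupby drops empty groups
            logger.warning("empty subgroup %r omitted", group)
            continue
        row = {"group": group, "n": len(sub)}
        for col, label in (("w_CT", "CT"), ("w_lung_function", "lung_function"),
                           ("w_environment", "environment")):
            row[f"{label}_mean"] = float(sub[col].mean())
            row[f"{label}_sd"] = float(sub[col].std(ddof=0))
        rows.append(row)
    return pd.DataFrame(rows)


def cross_validate(records: list[PatientRecord], config: TrainConfig,
                   k: int = 3, images: np.ndarray | None = None,
                   image_params: SyntheticImageParams | None = None
                   ) -> pd.DataFrame:
    """Stratified k-fold cross-validation (threefold by default).

    Each fold trains on k-1 folds (with an internal validation split for the
    decision threshold) and reports metrics on the held-out fold.
    """
    y = np.array([r.label == "COPD" for r in records], dtype=int)
    if images is None:
        params = image_params or SyntheticImageParams(height=32, width=32)
        images = render_cohort_images(records, params, seed=config.seed)
        image_params = params
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        cfg = dataclasses.replace(config, split_fractions=(0.8, 0.2, 0.0),
                                  seed=config.seed + fold)
        sub = [records[i] for i in tr]
        res = train_mmdf(sub, cfg, images=images[tr],
                         image_params=image_params)
        rep = res.evaluate(records=[records[i] for i in te],
                           images=images[te])
        rows.append({"fold": fold, **rep.as_dict()})
    return pd.DataFrame(rows)
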
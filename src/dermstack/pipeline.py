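"""End-to-end orchestration: enhance -> extract -> heads -> stack -> meta.

The protocol mirrors the study design: an 80/20 stratified train/test split
is made first; stratified K-fold cross-validation runs *inside* the
training split to build out-of-fold stacked vectors for the meta-model;
the base models are then refit on the full training split for deployment,
and everything is evaluated once on the held-out test split.

A single global seed fans out deterministically to per-stage seeds through
``numpy.random.SeedSequence``, so a whole run is reproducible bit-for-bit
with the seeded test backbone.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import backbone as bb
from . import clinical as cl
from . import evaluation as ev
from . import fusion_head as fh
from . import stacking as st
from .imaging import StructuringElement, ThresholdConfig, enhance_triplet

__all__ = [
    "PipelineConfig",
    "FittedPipeline",
    "stage_seeds",
    "compute_fused_gap_features",
    "fit_pipeline",
    "run_protocol",
    "save_pipeline",
    "load_pipeline",
]

logger = logging.getLogger("dermstack")

_STAGES = ("synth", "backbone", "head", "clinical", "folds", "split", "meta")


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds spawned from one global seed."""
    state = np.random.SeedSequence(global_seed).generate_state(len(_STAGES))
    return {name: int(s % 2**31) for name, s in zip(_STAGES, state)}


@dataclasses.dataclass
class PipelineConfig:
    """Resolved configuration of a full run."""

    kernel: StructuringElement = dataclasses.field(default_factory=StructuringElement)
    threshold: ThresholdConfig = dataclasses.field(default_factory=ThresholdConfig)
    backbone_depth: int = 2
    head: fh.HeadConfig | None = None
    clinical: cl.ClinicalConfig | None = None
    meta: st.MetaConfig | None = None
    n_folds: int = 10
    test_frac: float = 0.2
    val_frac: float = 0.2
    seed: int = 0

    def resolved(self) -> "PipelineConfig":
        """Fill per-stage configs from the global seed where unset."""
        seeds = stage_seeds(self.seed)
        return dataclasses.replace(
            self,
            head=self.head or fh.HeadConfig(seed=seeds["head"]),
            clinical=self.clinical or cl.ClinicalConfig(seed=seeds["clinical"]),
            meta=self.meta or st.MetaConfig(seed=seeds["meta"]),
        )


def compute_fused_gap_features(
    images: np.ndarray,
    backbone,
    kernel: StructuringElement | None = None,
    threshold: ThresholdConfig | None = None,
    chunk_size: int = 32,
) -> np.ndarray:
    """Enhance each image, extract the three feature maps, fuse, pool.

    Returns the (n, 768) matrix of GAP vectors of the fused maps.  Feature
    maps are processed in chunks and discarded immediately, keeping memory
    flat for large cohorts.
    """
    if isinstance(backbone, bb.BackboneSpec):
        backbone = bb.get_backbone(backbone)
    n = len(images)
    out = None
    for start in range(0, n, chunk_size):
        batch = images[start : start + chunk_size]
        triplets = [enhance_triplet(img, kernel, threshold) for img in batch]
        stacked = np.stack(
            [m for t in triplets for m in t.members()]
        )  # (3b, 224, 224, 3) ordered orig, bh, ad per sample
        fmaps = bb.extract_features_batch(stacked, backbone, chunk_size=chunk_size)
        for i in range(len(batch)):
            fused = fh.fuse_triplet_features(
                fmaps[3 * i], fmaps[3 * i + 1], fmaps[3 * i + 2]
            )
            gap = fh.global_average_pool(fused)
            if out is None:
                out = np.empty((n, gap.shape[0]))
            out[start + i] = gap
        logger.debug("features %d/%d", min(start + chunk_size, n), n)
    return out


@dataclasses.dataclass
class FittedPipeline:
    """Deployable artifacts of a training run."""

    head: fh.ImageHead
    clinical_model: cl.ClinicalModel
    meta: st.MetaModel
    fold_plan: st.FoldPlan
    oof_stack: np.ndarray
    config: PipelineConfig

    def predict_proba(self, gap_features: np.ndarray, clinical_rows: pd.DataFrame) -> np.ndarray:
        p_img = self.head.predict_proba(gap_features)
        p_clin = cl.predict_clinical_probs(self.clinical_model, clinical_rows)
        z = np.hstack([p_img, p_clin])
        return self.meta.predict_proba(z)

    def predict(self, gap_features: np.ndarray, clinical_rows: pd.DataFrame) -> np.ndarray:
        return np.argmax(self.predict_proba(gap_features, clinical_rows), axis=1)


def fit_pipeline(
    gap_features: np.ndarray,
    clinical_table: pd.DataFrame,
    labels: np.ndarray,
    cfg: PipelineConfig,
) -> FittedPipeline:
    """OOF stacking + meta-model fit + full-data base-model refit."""
    cfg = cfg.resolved()
    seeds = stage_seeds(cfg.seed)
    y = np.asarray(labels, dtype=int)
    plan = st.make_fold_plan(y, n_folds=cfg.n_folds, seed=seeds["folds"])
    z_oof, _ = st.make_oof_stack(
        gap_features, clinical_table, y, plan, cfg.head, cfg.clinical
    )
    meta = st.fit_meta(z_oof, y, cfg.meta)
    head = fh.fit_image_head(gap_features, y, cfg.head)
    clin = cl.fit_clinical_model(clinical_table, y, cfg.clinical)
    return FittedPipeline(
        head=head,
        clinical_model=clin,
        meta=meta,
        fold_plan=plan,
        oof_stack=z_oof,
        config=cfg,
    )


def run_protocol(
    images: np.ndarray,
    metadata: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> dict:
    """The full study protocol on one paired dataset.

    Splits 80/20 (stratified), trains the stacked model on the training
    side, and reports held-out accuracies of the image branch, the clinical
    branch and the stacked model, plus the test confusion matrix and the
    per-class/macro metrics report.
    """
    if cfg is None:
        cfg = PipelineConfig()
    cfg = cfg.resolved()
    seeds = stage_seeds(cfg.seed)

    features_table, y, categories = cl.clean_metadata(metadata)
    split = ev.split_dataset(
        len(y), y, test_frac=cfg.test_frac, val_frac=cfg.val_frac,
        seed=seeds["split"], stratify=True,
    )
    train_idx, test_idx = split.train_full, split.test

    spec = bb.BackboneSpec.for_testing(seed=seeds["backbone"], depth=cfg.backbone_depth)
    logger.info("extracting fused features for %d images", len(images))
    gap = compute_fused_gap_features(images, spec, cfg.kernel, cfg.threshold)

    logger.info("fitting stacked model on %d training samples", len(train_idx))
    fitted = fit_pipeline(
        gap[train_idx], features_table.iloc[train_idx], y[train_idx], cfg
    )

    y_test = y[test_idx]
    p_img = fitted.head.predict_proba(gap[test_idx])
    p_clin = cl.predict_clinical_probs(
        fitted.clinical_model, features_table.iloc[test_idx]
    )
    z_test = np.hstack([p_img, p_clin])
    p_stack = fitted.meta.predict_proba(z_test)

    acc = lambda p: float(np.mean(np.argmax(p, axis=1) == y_test))  # noqa: E731
    cm = ev.confusion_matrix(y_test, np.argmax(p_stack, axis=1))
    report = ev.per_class_metrics(cm, n_total=len(y_test))
    results = {
        "image_accuracy": acc(p_img),
        "clinical_accuracy": acc(p_clin),
        "stacked_accuracy": acc(p_stack),
        "confusion": cm,
        "report": report,
        "split": split,
        "fitted": fitted,
        "gap_features": gap,
        "labels": y,
        "categories": categories,
    }
    logger.info(
        "held-out accuracy: image %.3f, clinical %.3f, stacked %.3f",
        results["image_accuracy"], results["clinical_accuracy"],
        results["stacked_accuracy"],
    )
    return results


def save_pipeline(fitted: FittedPipeline, out_dir) -> None:
    """Persist the deployable artifacts of a fitted pipeline.

    Layout: ``head.npz`` (dense-layer weights and standardisation),
    ``clinical.ubj`` (the boosted trees), ``meta.npz`` (logistic-regression
    coefficients) and ``pipeline.json`` (configs, schema, encodings).
    """
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(
        out / "head.npz",
        w=fitted.head.w, b=fitted.head.b,
        mean=fitted.head.mean, std=fitted.head.std,
    )
    fitted.clinical_model.booster.get_booster().save_model(out / "clinical.ubj")
    lr = fitted.meta.model
    np.savez(
        out / "meta.npz",
        coef=lr.coef_, intercept=lr.intercept_, classes=lr.classes_,
        clinical_classes=fitted.clinical_model.classes_present,
    )
    cfg = fitted.config
    meta_json = {
        "kernel": {"shape": cfg.kernel.shape, "size": list(cfg.kernel.size)},
        "threshold": dataclasses.asdict(cfg.threshold),
        "backbone_depth": cfg.backbone_depth,
        "head": dataclasses.asdict(cfg.head),
        "clinical": dataclasses.asdict(cfg.clinical),
        "meta": dataclasses.asdict(cfg.meta),
        "n_folds": cfg.n_folds,
        "test_frac": cfg.test_frac,
        "val_frac": cfg.val_frac,
        "seed": cfg.seed,
        "clinical_columns": list(fitted.clinical_model.columns),
        "categories": fitted.clinical_model.categories,
    }
    (out / "pipeline.json").write_text(json.dumps(meta_json, indent=2))


def load_pipeline(model_dir) -> FittedPipeline:
    """Rebuild a :class:`FittedPipeline` saved by :func:`save_pipeline`."""
    import json
    from pathlib import Path

    import xgboost as xgb
    from sklearn.linear_model import LogisticRegression

    out = Path(model_dir)
    meta_json = json.loads((out / "pipeline.json").read_text())
    head_cfg = fh.HeadConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in meta_json["head"].items()
    })
    clin_cfg = cl.ClinicalConfig(**meta_json["clinical"])
    meta_cfg = st.MetaConfig(**meta_json["meta"])
    cfg = PipelineConfig(
        kernel=StructuringElement(
            shape=meta_json["kernel"]["shape"],
            size=tuple(meta_json["kernel"]["size"]),
        ),
        threshold=ThresholdConfig(**meta_json["threshold"]),
        backbone_depth=meta_json["backbone_depth"],
        head=head_cfg, clinical=clin_cfg, meta=meta_cfg,
        n_folds=meta_json["n_folds"], test_frac=meta_json["test_frac"],
        val_frac=meta_json["val_frac"], seed=meta_json["seed"],
    )

    h = np.load(out / "head.npz")
    head = fh.ImageHead(w=h["w"], b=h["b"], mean=h["mean"], std=h["std"], cfg=head_cfg)

    raw = xgb.Booster()
    raw.load_model(str(out / "clinical.ubj"))
    m = np.load(out / "meta.npz")
    clin = cl.ClinicalModel(
        booster=cl.BoosterAdapter(raw),
        columns=tuple(meta_json["clinical_columns"]),
        classes_present=m["clinical_classes"],
        categories=meta_json["categories"],
        config=clin_cfg,
    )

    lr = LogisticRegression(C=meta_cfg.C, max_iter=meta_cfg.max_iter,
                            random_state=meta_cfg.seed)
    lr.coef_, lr.intercept_, lr.classes_ = m["coef"], m["intercept"], m["classes"]
    meta = st.MetaModel(
        model=lr, classes_present=m["classes"], config=meta_cfg, converged=True
    )
    plan = st.FoldPlan(
        n_folds=cfg.n_folds, assignment=np.array([], dtype=int), seed=cfg.seed
    )
    return FittedPipeline(
        head=head, clinical_model=clin, meta=meta,
        fold_plan=plan, oof_stack=np.empty((0, 12)), config=cfg,
    )
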
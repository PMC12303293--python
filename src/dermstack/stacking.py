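"""Out-of-fold stacking of the image and clinical branches.

Each sample's two 6-class probability vectors are concatenated — image half
first — into a 12-long stacked vector.  To keep the meta-model honest, the
stacked vector of every sample is produced by base models trained *without*
that sample's fold (out-of-fold, OOF): a stratified K-fold plan partitions
the training set, and for each fold both branches are refit on the other
K-1 folds and predict the held-out fold.  A multinomial logistic regression
then learns how much to trust each branch per class.

For deployment the base models are refit on the full training split; the
meta-model keeps its OOF-trained coefficients.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .clinical import ClinicalConfig, fit_clinical_model, predict_clinical_probs
from .fusion_head import HeadConfig, fit_image_head

__all__ = [
    "FoldPlan",
    "MetaConfig",
    "MetaModel",
    "make_fold_plan",
    "stack_probs",
    "make_oof_stack",
    "fit_meta",
    "predict_final",
]

N_CLASSES = 6
STACK_DIM = 12


@dataclasses.dataclass(frozen=True)
class FoldPlan:
    """Stratified partition of samples into K folds."""

    n_folds: int
    assignment: np.ndarray  # fold index per sample
    seed: int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)


@dataclasses.dataclass(frozen=True)
class MetaConfig:
    """L2-regularised multinomial logistic regression settings."""

    C: float = 1.0
    max_iter: int = 1000
    seed: int = 0


def make_fold_plan(labels, n_folds: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified K-fold assignment, deterministic given the seed.

    Every class must have at least ``n_folds`` members so each fold can hold
    a proportional share; per-fold class counts then differ from exact
    proportionality by at most one sample.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels)
    rare = np.flatnonzero((counts > 0) & (counts < n_folds))
    if rare.size:
        raise ValueError(
            f"classes {rare.tolist()} have fewer than {n_folds} members; "
            f"lower n_folds to at most {int(counts[counts > 0].min())}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return FoldPlan(n_folds=n_folds, assignment=assignment, seed=seed)


def _check_prob_vector(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (N_CLASSES,):
        raise ValueError(f"{name} must have shape (6,), got {p.shape}")
    if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"{name} is not a probability vector (sum {p.sum():.8f})")
    return p


def stack_probs(p_img: np.ndarray, p_clin: np.ndarray) -> np.ndarray:
    """Concatenate branch probabilities, image half first: (6,)+(6,) -> (12,)."""
    return np.concatenate([
        _check_prob_vector(p_img, "p_img"),
        _check_prob_vector(p_clin, "p_clin"),
    ])


def make_oof_stack(
    image_features: np.ndarray,
    clinical_table: pd.DataFrame,
    labels,
    plan: FoldPlan,
    head_cfg: HeadConfig | None = None,
    clin_cfg: ClinicalConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold stacked vectors for every sample.

    ``image_features`` are the fused feature maps (n, h, w, d) or their GAP
    vectors (n, d); ``clinical_table`` the cleaned clinical features aligned
    row-for-row.  For each fold, both branches are trained on the remaining
    folds only and predict the held-out samples, so no sample's stacked
    vector ever depends on models that saw it.

    Returns ``(Z, labels)`` with Z of shape (n, 12).
    """
    x_img = np.asarray(image_features)
    x_clin = pd.DataFrame(clinical_table)
    y = np.asarray(labels, dtype=int)
    if not (len(x_img) == len(x_clin) == len(y) == len(plan.assignment)):
        raise ValueError("image features, clinical rows, labels and fold plan "
                         "must cover the same samples")

    z = np.full((len(y), STACK_DIM), np.nan)
    for fold in range(plan.n_folds):
        test = plan.fold_indices(fold)
        train = np.flatnonzero(plan.assignment != fold)
        head = fit_image_head(x_img[train], y[train], head_cfg)
        clin = fit_clinical_model(x_clin.iloc[train], y[train], clin_cfg)
        p_img = head.predict_proba(x_img[test])
        p_clin = predict_clinical_probs(clin, x_clin.iloc[test])
        z[test] = np.hstack([p_img, p_clin])
    assert not np.isnan(z).any(), "some samples received no OOF vector"
    return z, y


@dataclasses.dataclass
class MetaModel:
    """Multinomial logistic regression over the 12 stacked probabilities."""

    model: LogisticRegression
    classes_present: np.ndarray
    config: MetaConfig
    converged: bool

    def predict_proba(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        if z.shape[1] != STACK_DIM:
            raise ValueError(f"stacked vectors must have {STACK_DIM} entries")
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite stacked vector")
        compact = self.model.predict_proba(z)
        probs = np.zeros((len(z), N_CLASSES))
        probs[:, self.classes_present] = compact
        return probs


def fit_meta(stacked_table: np.ndarray, labels, cfg: MetaConfig | None = None) -> MetaModel:
    """Fit the logistic-regression meta-model on (OOF) stacked vectors."""
    if cfg is None:
        cfg = MetaConfig()
    z = np.asarray(stacked_table, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite stacked table")
    classes_present = np.unique(y)
    if len(classes_present) < 2:
        raise ValueError("need at least two classes to fit the meta-model")
    lr = LogisticRegression(  # default penalty is L2 at strength 1/C
        C=cfg.C,
        max_iter=cfg.max_iter,
        random_state=cfg.seed,
    )
    lr.fit(z, y)
    converged = bool(np.all(lr.n_iter_ < cfg.max_iter))
    return MetaModel(
        model=lr, classes_present=classes_present, config=cfg, converged=converged
    )


def predict_final(meta: MetaModel, z: np.ndarray) -> tuple[int, np.ndarray]:
    """Final label and probability vector for one stacked vector.

    Ties in the argmax break toward the lowest class code.
    """
    probs = meta.predict_proba(np.asarray(z))[0]
    return int(np.argmax(probs)), probs
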
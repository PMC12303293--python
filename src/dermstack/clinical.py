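"""Clinical-metadata cleaning and the gradient-boosted tabular branch.

The metadata table follows the PAD-UFES-20 schema: 26 attributes per lesion
covering identifiers, lifestyle (smoking, drinking, pesticide exposure),
family background and cancer history, Fitzpatrick skin type, lesion
diameters, symptom booleans (itch, grew, hurt, changed, bled, elevation)
and biopsy status.  Roughly a third of the lifestyle/demographic cells are
missing in the real data.

Cleaning drops the five non-predictive columns (the three identifiers, the
diagnostic label itself, and the anatomical region), encodes booleans as
{0, 1} and categoricals as ordinal integer codes, and — deliberately —
leaves missing values as NaN: the gradient-boosted trees route missing
values natively, so no imputation step distorts the data.

Note: ``biopsied`` is kept as a predictor, mirroring the source schema, but
it encodes how the ground-truth label was confirmed and may leak diagnostic
certainty; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .imaging import CLASS_NAMES, encode_class

__all__ = [
    "TABLE_COLUMNS",
    "BoosterAdapter",
    "DROPPED_COLUMNS",
    "BOOLEAN_COLUMNS",
    "CATEGORICAL_COLUMNS",
    "NUMERIC_COLUMNS",
    "ClinicalConfig",
    "ClinicalModel",
    "clean_metadata",
    "fit_clinical_model",
    "predict_clinical_probs",
]

#: Full metadata schema in canonical order.
TABLE_COLUMNS = (
    "patient_id", "lesion_id", "smoke", "drink", "background_father",
    "background_mother", "age", "pesticide", "gender", "skin_cancer_history",
    "cancer_history", "has_piped_water", "has_sewage_system", "fitzpatrick",
    "region", "diameter_1", "diameter_2", "diagnostic", "itch", "grew",
    "hurt", "changed", "bled", "elevation", "img_id", "biopsied",
)

#: Omitted before modelling: identifiers, the label, and the anatomical region.
DROPPED_COLUMNS = ("patient_id", "lesion_id", "img_id", "diagnostic", "region")

BOOLEAN_COLUMNS = (
    "smoke", "drink", "pesticide", "skin_cancer_history", "cancer_history",
    "has_piped_water", "has_sewage_system", "itch", "grew", "hurt",
    "changed", "bled", "elevation", "biopsied",
)

CATEGORICAL_COLUMNS = ("background_father", "background_mother", "gender")

NUMERIC_COLUMNS = ("age", "fitzpatrick", "diameter_1", "diameter_2")

_TRUE_STRINGS = {"true", "1", "yes"}
_FALSE_STRINGS = {"false", "0", "no"}


@dataclasses.dataclass(frozen=True)
class ClinicalConfig:
    """Gradient-boosting hyperparameters for the clinical branch."""

    n_estimators: int = 300
    max_depth: int = 6
    learning_rate: float = 0.1
    seed: int = 0


def _encode_boolean(series: pd.Series) -> pd.Series:
    def conv(v):
        if pd.isna(v):
            return np.nan
        if isinstance(v, (bool, np.bool_)):
            return float(v)
        if isinstance(v, (int, float, np.integer, np.floating)):
            return float(bool(v))
        s = str(v).strip().lower()
        if s in _TRUE_STRINGS:
            return 1.0
        if s in _FALSE_STRINGS:
            return 0.0
        raise ValueError(f"cannot interpret {v!r} as boolean")

    return series.map(conv).astype(float)


def clean_metadata(
    records: pd.DataFrame,
    categories: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, np.ndarray, dict[str, list[str]]]:
    """Clean a raw metadata table into a numeric feature table plus labels.

    Parameters
    ----------
    records
        Table with the columns of :data:`TABLE_COLUMNS` (order-insensitive).
    categories
        Optional frozen category lists (from a previous call) so that rows
        seen at predict time are encoded with the training codes.

    Returns
    -------
    (features, labels, categories): the feature table keeps NaN for missing
    cells (no imputation — missing-cell counts are preserved), labels are
    the integer class codes, and ``categories`` records the ordinal code
    assignment per categorical column.
    """
    records = pd.DataFrame(records)
    missing_cols = set(TABLE_COLUMNS) - set(records.columns)
    if missing_cols:
        raise ValueError(f"metadata table lacks columns: {sorted(missing_cols)}")
    if records["img_id"].duplicated().any():
        dupes = records.loc[records["img_id"].duplicated(), "img_id"].tolist()
        raise ValueError(f"duplicate img_id values: {dupes[:5]}")

    labels = np.asarray([encode_class(d) for d in records["diagnostic"]], dtype=int)

    feat = records.drop(columns=list(DROPPED_COLUMNS)).copy()
    for col in BOOLEAN_COLUMNS:
        feat[col] = _encode_boolean(feat[col])
    for col in NUMERIC_COLUMNS:
        feat[col] = pd.to_numeric(feat[col], errors="raise").astype(float)

    out_categories: dict[str, list[str]] = {}
    for col in CATEGORICAL_COLUMNS:
        values = feat[col].map(lambda v: np.nan if pd.isna(v) else str(v))
        if categories is not None:
            cats = list(categories[col])
        else:
            cats = sorted({v for v in values if isinstance(v, str)})
        code_of = {c: float(i) for i, c in enumerate(cats)}
        feat[col] = values.map(lambda v: np.nan if not isinstance(v, str) else code_of.get(v, np.nan))
        out_categories[col] = cats

    # stable column order regardless of incoming order
    ordered = [c for c in TABLE_COLUMNS if c not in DROPPED_COLUMNS]
    feat = feat[ordered].astype(float)
    feat.index = pd.Index(records["img_id"], name="img_id")
    return feat, labels, out_categories


class BoosterAdapter:
    """predict_proba facade over a raw (deserialised) xgboost Booster."""

    def __init__(self, booster):
        self._booster = booster

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        import xgboost as xgb

        dm = xgb.DMatrix(np.asarray(x, dtype=float), missing=np.nan)
        return self._booster.predict(dm)

    def get_booster(self):
        return self._booster


@dataclasses.dataclass
class ClinicalModel:
    """Fitted gradient-boosted ensemble plus its encoding context."""

    booster: "XGBClassifier | BoosterAdapter"
    columns: tuple[str, ...]
    classes_present: np.ndarray  # original class codes, sorted
    categories: dict[str, list[str]] | None = None
    config: ClinicalConfig = dataclasses.field(default_factory=ClinicalConfig)


def fit_clinical_model(
    table: pd.DataFrame,
    labels,
    cfg: ClinicalConfig | None = None,
    categories: dict[str, list[str]] | None = None,
) -> ClinicalModel:
    """Fit the gradient-boosted clinical branch.

    Missing entries (NaN) are consumed natively by the trees — no
    pre-imputation.  Deterministic for a fixed seed and config.
    """
    if cfg is None:
        cfg = ClinicalConfig()
    x = pd.DataFrame(table)
    y = np.asarray(labels, dtype=int)
    if len(x) == 0:
        raise ValueError("empty feature table")
    if len(x) != len(y):
        raise ValueError("table and labels length mismatch")
    classes_present = np.unique(y)
    if len(classes_present) < 2:
        raise ValueError("need at least two classes to fit the clinical model")

    remap = {c: i for i, c in enumerate(classes_present)}
    y_compact = np.asarray([remap[c] for c in y])

    booster = XGBClassifier(
        n_estimators=cfg.n_estimators,
        max_depth=cfg.max_depth,
        learning_rate=cfg.learning_rate,
        objective="multi:softprob",
        num_class=len(classes_present),
        tree_method="hist",
        n_jobs=1,
        random_state=cfg.seed,
        verbosity=0,
    )
    booster.fit(x.to_numpy(dtype=float), y_compact)
    return ClinicalModel(
        booster=booster,
        columns=tuple(x.columns),
        classes_present=classes_present,
        categories=categories,
        config=cfg,
    )


def predict_clinical_probs(model: ClinicalModel, rows: pd.DataFrame) -> np.ndarray:
    """Per-row 6-class probability vectors from the clinical branch.

    Classes absent at training time get probability zero, so each row still
    sums to one.  Rows may contain NaN anywhere (all-missing rows are fine).
    """
    rows = pd.DataFrame(rows)
    if tuple(rows.columns) != model.columns:
        if set(rows.columns) == set(model.columns):
            rows = rows[list(model.columns)]
        else:
            raise ValueError(
                f"row schema {tuple(rows.columns)} does not match "
                f"training schema {model.columns}"
            )
    compact = model.booster.predict_proba(rows.to_numpy(dtype=float))
    probs = np.zeros((len(rows), len(CLASS_NAMES)))
    probs[:, model.classes_present] = compact
    return probs
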
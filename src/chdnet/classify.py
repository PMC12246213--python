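"""Phenotype-category classification from binary phenotype-code matrices.

Patients carry sparse binary indicators over a large hierarchical code
vocabulary; many codes (septal defects, pulmonary stenosis) occur in every
CHD category and carry little signal, while others are nearly diagnostic.
A gradient-boosted tree ensemble learns per-code importance from physician-
labelled training data and assigns each patient a probability over the five
categories (LVO, HTX, AVC, CTD, OTH); the argmax becomes the assignment and
the gap between the best and second-best probability is the confidence
margin.

The learner itself is a pluggable component satisfying a
fit/predict-probabilities contract (xgboost by default); the protocol owned
here is the encoding, the k-fold cross-validated grid search (minimize mean
multiclass log loss, ties by classification error then loss SD), the final
refit on all data, and the assignment/margin/metric conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, log_loss
from sklearn.model_selection import StratifiedKFold

CATEGORIES = ("LVO", "HTX", "AVC", "CTD", "OTH")

DEFAULT_GRID = {
    "max_depth": [3, 4, 6],
    "learning_rate": [0.1, 0.3],
    "n_estimators": [50, 100, 200],
}


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class FylerMatrix:
    """Patients x binary phenotype-code indicators (no missing values)."""

    frame: pd.DataFrame

    def __post_init__(self):
        vals = self.frame.to_numpy()
        if np.isnan(vals.astype(float)).any():
            raise ClassificationError("code matrix must have no missing cells")
        if not np.isin(vals, (0, 1)).all():
            raise ClassificationError("code matrix must be binary")
        if self.frame.index.has_duplicates:
            raise ClassificationError("duplicate patient ids")

    @property
    def patient_ids(self) -> list:
        return list(self.frame.index)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)


@dataclass
class ClassifierModel:
    booster: object
    vocabulary: tuple[str, ...]
    categories: tuple[str, ...]
    hyperparameters: dict
    cv_results: pd.DataFrame
    folds: int
    seed: int


def _make_booster(params: dict, n_classes: int, seed: int):
    from xgboost import XGBClassifier

    return XGBClassifier(
        objective="multi:softprob",
        num_class=n_classes,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="mlogloss",
        **params,
    )


def train_classifier(
    fm: FylerMatrix,
    labels: pd.Series,
    folds: int = 5,
    grid: dict | None = None,
    seed: int = 0,
    categories: tuple[str, ...] = CATEGORIES,
    subsample: float = 1.0,
) -> ClassifierModel:
    """Cross-validated grid search, then a final refit on all data.

    Every grid point is evaluated with stratified k-fold CV; the point with
    the lowest mean multiclass log loss wins, ties broken by lower
    classification error and then lower log-loss SD. ``subsample`` exposes
    the per-round row subsampling of the booster. All diagnostics are kept
    in ``cv_results``.
    """
    grid = dict(grid or DEFAULT_GRID)
    labels = labels.reindex(fm.frame.index)
    if labels.isna().any():
        raise ClassificationError("labels missing for some patients")
    present = set(labels.unique())
    absent = set(categories) - present
    if absent:
        raise ClassificationError(
            f"categories absent from training labels: {sorted(absent)}"
        )
    if not present <= set(categories):
        raise ClassificationError(
            f"unknown labels: {sorted(present - set(categories))}"
        )
    X = fm.frame.to_numpy(dtype=np.float32)
    cat_index = {c: i for i, c in enumerate(categories)}
    y = labels.map(cat_index).to_numpy()

    keys = sorted(grid)
    records = []
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    for values in product(*(grid[k] for k in keys)):
        params = dict(zip(keys, values))
        losses, errors = [], []
        for tr, va in splits:
            clf = _make_booster({**params, "subsample": subsample},
                                len(categories), seed)
            clf.fit(X[tr], y[tr])
            proba = clf.predict_proba(X[va])
            losses.append(log_loss(y[va], proba,
                                   labels=list(range(len(categories)))))
            errors.append(float((proba.argmax(axis=1) != y[va]).mean()))
        records.append({
            **params,
            "mlogloss": float(np.mean(losses)),
            "std_mlogloss": float(np.std(losses, ddof=1)),
            "error": float(np.mean(errors)),
        })
    cv = pd.DataFrame(records)
    order = cv.sort_values(["mlogloss", "error", "std_mlogloss"],
                           kind="stable")
    best = order.iloc[0]
    # pandas upcasts ints to float in mixed rows; restore plain scalars
    best_params = {}
    for k in keys:
        if all(isinstance(v, (int, np.integer)) for v in grid[k]):
            best_params[k] = int(best[k])
        else:
            best_params[k] = float(best[k])

    final = _make_booster({**best_params, "subsample": subsample},
                          len(categories), seed)
    final.fit(X, y)
    return ClassifierModel(
        booster=final,
        vocabulary=fm.codes,
        categories=tuple(categories),
        hyperparameters={**best_params, "subsample": subsample},
        cv_results=cv,
        folds=folds,
        seed=seed,
    )


def predict_assign(model: ClassifierModel, fm: FylerMatrix) -> pd.DataFrame:
    """Per-patient class probabilities, argmax assignment and margin.

    Codes unseen at training time are dropped with a warning; vocabulary
    codes absent from the input are treated as all-zero columns. Returns a
    frame with one probability column per category plus ``assigned`` and
    ``margin`` (best minus second-best probability).
    """
    if fm.frame.shape[0] == 0:
        cols = list(model.categories) + ["assigned", "margin"]
        return pd.DataFrame(columns=cols)
    unseen = set(fm.codes) - set(model.vocabulary)
    if unseen:
        warnings.warn(
            f"dropping {len(unseen)} codes unseen at training time",
            stacklevel=2,
        )
    X = fm.frame.reindex(columns=list(model.vocabulary), fill_value=0) \
        .to_numpy(dtype=np.float32)
    proba = model.booster.predict_proba(X)
    proba = proba / proba.sum(axis=1, keepdims=True)
    top2 = np.sort(proba, axis=1)[:, -2:]
    out = pd.DataFrame(proba, index=fm.frame.index,
                       columns=list(model.categories))
    out["assigned"] = [model.categories[i] for i in proba.argmax(axis=1)]
    out["margin"] = top2[:, 1] - top2[:, 0]
    return out


def evaluate(labels: pd.Series, preds: pd.DataFrame,
             categories: tuple[str, ...] | None = None) -> dict:
    """Overall and one-vs-rest accuracy metrics against known categories.

    Returns overall accuracy, a per-class frame (accuracy, sensitivity,
    specificity), and the confusion matrix (rows = true, columns =
    predicted).
    """
    if set(labels.index) != set(preds.index):
        raise ClassificationError("label and prediction ids do not match")
    labels = labels.reindex(preds.index)
    cats = list(categories or sorted(set(labels) | set(preds["assigned"])))
    y_true = labels.to_numpy()
    y_pred = preds["assigned"].to_numpy()
    cm = confusion_matrix(y_true, y_pred, labels=cats)
    total = cm.sum()
    per = {}
    for i, c in enumerate(cats):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        per[c] = {
            "accuracy": (tp + tn) / total,
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
            "n": int(tp + fn),
        }
    per_class = pd.DataFrame(per).T
    overall = float((y_true == y_pred).mean())
    macro = {
        "sensitivity": float(per_class["sensitivity"].mean()),
        "specificity": float(per_class["specificity"].mean()),
    }
    return {
        "overall_accuracy": overall,
        "per_class": per_class,
        "macro": macro,
        "confusion": pd.DataFrame(cm, index=cats, columns=cats),
    }
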
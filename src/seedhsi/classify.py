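"""Sample-set splitting, RBF-SVM training with grid search, and evaluation.

The discriminant model is a support vector machine with a radial basis
kernel, exp(-g ||x - x'||^2), trained on per-seed mean spectra at the
effective wavelengths.  The penalty coefficient c and kernel width g are
tuned over the grid 2^-8 .. 2^8 (integer exponents by default) by seeded
stratified cross-validated accuracy on the calibration set; multiclass
handling is one-vs-one voting.  Splitting is done at the image level so
that all seeds of an image share a fold, mirroring a protocol where whole
scenes are held out; one image per stratum is reserved for external
validation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

__all__ = [
    "SplitPlan",
    "DiscriminantModel",
    "EvalReport",
    "split_by_image",
    "grid_search_svm",
    "evaluate",
    "report_from_confusion",
    "predict_objects",
    "save_model",
    "load_model",
]

CLASS_CODES = (1, 2, 3)


@dataclasses.dataclass
class SplitPlan:
    """Disjoint image-id lists for calibration, prediction and external validation."""

    calibration_ids: list
    prediction_ids: list
    external_ids: list
    unit: str = "image"

    def __post_init__(self) -> None:
        pools = [set(self.calibration_ids), set(self.prediction_ids), set(self.external_ids)]
        total = sum(len(p) for p in pools)
        if len(set().union(*pools)) != total:
            raise ValueError("split pools must be disjoint")


def split_by_image(
    image_ids: Sequence,
    image_classes: Sequence[int] | None = None,
    ratio: tuple[int, int] = (2, 1),
    n_external: int = 1,
    rng_seed: int = 0,
) -> SplitPlan:
    """Seeded image-level split into calibration : prediction (+ external).

    With ``image_classes`` given (one class per image) the split is applied
    per class, and ``n_external`` images are reserved *per class*; without
    it, the split is over the pooled id list.  The calibration share is
    ``ratio[0] / (ratio[0] + ratio[1])`` of the non-external images,
    rounded down in favour of prediction only when exact division fails.
    """
    image_ids = list(image_ids)
    if len(set(image_ids)) != len(image_ids):
        raise ValueError("image ids must be unique")
    rng = np.random.default_rng(rng_seed)
    groups: dict[int | None, list] = {}
    if image_classes is None:
        groups[None] = image_ids
    else:
        if len(image_classes) != len(image_ids):
            raise ValueError("image_classes length must match image_ids")
        for iid, cls in zip(image_ids, image_classes):
            groups.setdefault(int(cls), []).append(iid)
    cal: list = []
    pred: list = []
    ext: list = []
    for cls in sorted(groups, key=lambda c: (c is None, c)):
        ids = list(groups[cls])
        if len(ids) < n_external + 3:
            raise ValueError(
                f"need at least {n_external + 3} images per stratum, got {len(ids)}"
            )
        perm = rng.permutation(len(ids))
        ids = [ids[i] for i in perm]
        ext.extend(ids[:n_external])
        rest = ids[n_external:]
        n_cal = round(len(rest) * ratio[0] / (ratio[0] + ratio[1]))
        n_cal = min(max(n_cal, 1), len(rest) - 1)
        cal.extend(rest[:n_cal])
        pred.extend(rest[n_cal:])
    return SplitPlan(calibration_ids=cal, prediction_ids=pred, external_ids=ext)


@dataclasses.dataclass
class DiscriminantModel:
    """Trained RBF-SVM plus its full grid-search record."""

    svc: SVC
    c: float
    g: float
    grid_record: pd.DataFrame  # columns: c, g, cv_accuracy
    feature_wavelengths_nm: np.ndarray | None = None
    train_X: np.ndarray | None = None
    train_y: np.ndarray | None = None


def grid_search_svm(
    X: np.ndarray,
    y: np.ndarray,
    c_exponents: Sequence[float] = tuple(range(-8, 9)),
    g_exponents: Sequence[float] = tuple(range(-8, 9)),
    cv_folds: int = 5,
    rng_seed: int = 0,
    *,
    refine: bool = False,
    feature_wavelengths_nm: np.ndarray | None = None,
) -> DiscriminantModel:
    """Train an RBF-SVM with (c, g) tuned by stratified cross-validation.

    The selection score is mean CV accuracy on (X, y); ties break to the
    smaller c, then the smaller g.  With ``refine`` a second pass searches
    quarter-octave steps around the best coarse cell.  The winning (c, g)
    is refitted on the full calibration data.  No feature scaling is
    applied.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("grid search needs at least two classes")
    folds = int(min(cv_folds, counts.min()))
    if folds < 2:
        raise ValueError("smallest class has a single sample; cannot cross-validate")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)

    def run_grid(c_exps, g_exps):
        rows = []
        for ce in c_exps:
            for ge in g_exps:
                c, g = 2.0**ce, 2.0**ge
                score = cross_val_score(
                    SVC(C=c, kernel="rbf", gamma=g), X, y, cv=skf, scoring="accuracy"
                ).mean()
                rows.append((c, g, score))
        return rows

    rows = run_grid(c_exponents, g_exponents)
    best = max(rows, key=lambda r: (r[2], -r[0], -r[1]))
    if refine:
        bc, bg = np.log2(best[0]), np.log2(best[1])
        step = 0.25
        fine_c = [bc + k * step for k in range(-3, 4)]
        fine_g = [bg + k * step for k in range(-3, 4)]
        rows += run_grid(fine_c, fine_g)
        best = max(rows, key=lambda r: (r[2], -r[0], -r[1]))
    record = pd.DataFrame(rows, columns=["c", "g", "cv_accuracy"])
    svc = SVC(C=best[0], kernel="rbf", gamma=best[1]).fit(X, y)
    return DiscriminantModel(
        svc=svc,
        c=float(best[0]),
        g=float(best[1]),
        grid_record=record,
        feature_wavelengths_nm=None
        if feature_wavelengths_nm is None
        else np.asarray(feature_wavelengths_nm, dtype=float),
        train_X=X,
        train_y=y,
    )


@dataclasses.dataclass
class EvalReport:
    """3x3 confusion matrix (rows = true class 1..3) with accuracies.

    Percentages are reported to one decimal, as accuracies of this kind are
    conventionally printed.
    """

    confusion: np.ndarray
    per_class_accuracy: np.ndarray  # fractions
    overall_accuracy: float  # fraction

    @property
    def per_class_percent(self) -> np.ndarray:
        return np.round(100.0 * self.per_class_accuracy, 1)

    @property
    def overall_percent(self) -> float:
        return float(np.round(100.0 * self.overall_accuracy, 1))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.confusion,
            index=[f"true_{c}" for c in CLASS_CODES],
            columns=[f"pred_{c}" for c in CLASS_CODES],
        )
        df["accuracy_pct"] = self.per_class_percent
        return df


def report_from_confusion(confusion: np.ndarray) -> EvalReport:
    """Build the evaluation report from a 3x3 count matrix."""
    confusion = np.asarray(confusion, dtype=np.int64)
    if confusion.shape != (3, 3) or (confusion < 0).any():
        raise ValueError("confusion must be a non-negative 3x3 count matrix")
    if confusion.sum() == 0:
        raise ValueError("confusion matrix is empty")
    row_sums = confusion.sum(axis=1)
    with np.errstate(invalid="ignore"):
        # a class absent from the evaluated set has undefined accuracy
        per_class = np.where(row_sums > 0, np.diag(confusion) / np.maximum(row_sums, 1), np.nan)
    overall = np.trace(confusion) / confusion.sum()
    return EvalReport(confusion=confusion, per_class_accuracy=per_class, overall_accuracy=overall)


def evaluate(model: DiscriminantModel, X: np.ndarray, y: np.ndarray) -> EvalReport:
    """Confusion matrix and accuracies of ``model`` on labelled spectra."""
    y = np.asarray(y, dtype=int)
    if not np.isin(y, CLASS_CODES).all():
        raise ValueError("class labels must be in {1, 2, 3}")
    pred = predict_objects(model, X)
    confusion = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(y, pred):
        confusion[t - 1, p - 1] += 1
    return report_from_confusion(confusion)


def predict_objects(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    """Predicted class per row; deterministic given the model."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.svc.n_features_in_:
        raise ValueError(
            f"feature count {X.shape[1]} does not match the model's "
            f"{model.svc.n_features_in_} training wavelengths"
        )
    return model.svc.predict(X).astype(int)


def save_model(model: DiscriminantModel, path: str | Path) -> Path:
    """Serialise the model to a self-contained JSON file (format v1).

    The file stores the winning (c, g), the grid record and the training
    data; loading refits the SVM, which reproduces the predictor exactly
    since libsvm training is deterministic.
    """
    if model.train_X is None or model.train_y is None:
        raise ValueError("model lacks stored training data; cannot serialise")
    payload = {
        "format": "seedhsi-svm-v1",
        "c": model.c,
        "g": model.g,
        "grid_record": model.grid_record.to_dict(orient="list"),
        "feature_wavelengths_nm": None
        if model.feature_wavelengths_nm is None
        else model.feature_wavelengths_nm.tolist(),
        "train_X": model.train_X.tolist(),
        "train_y": model.train_y.tolist(),
    }
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path


def load_model(path: str | Path) -> DiscriminantModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "seedhsi-svm-v1":
        raise ValueError("unrecognised model file format")
    X = np.asarray(payload["train_X"], dtype=float)
    y = np.asarray(payload["train_y"], dtype=int)
    svc = SVC(C=payload["c"], kernel="rbf", gamma=payload["g"]).fit(X, y)
    fw = payload.get("feature_wavelengths_nm")
    return DiscriminantModel(
        svc=svc,
        c=float(payload["c"]),
        g=float(payload["g"]),
        grid_record=pd.DataFrame(payload["grid_record"]),
        feature_wavelengths_nm=None if fw is None else np.asarray(fw, dtype=float),
        train_X=X,
        train_y=y,
    )
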
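"""Sector classification: nearest-neighbor mixing augmentation, SVM-RBF
training with probability calibration, 0–100 sector scoring, and held-out
evaluation.

Training data are labeled 500 ms waveforms (normal / abnormal).  The
augmentation step inflates the training set to a target count (default
2**16 = 65,536) by convex mixing: pick a random sample, find its nearest
same-class neighbor (exact KD-tree search), draw a mixing factor
alpha ~ N(0.5, 0.25^2) clipped to [0, 1], and emit alpha*x + (1-alpha)*nn(x)
with the source's label.  Features are standardized (z-score fitted on
training data) before the RBF-kernel SVM.

A sector's score is 100 * P(normal); scores below 50 call the sector
abnormal, and the 40–60 mid-gray band is flagged ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy.spatial import cKDTree
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES, ReferenceTemplate, extract_feature_matrix

__all__ = [
    "AugmentedSet",
    "SectorScore",
    "EvalMetrics",
    "Model",
    "augment_dataset",
    "train_classifier",
    "train_from_waveforms",
    "score_sectors",
    "evaluate",
    "save_model",
    "load_model",
    "DEFAULT_AUGMENT_TARGET",
]

DEFAULT_AUGMENT_TARGET = 2**16
LABELS = ("normal", "abnormal")


@dataclass
class AugmentedSet:
    samples: np.ndarray  # (target, d) waveforms or feature vectors
    labels: np.ndarray
    source_index: np.ndarray
    neighbor_index: np.ndarray
    mixing_factor: np.ndarray


@dataclass
class SectorScore:
    sector_id: int
    eye: str
    score: float  # 0..100, 100*P(normal)
    call: str  # "abnormal" iff score < 50
    ambiguous: bool  # mid-gray band, 40 <= score <= 60

    @property
    def gray_level(self) -> float:
        return self.score / 100.0


@dataclass
class EvalMetrics:
    accuracy: float
    sensitivity: float  # recall on "abnormal"
    specificity: float  # recall on "normal"
    auc: float  # NaN (flagged) on single-class evaluation sets
    auc_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def augment_dataset(
    samples: np.ndarray,
    labels: np.ndarray,
    target_count: int = DEFAULT_AUGMENT_TARGET,
    seed: int = 0,
) -> AugmentedSet:
    """Randomized nearest-neighbor mixing to ``target_count`` samples.

    Nearest neighbors are same-class and exclude the sample itself (exact
    KD-tree query).  Every emitted sample lies on the segment between its
    source and that neighbor; class proportions follow the uniform choice of
    sources.
    """
    X = np.asarray(samples, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    nn = np.empty(len(X), dtype=int)
    for lab in np.unique(y):
        idx = np.nonzero(y == lab)[0]
        if len(idx) < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 samples; cannot mix")
        tree = cKDTree(X[idx])
        _, j = tree.query(X[idx], k=2)
        nn[idx] = idx[j[:, 1]]
    src = rng.integers(0, len(X), size=target_count)
    alpha = np.clip(rng.normal(0.5, 0.25, size=target_count), 0.0, 1.0)
    mixed = alpha[:, None] * X[src] + (1.0 - alpha[:, None]) * X[nn[src]]
    return AugmentedSet(
        samples=mixed,
        labels=y[src],
        source_index=src,
        neighbor_index=nn[src],
        mixing_factor=alpha,
    )


@dataclass
class Model:
    """Trained sector classifier bundle: standardization + calibrated
    SVM-RBF, the reference template used by the feature extractor, the
    feature schema, and the training seed."""

    pipeline: Pipeline
    reference: ReferenceTemplate
    feature_names: tuple = FEATURE_NAMES
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0
    cv_scores: np.ndarray | None = None

    @property
    def normal_column(self) -> int:
        return int(np.nonzero(self.pipeline.classes_ == "normal")[0][0])


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    reference: ReferenceTemplate | None = None,
    C: float = 1.0,
    gamma="scale",
    seed: int = 0,
    cv_folds: int = 0,
) -> Model:
    """Fit the standardized SVM-RBF with internal probability calibration.

    ``cv_folds > 0`` additionally records per-fold cross-validation
    accuracies on the training set.  Deterministic for a fixed seed.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    svm = CalibratedClassifierCV(
        SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed), ensemble=False, cv=5
    )
    pipe = Pipeline([("scale", StandardScaler()), ("svm", svm)])
    X = np.asarray(features, dtype=float)
    if X.shape[1] != len(FEATURE_NAMES) and reference is None:
        raise ValueError("feature matrix width does not match the feature schema")
    cv_scores = None
    if cv_folds and cv_folds > 1:
        cv_scores = cross_val_score(pipe, X, y, cv=cv_folds)
    pipe.fit(X, y)
    return Model(
        pipeline=pipe,
        reference=reference if reference is not None else ReferenceTemplate(np.zeros(200), "unset"),
        feature_names=tuple(FEATURE_NAMES[: X.shape[1]]) if X.shape[1] <= len(FEATURE_NAMES) else tuple(f"f{i}" for i in range(X.shape[1])),
        hyperparams={"C": C, "gamma": gamma, "kernel": "rbf"},
        seed=seed,
        cv_scores=cv_scores,
    )


def train_from_waveforms(
    waveforms: np.ndarray,
    labels: np.ndarray,
    augment_target: int = DEFAULT_AUGMENT_TARGET,
    seed: int = 0,
    cv_folds: int = 0,
) -> Model:
    """Full training route: augment raw 500 ms waveforms in signal space,
    build the reference template from the normal class, extract the
    19-feature matrix, and fit the classifier."""
    y = np.asarray(labels)
    reference = ReferenceTemplate.from_normals(np.asarray(waveforms)[y == "normal"])
    if augment_target and augment_target > len(y):
        aug = augment_dataset(waveforms, y, target_count=augment_target, seed=seed)
        Xw, ya = aug.samples, aug.labels
    else:
        Xw, ya = np.asarray(waveforms, dtype=float), y
    F = extract_feature_matrix(Xw, reference)
    return train_classifier(F, ya, reference=reference, seed=seed, cv_folds=cv_folds)


def score_sectors(model: Model, features: np.ndarray, sector_ids=None, eyes=None) -> list[SectorScore]:
    """Score sectors 0–100 as 100 * P(normal); call abnormal iff score < 50
    (a score of exactly 50 is normal); 40–60 flags ambiguous."""
    X = np.asarray(features, dtype=float)
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"feature schema mismatch: model expects {len(model.feature_names)} features, got {X.shape[1]}"
        )
    p_normal = model.pipeline.predict_proba(X)[:, model.normal_column]
    out = []
    for i, p in enumerate(p_normal):
        score = 100.0 * float(p)
        out.append(
            SectorScore(
                sector_id=int(sector_ids[i]) if sector_ids is not None else i + 1,
                eye=str(eyes[i]) if eyes is not None else "L",
                score=score,
                call="abnormal" if score < 50.0 else "normal",
                ambiguous=40.0 <= score <= 60.0,
            )
        )
    return out


def evaluate(model: Model, features: np.ndarray, labels: np.ndarray) -> EvalMetrics:
    """Accuracy, sensitivity (recall on abnormal), specificity (recall on
    normal) and AUC of the model on a held-out labeled set."""
    y = np.asarray(labels)
    X = np.asarray(features, dtype=float)
    pred = model.pipeline.predict(X)
    acc = float((pred == y).mean())
    ab = y == "abnormal"
    no = y == "normal"
    sens = float((pred[ab] == "abnormal").mean()) if ab.any() else float("nan")
    spec = float((pred[no] == "normal").mean()) if no.any() else float("nan")
    if ab.any() and no.any():
        p_abnormal = model.pipeline.predict_proba(X)[:, 1 - model.normal_column]
        auc = float(roc_auc_score(ab.astype(int), p_abnormal))
        defined = True
    else:
        auc, defined = float("nan"), False
    return EvalMetrics(acc, sens, spec, auc, auc_defined=defined)


def save_model(model: Model, path) -> None:
    """Persist the full bundle (SVM, standardization, template, schema,
    seeds) as a single file."""
    joblib.dump(
        {
            "pipeline": model.pipeline,
            "reference_waveform": model.reference.waveform,
            "reference_provenance": model.reference.provenance,
            "feature_names": model.feature_names,
            "hyperparams": model.hyperparams,
            "seed": model.seed,
            "cv_scores": model.cv_scores,
        },
        path,
    )


def load_model(path) -> Model:
    d = joblib.load(path)
    return Model(
        pipeline=d["pipeline"],
        reference=ReferenceTemplate(d["reference_waveform"], d["reference_provenance"]),
        feature_names=tuple(d["feature_names"]),
        hyperparams=d["hyperparams"],
        seed=d["seed"],
        cv_scores=d["cv_scores"],
    )
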
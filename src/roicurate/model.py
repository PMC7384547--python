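"""Train, cross-validate, persist and apply include/exclude classifiers.

The model space mirrors the conventional baselines for this task: decision
trees and k-nearest neighbors, each optionally behind a PCA projection, with
out-of-the-box hyperparameters (KNN k=5; unrestricted tree depth, minimum
leaf 1).  Model selection uses stratified k-fold cross-validation (default
10 folds) scored on F1 — or F-beta when false negatives and false positives
deserve unequal weight.  An ``external_automl`` family is a plug-in seam:
any engine honoring the same dataset-in / estimator-out contract can be
registered, but no search ships here.

Per-ROI confidence is the predicted class's probability (leaf class
fraction for trees, neighbor vote fraction for KNN); :func:`triage` routes
low-confidence predictions to a human review queue, which is what makes the
curation semi-automated rather than blind.
"""

from __future__ import annotations

import json
import pickle
import zipfile
from dataclasses import asdict, dataclass, field
from typing import Callable, Sequence

import numpy as np
import sklearn
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.metrics import fbeta_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.tree import DecisionTreeClassifier

from .errors import (
    BundleFormatError,
    PluginError,
    ShapeMismatchError,
    SpecError,
    StratificationError,
)
from .features import (
    INT_TO_LABEL,
    FeatureVector,
    LabeledDataset,
    PreprocessSpec,
    build_feature_vector,
)
from .io_cnmfe import ROI, ROICollection

_BUNDLE_FORMAT_VERSION = 1

FAMILIES = ("decision_tree", "knn", "external_automl")

_AUTOML_BACKENDS: dict[str, Callable[["ClassifierSpec"], BaseEstimator]] = {}


def register_automl_backend(name: str, factory: Callable[["ClassifierSpec"], BaseEstimator]) -> None:
    """Register an external AutoML engine.

    ``factory(spec)`` must return a scikit-learn-compatible estimator with
    ``fit``/``predict``/``predict_proba``.  Selecting
    ``family="external_automl"`` with ``hyperparameters={"backend": name}``
    then routes training through it — same dataset in, same bundle out.
    """
    _AUTOML_BACKENDS[name] = factory


@dataclass(frozen=True)
class ClassifierSpec:
    """Everything needed to reproduce one classifier fit.

    ``objective`` is the CV selection metric: ``f1`` or ``f_beta`` with the
    given ``beta`` (beta > 1 weights recall — fewer lost neurons — over
    precision).
    """

    family: str = "decision_tree"
    use_pca: bool = False
    n_components: int = 50
    hyperparameters: dict = field(default_factory=dict)
    objective: str = "f1"
    beta: float = 1.0
    cv_folds: int = 10
    cv_repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise SpecError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.objective not in ("f1", "f_beta"):
            raise SpecError(f"unknown objective {self.objective!r}")
        if self.beta <= 0:
            raise SpecError(f"beta must be positive, got {self.beta}")
        if self.cv_folds < 2:
            raise SpecError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.cv_repeats < 1:
            raise SpecError(f"cv_repeats must be >= 1, got {self.cv_repeats}")

    @property
    def effective_beta(self) -> float:
        return 1.0 if self.objective == "f1" else self.beta


@dataclass
class Prediction:
    """One ROI's predicted label with the classifier's certainty in it.

    ``confidence`` is the probability assigned to the *predicted* class, so
    it is always >= 0.5 for a two-class model.
    """

    roi_id: str
    label: str
    confidence: float


@dataclass(frozen=True)
class TriagePolicy:
    """Confidence threshold below which predictions go to human review."""

    auto_threshold: float = 0.9

    def __post_init__(self) -> None:
        if not 0.5 < self.auto_threshold <= 1.0:
            raise ValueError(
                f"auto_threshold must be in (0.5, 1], got {self.auto_threshold}"
            )


@dataclass
class TriageResult:
    auto_include: list[Prediction] = field(default_factory=list)
    auto_exclude: list[Prediction] = field(default_factory=list)
    review_queue: list[Prediction] = field(default_factory=list)


@dataclass
class ClassifierBundle:
    """A fitted pipeline plus the recipe that produced it.

    ``input_dim`` is the raw feature dimension the pipeline accepts;
    ``feature_dim`` is the dimension the estimator actually sees
    (``n_components`` when PCA is on).  ``created`` is an optional ISO
    timestamp — left unset by default so identical fits serialize to
    identical bytes.
    """

    spec: ClassifierSpec
    preprocess: PreprocessSpec
    pipeline: Pipeline
    cv_report: dict
    input_dim: int
    feature_dim: int
    modality: str = "combined"
    created: str | None = None


def _make_estimator(spec: ClassifierSpec) -> BaseEstimator:
    hp = dict(spec.hyperparameters)
    if spec.family == "decision_tree":
        hp.setdefault("random_state", spec.seed)
        return DecisionTreeClassifier(**hp)
    if spec.family == "knn":
        hp.pop("backend", None)
        hp.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**hp)
    # external_automl
    backend = spec.hyperparameters.get("backend")
    if backend is None or backend not in _AUTOML_BACKENDS:
        raise PluginError(
            "family='external_automl' requires hyperparameters={'backend': <name>} "
            f"with a backend registered via register_automl_backend; "
            f"registered: {sorted(_AUTOML_BACKENDS)}"
        )
    return _AUTOML_BACKENDS[backend](spec)


def make_pipeline(spec: ClassifierSpec) -> Pipeline:
    """Build the (optional PCA ->) estimator pipeline for a spec."""
    steps = []
    if spec.use_pca:
        steps.append(("pca", PCA(n_components=spec.n_components, random_state=spec.seed)))
    steps.append(("clf", _make_estimator(spec)))
    return Pipeline(steps)


def _check_cv_feasible(y: np.ndarray, spec: ClassifierSpec) -> None:
    counts = np.bincount(y, minlength=2)
    if counts.min() < spec.cv_folds:
        raise StratificationError(
            f"class counts include/exclude = {counts[1]}/{counts[0]} cannot fill "
            f"{spec.cv_folds} stratified folds"
        )


def _score(estimator, X: np.ndarray, y: np.ndarray, beta: float) -> float:
    return float(fbeta_score(y, estimator.predict(X), beta=beta, zero_division=0))


def cross_validate(dataset: LabeledDataset, spec: ClassifierSpec) -> np.ndarray:
    """Stratified k-fold CV on the training rows; returns folds x repeats scores.

    Folds preserve the global include/exclude proportion to within one
    sample; the fold assignment is a deterministic function of the seed.
    """
    X, y = dataset.X_train, dataset.y_train
    _check_cv_feasible(y, spec)
    cv = RepeatedStratifiedKFold(
        n_splits=spec.cv_folds, n_repeats=spec.cv_repeats, random_state=spec.seed
    )
    beta = spec.effective_beta
    scores = []
    for train_idx, val_idx in cv.split(X, y):
        pipe = make_pipeline(spec)
        pipe.fit(X[train_idx], y[train_idx])
        scores.append(_score(pipe, X[val_idx], y[val_idx], beta))
    return np.array(scores)


def train(
    dataset: LabeledDataset,
    spec: ClassifierSpec,
    run_cv: bool = True,
    created: str | None = None,
) -> ClassifierBundle:
    """Cross-validate, then fit on all training rows.

    Any fitted transformation (PCA) sees training rows only — the held-out
    test rows never leak into preprocessing statistics.
    """
    X, y = dataset.X_train, dataset.y_train
    if run_cv:
        _check_cv_feasible(y, spec)
        scores = cross_validate(dataset, spec)
        cv_report = {
            "objective": spec.objective,
            "beta": spec.effective_beta,
            "scores": [float(s) for s in scores],
            "mean": float(scores.mean()),
            "sd": float(scores.std(ddof=1)) if scores.size > 1 else 0.0,
        }
    else:
        cv_report = {"objective": spec.objective, "beta": spec.effective_beta, "scores": []}
    pipeline = make_pipeline(spec)
    pipeline.fit(X, y)
    input_dim = X.shape[1]
    feature_dim = spec.n_components if spec.use_pca else input_dim
    return ClassifierBundle(
        spec=spec,
        preprocess=dataset.preprocess,
        pipeline=pipeline,
        cv_report=cv_report,
        input_dim=input_dim,
        feature_dim=feature_dim,
        modality=dataset.modality,
        created=created,
    )


def _features_from_inputs(bundle: ClassifierBundle, inputs) -> tuple[np.ndarray, list[str]]:
    spec = bundle.preprocess
    if isinstance(inputs, ROICollection):
        inputs = list(inputs)
    if isinstance(inputs, LabeledDataset):
        return inputs.features, list(inputs.ids)
    if isinstance(inputs, np.ndarray):
        X = np.atleast_2d(np.asarray(inputs, dtype=float))
        return X, [f"row{i}" for i in range(X.shape[0])]
    if isinstance(inputs, Sequence):
        if len(inputs) == 0:
            return np.empty((0, bundle.input_dim)), []
        if isinstance(inputs[0], ROI):
            vecs = [build_feature_vector(r, spec) for r in inputs]
        elif isinstance(inputs[0], FeatureVector):
            vecs = list(inputs)
        else:
            X = np.atleast_2d(np.asarray(inputs, dtype=float))
            return X, [f"row{i}" for i in range(X.shape[0])]
        X = np.stack([v.values for v in vecs])
        if bundle.modality == "spatial":
            X = X[:, : spec.n_spatial]
        elif bundle.modality == "trace":
            X = X[:, spec.n_spatial :]
        return X, [v.roi_id for v in vecs]
    raise TypeError(f"cannot predict from inputs of type {type(inputs).__name__}")


def predict(bundle: ClassifierBundle, inputs) -> list[Prediction]:
    """Apply a trained bundle to ROIs, feature vectors or a raw matrix.

    Raw :class:`ROI` inputs are run through the bundle's stored
    preprocessing recipe first, so train- and predict-time features always
    agree.
    """
    X, ids = _features_from_inputs(bundle, inputs)
    if len(ids) == 0:
        return []
    if X.shape[1] != bundle.input_dim:
        raise ShapeMismatchError(
            f"feature dimension mismatch: bundle expects {bundle.input_dim}, got {X.shape[1]}"
        )
    proba = bundle.pipeline.predict_proba(X)
    classes = bundle.pipeline.classes_
    best = np.argmax(proba, axis=1)
    return [
        Prediction(
            roi_id=ids[i],
            label=INT_TO_LABEL[int(classes[best[i]])],
            confidence=float(proba[i, best[i]]),
        )
        for i in range(len(ids))
    ]


def triage(predictions: Sequence[Prediction], policy: TriagePolicy) -> TriageResult:
    """Partition predictions into auto-include / auto-exclude / review queue.

    A prediction is queued for human review iff its confidence is strictly
    below ``policy.auto_threshold``; input order is preserved within lists.
    """
    result = TriageResult()
    for p in predictions:
        if p.confidence < policy.auto_threshold:
            result.review_queue.append(p)
        elif p.label == "include":
            result.auto_include.append(p)
        else:
            result.auto_exclude.append(p)
    return result


def save_bundle(bundle: ClassifierBundle, path: str) -> None:
    """Persist a bundle as a single zip archive: metadata JSON + model blob.

    Archive member timestamps are fixed at the zip epoch, so saving the same
    fit twice produces byte-identical files.
    """
    meta = {
        "format_version": _BUNDLE_FORMAT_VERSION,
        "spec": asdict(bundle.spec),
        "preprocess": asdict(bundle.preprocess),
        "cv_report": bundle.cv_report,
        "input_dim": bundle.input_dim,
        "feature_dim": bundle.feature_dim,
        "modality": bundle.modality,
        "created": bundle.created,
        "sklearn_version": sklearn.__version__,
    }
    blob = pickle.dumps(bundle.pipeline, protocol=5)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as z:
        for name, data in (
            ("metadata.json", json.dumps(meta, sort_keys=True, indent=1).encode()),
            ("model.pkl", blob),
        ):
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o644 << 16
            z.writestr(info, data)


def load_bundle(path: str) -> ClassifierBundle:
    """Load a bundle written by :func:`save_bundle`.

    Raises :class:`BundleFormatError` on truncated archives or a format
    version this library does not understand.
    """
    try:
        with zipfile.ZipFile(path, "r") as z:
            meta = json.loads(z.read("metadata.json"))
            blob = z.read("model.pkl")
    except (zipfile.BadZipFile, KeyError, OSError) as exc:
        raise BundleFormatError(f"cannot read bundle {path!r}: {exc}") from exc
    version = meta.get("format_version")
    if version != _BUNDLE_FORMAT_VERSION:
        raise BundleFormatError(
            f"bundle format version {version!r} is incompatible with this library "
            f"(expects {_BUNDLE_FORMAT_VERSION})"
        )
    pipeline = pickle.loads(blob)
    return ClassifierBundle(
        spec=ClassifierSpec(**meta["spec"]),
        preprocess=PreprocessSpec(**meta["preprocess"]),
        pipeline=pipeline,
        cv_report=meta["cv_report"],
        input_dim=int(meta["input_dim"]),
        feature_dim=int(meta["feature_dim"]),
        modality=meta.get("modality", "combined"),
        created=meta.get("created"),
    )
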
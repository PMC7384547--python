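"""ROI -> feature-vector preprocessing and dataset assembly.

Each ROI is reduced to a fixed-length vector: the spatial footprint is
cropped to a ``crop_size x crop_size`` window centered on its peak-intensity
pixel (the footprint's location in the FOV carries no curation signal, its
shape and size do), flattened row-major, and the first ``trace_len`` frames
of the min-max-normalized calcium trace are concatenated to the end.  With
the defaults (80 px crop, 500 frames) the vector has 6400 + 500 = 6900
entries.  Datasets are split into stratified train/test partitions so the
include/exclude mix is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from sklearn.model_selection import train_test_split

from .errors import (
    DegenerateInputError,
    LabelError,
    RoicurateError,
    ShapeMismatchError,
    StratificationError,
)
from .io_cnmfe import ROI, ROICollection

MODALITIES = ("combined", "spatial", "trace")

LABEL_TO_INT = {"exclude": 0, "include": 1}
INT_TO_LABEL = {0: "exclude", 1: "include"}


@dataclass(frozen=True)
class PreprocessSpec:
    """Preprocessing recipe applied identically at train and predict time.

    Parameters
    ----------
    crop_size : int
        Side of the peak-centered footprint crop, pixels (default 80).
    trace_len : int
        Number of frames kept from each trace (default 500, i.e. 100 s at
        5 fps).  Shorter traces are right-padded with ``pad_value``.
    trace_norm : {"minmax", "none"}
        Per-trace normalization; ``minmax`` maps each trace to [0, 1]
        (constant traces to all-zeros).
    pad_value : float
        Fill value for out-of-FOV crop regions and short-trace padding.
    """

    crop_size: int = 80
    trace_len: int = 500
    trace_norm: str = "minmax"
    pad_value: float = 0.0

    def __post_init__(self) -> None:
        if self.crop_size < 1 or self.trace_len < 1:
            raise ValueError("crop_size and trace_len must be >= 1")
        if self.trace_norm not in ("minmax", "none"):
            raise ValueError(f"unknown trace_norm {self.trace_norm!r}")

    @property
    def n_spatial(self) -> int:
        return self.crop_size * self.crop_size

    def feature_dim(self, modality: str = "combined") -> int:
        if modality == "combined":
            return self.n_spatial + self.trace_len
        if modality == "spatial":
            return self.n_spatial
        if modality == "trace":
            return self.trace_len
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")


@dataclass
class FeatureVector:
    """Flattened footprint crop followed by the standardized trace."""

    values: np.ndarray
    roi_id: str


@dataclass
class LabeledDataset:
    """Feature matrix with labels, ids, split tags and provenance.

    ``labels`` are binary: 1 = include, 0 = exclude.  ``split`` tags each
    row ``train`` or ``test``; the split is stratified and a deterministic
    function of the seed it was built with.
    """

    features: np.ndarray
    labels: np.ndarray
    ids: list[str]
    split: np.ndarray
    provenance: list[str] = field(default_factory=list)
    modality: str = "combined"
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.split = np.asarray(self.split, dtype=object)
        n = self.features.shape[0]
        if not (len(self.labels) == len(self.ids) == len(self.split) == n):
            raise ShapeMismatchError("features, labels, ids and split lengths differ")
        if not self.provenance:
            self.provenance = [""] * n

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def _mask(self, tag: str) -> np.ndarray:
        return self.split == tag

    @property
    def X_train(self) -> np.ndarray:
        return self.features[self._mask("train")]

    @property
    def y_train(self) -> np.ndarray:
        return self.labels[self._mask("train")]

    @property
    def X_test(self) -> np.ndarray:
        return self.features[self._mask("test")]

    @property
    def y_test(self) -> np.ndarray:
        return self.labels[self._mask("test")]

    @property
    def ids_test(self) -> list[str]:
        return [i for i, s in zip(self.ids, self.split) if s == "test"]


def crop_footprint(
    footprint: np.ndarray, crop_size: int, pad_value: float = 0.0
) -> np.ndarray:
    """Crop a footprint to ``crop_size x crop_size`` centered on its peak.

    The global maximum lands at index ``(crop_size // 2, crop_size // 2)``;
    window regions outside the FOV are filled with ``pad_value``.  Ties for
    the peak break to the smallest row, then smallest column.
    """
    fp = np.asarray(footprint, dtype=float)
    if fp.ndim != 2:
        raise ShapeMismatchError(f"footprint must be 2-D, got shape {fp.shape}")
    if not np.any(fp > 0):
        raise DegenerateInputError("cannot crop an all-zero footprint (no peak)")
    # np.argmax on the raveled row-major array returns the first maximum,
    # which is exactly the smallest-row-then-column tie break.
    pr, pc = np.unravel_index(int(np.argmax(fp)), fp.shape)
    half = crop_size // 2
    out = np.full((crop_size, crop_size), float(pad_value))
    r0, c0 = pr - half, pc - half
    rs, re = max(r0, 0), min(r0 + crop_size, fp.shape[0])
    cs, ce = max(c0, 0), min(c0 + crop_size, fp.shape[1])
    out[rs - r0 : re - r0, cs - c0 : ce - c0] = fp[rs:re, cs:ce]
    return out


def standardize_trace(
    trace: np.ndarray,
    trace_len: int,
    trace_norm: str = "minmax",
    pad_value: float = 0.0,
) -> np.ndarray:
    """Crop/pad a trace to ``trace_len`` frames, then normalize.

    The first ``trace_len`` frames are kept; shorter traces are right-padded
    with ``pad_value`` before normalization.  Under ``minmax`` the output
    spans [0, 1]; constant traces map to all-zeros.
    """
    t = np.asarray(trace, dtype=float).ravel()
    if t.size >= trace_len:
        out = t[:trace_len].copy()
    else:
        out = np.full(trace_len, float(pad_value))
        out[: t.size] = t
    if trace_norm == "none":
        return out
    if trace_norm != "minmax":
        raise ValueError(f"unknown trace_norm {trace_norm!r}")
    lo, hi = out.min(), out.max()
    if hi > lo:
        return (out - lo) / (hi - lo)
    return np.zeros_like(out)


def build_feature_vector(roi: ROI, spec: PreprocessSpec) -> FeatureVector:
    """Assemble one ROI's combined feature vector (footprint block then trace block)."""
    crop = crop_footprint(roi.footprint, spec.crop_size, spec.pad_value)
    trace = standardize_trace(roi.trace, spec.trace_len, spec.trace_norm, spec.pad_value)
    return FeatureVector(values=np.concatenate([crop.ravel(), trace]), roi_id=roi.id)


def assemble_dataset(
    collection: ROICollection,
    spec: PreprocessSpec,
    test_fraction: float = 0.2,
    seed: int = 0,
    modality: str = "combined",
) -> LabeledDataset:
    """Preprocess every ROI and produce a stratified train/test dataset.

    ``modality`` restricts the feature block: ``spatial`` keeps only the
    flattened footprint crop, ``trace`` only the standardized trace,
    ``combined`` (default) both.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    unlabeled = [r.id for r in collection if r.label == "unlabeled"]
    if unlabeled:
        raise LabelError(f"unlabeled ROIs present: {unlabeled}")

    vectors = [build_feature_vector(r, spec) for r in collection]
    X = np.stack([v.values for v in vectors])
    if modality == "spatial":
        X = X[:, : spec.n_spatial]
    elif modality == "trace":
        X = X[:, spec.n_spatial :]
    y = np.array([LABEL_TO_INT[r.label] for r in collection], dtype=int)

    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise StratificationError(
            f"cannot stratify: class counts include/exclude = {counts[1]}/{counts[0]} "
            "(each class needs >= 2 members)"
        )
    idx = np.arange(len(collection))
    _, idx_test = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed, shuffle=True
    )
    split = np.array(["train"] * len(collection), dtype=object)
    split[idx_test] = "test"
    return LabeledDataset(
        features=X,
        labels=y,
        ids=collection.ids,
        split=split,
        provenance=[r.source for r in collection],
        modality=modality,
        preprocess=spec,
    )


def save_feature_matrix(dataset: LabeledDataset, path: str) -> None:
    """Export a dataset as HDF5 (datasets ``X``, ``y``, ``ids``, ``split``).

    This is the interoperability surface for external AutoML engines.
    """
    str_dt = h5py.string_dtype(encoding="utf-8")
    try:
        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=dataset.features)
            f.create_dataset("y", data=dataset.labels)
            f.create_dataset("ids", data=np.array(dataset.ids, dtype=object), dtype=str_dt)
            f.create_dataset(
                "split", data=np.array(list(dataset.split), dtype=object), dtype=str_dt
            )
            f.attrs["modality"] = dataset.modality
            f.attrs["crop_size"] = dataset.preprocess.crop_size
            f.attrs["trace_len"] = dataset.preprocess.trace_len
            f.attrs["trace_norm"] = dataset.preprocess.trace_norm
            f.attrs["pad_value"] = dataset.preprocess.pad_value
    except OSError as exc:
        raise RoicurateError(f"cannot write features to {path!r}: {exc}") from exc


def load_feature_matrix(path: str) -> LabeledDataset:
    """Load a dataset written by :func:`save_feature_matrix`."""
    with h5py.File(path, "r") as f:
        for key in ("X", "y", "ids", "split"):
            if key not in f:
                raise RoicurateError(f"feature file {path!r} lacks dataset {key!r}")
        X = f["X"][()]
        y = f["y"][()]
        ids = [v.decode() if isinstance(v, bytes) else str(v) for v in f["ids"][()]]
        split = [v.decode() if isinstance(v, bytes) else str(v) for v in f["split"][()]]
        spec = PreprocessSpec(
            crop_size=int(f.attrs.get("crop_size", 80)),
            trace_len=int(f.attrs.get("trace_len", 500)),
            trace_norm=str(f.attrs.get("trace_norm", "minmax")),
            pad_value=float(f.attrs.get("pad_value", 0.0)),
        )
        modality = str(f.attrs.get("modality", "combined"))
    return LabeledDataset(
        features=X,
        labels=y,
        ids=ids,
        split=np.array(split, dtype=object),
        modality=modality,
        preprocess=spec,
    )
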
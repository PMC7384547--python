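"""Read and write CNMF-E source-extraction outputs.

CNMF-E produces two matrices per recording: the spatial footprints ``A``
(pixels x K, each column one putative neuron's pixel weights) and the
calcium traces ``C`` (K x T, one fluorescence time series per ROI).  This
module maps those containers — plain HDF5 or MATLAB v7.3 ``.mat`` files,
which are HDF5 underneath — onto the in-memory :class:`ROI` /
:class:`ROICollection` model used by the rest of the package, and writes
collections back out losslessly.

Conventions: field-of-view images are row-major (row = y, column = x) with
0-based indexing.  Matrix orientation on disk is resolved by matching the
ROI count K between the footprint and trace matrices; genuinely ambiguous
(square) cases require an explicit flag rather than a guess.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    LabelError,
    MissingDatasetError,
    OrientationError,
    RoicurateError,
    ShapeMismatchError,
)

VALID_LABELS = ("include", "exclude", "unlabeled")

_DIALECTS = ("matlab_cnmfe", "caiman_hdf5", "generic_hdf5")


@dataclass(frozen=True)
class FOVGeometry:
    """Field-of-view geometry shared by every ROI in a collection.

    Parameters
    ----------
    height, width : int
        FOV size in pixels.
    n_frames : int
        Recording length in frames.
    frame_rate : float
        Acquisition rate in Hz.  Default 5, the typical miniscope rate at
        which 500 frames correspond to 100 s of recording.
    """

    height: int
    width: int
    n_frames: int
    frame_rate: float = 5.0

    def __post_init__(self) -> None:
        for name in ("height", "width", "n_frames"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")

    @property
    def n_pixels(self) -> int:
        return self.height * self.width


@dataclass
class ROI:
    """One extracted unit: a spatial footprint plus a calcium trace.

    ``label`` is the curation state: ``include`` (neuronal), ``exclude``
    (artifact) or ``unlabeled``.  An all-zero footprint is retained (flagged
    via :attr:`footprint_is_empty`) rather than rejected, so that dropping
    bad units happens in exactly one place downstream.
    """

    id: str
    footprint: np.ndarray
    trace: np.ndarray
    label: str = "unlabeled"
    source: str = ""

    def __post_init__(self) -> None:
        self.footprint = np.asarray(self.footprint, dtype=float)
        self.trace = np.asarray(self.trace, dtype=float).ravel()
        if self.footprint.ndim != 2:
            raise ShapeMismatchError(
                f"footprint must be 2-D (height x width), got shape {self.footprint.shape}"
            )
        if self.label not in VALID_LABELS:
            raise LabelError(f"unknown label {self.label!r}; expected one of {VALID_LABELS}")

    @property
    def footprint_is_empty(self) -> bool:
        """True when the footprint has no strictly positive pixel."""
        return not bool(np.any(self.footprint > 0))


@dataclass
class ROICollection:
    """An ordered set of ROIs sharing one field-of-view geometry."""

    geometry: FOVGeometry
    rois: list[ROI] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.rois]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate ROI ids in collection: {dupes}")
        g = self.geometry
        for r in self.rois:
            if r.footprint.shape != (g.height, g.width):
                raise ShapeMismatchError(
                    f"ROI {r.id}: footprint shape {r.footprint.shape} != FOV "
                    f"({g.height}, {g.width})"
                )
            if r.trace.size != g.n_frames:
                raise ShapeMismatchError(
                    f"ROI {r.id}: trace length {r.trace.size} != n_frames {g.n_frames}"
                )

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rois]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rois]


def _get_dataset(f: h5py.File, key: str) -> np.ndarray:
    node = f.get(key)
    if node is None or not isinstance(node, h5py.Dataset):
        raise MissingDatasetError(f"dataset {key!r} not found in {f.filename}")
    return np.asarray(node[()])


def _orient_footprints(
    A: np.ndarray, n_pixels: int, footprint_orientation: str
) -> np.ndarray:
    """Return footprints as (pixels x K)."""
    if A.ndim == 3:
        h_w_k = A.reshape(A.shape[0] * A.shape[1], A.shape[2])
        return h_w_k
    if A.ndim != 2:
        raise ShapeMismatchError(f"footprint matrix must be 2-D or 3-D, got {A.ndim}-D")
    r, c = A.shape
    if r == n_pixels and c == n_pixels:
        if footprint_orientation == "pixels_by_rois":
            return A
        if footprint_orientation == "rois_by_pixels":
            return A.T
        raise OrientationError(
            f"footprint matrix is square ({r} x {c}); pass "
            "footprint_orientation='pixels_by_rois' or 'rois_by_pixels'"
        )
    if r == n_pixels:
        return A
    if c == n_pixels:
        return A.T
    raise ShapeMismatchError(
        f"neither footprint dimension {A.shape} matches the FOV pixel count {n_pixels}"
    )


def _orient_traces(C: np.ndarray, K: int, trace_orientation: str) -> np.ndarray:
    """Return traces as (K x T)."""
    if C.ndim != 2:
        raise ShapeMismatchError(f"trace matrix must be 2-D, got {C.ndim}-D")
    r, c = C.shape
    if r == K and c == K:
        if trace_orientation == "rois_by_frames":
            return C
        if trace_orientation == "frames_by_rois":
            return C.T
        raise OrientationError(
            f"trace matrix is square ({r} x {c}); pass "
            "trace_orientation='rois_by_frames' or 'frames_by_rois'"
        )
    if r == K:
        return C
    if c == K:
        return C.T
    raise ShapeMismatchError(
        f"trace matrix shape {C.shape} has no axis matching K={K} ROIs"
    )


def _decode(values) -> list[str]:
    return [v.decode() if isinstance(v, bytes) else str(v) for v in values]


def load_cnmfe_output(
    path: str,
    dialect: str = "generic_hdf5",
    footprint_key: str = "A",
    trace_key: str = "C",
    fov_shape: tuple[int, int] | None = None,
    footprint_orientation: str = "auto",
    trace_orientation: str = "auto",
) -> ROICollection:
    """Load a CNMF-E output container into an :class:`ROICollection`.

    Parameters
    ----------
    path : str
        HDF5 (or MAT v7.3) file.
    dialect : {"matlab_cnmfe", "caiman_hdf5", "generic_hdf5"}
        ``matlab_cnmfe`` accounts for MATLAB's column-major storage of 3-D
        arrays; the other dialects differ only in their conventional dataset
        keys and are otherwise identical readers.
    footprint_key, trace_key : str
        Dataset paths inside the container (slash-separated for groups).
    fov_shape : (height, width), optional
        Required when the footprint matrix is stored flat (pixels x K) and
        the file carries no geometry attributes.
    footprint_orientation, trace_orientation : str
        Disambiguators for square matrices; ``"auto"`` resolves orientation
        by matching the ROI count K across the two matrices.

    Notes
    -----
    All-zero footprints are loaded and flagged with a warning, never
    silently dropped.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    with h5py.File(path, "r") as f:
        A = _get_dataset(f, footprint_key)
        C = _get_dataset(f, trace_key)
        attrs = dict(f.attrs)
        ids = _decode(f["ids"][()]) if "ids" in f else None
        labels = _decode(f["labels"][()]) if "labels" in f else None

    if A.ndim == 3 and dialect == "matlab_cnmfe":
        # MAT v7.3 stores MATLAB (h, w, K) arrays transposed as (K, w, h).
        A = A.transpose(2, 1, 0)

    if "height" in attrs and "width" in attrs:
        h, w = int(attrs["height"]), int(attrs["width"])
    elif fov_shape is not None:
        h, w = int(fov_shape[0]), int(fov_shape[1])
    elif A.ndim == 3:
        h, w = A.shape[0], A.shape[1]
    else:
        raise RoicurateError(
            "cannot infer field-of-view shape: footprint matrix is flat and the "
            "file has no height/width attributes; pass fov_shape=(height, width)"
        )

    A2 = _orient_footprints(A, h * w, footprint_orientation)
    K = A2.shape[1]
    if trace_orientation == "auto" and "n_frames" in attrs and C.ndim == 2:
        # stored geometry disambiguates square trace matrices
        nf = int(attrs["n_frames"])
        if C.shape == (K, nf):
            trace_orientation = "rois_by_frames"
        elif C.shape == (nf, K):
            trace_orientation = "frames_by_rois"
    C2 = _orient_traces(C, K, trace_orientation)
    n_frames = C2.shape[1]
    frame_rate = float(attrs.get("frame_rate", 5.0))
    geometry = FOVGeometry(h, w, n_frames, frame_rate)

    if ids is None:
        ids = [f"roi{i:04d}" for i in range(K)]
    if labels is None:
        labels = ["unlabeled"] * K

    rois = [
        ROI(
            id=ids[k],
            footprint=A2[:, k].reshape(h, w),
            trace=C2[k],
            label=labels[k],
            source=f"{dialect}:{path}",
        )
        for k in range(K)
    ]
    empty = [r.id for r in rois if r.footprint_is_empty]
    if empty:
        warnings.warn(
            f"{len(empty)} ROI(s) have all-zero footprints (retained, flagged): {empty}",
            stacklevel=2,
        )
    return ROICollection(geometry=geometry, rois=rois)


def save_collection(collection: ROICollection, path: str) -> None:
    """Write a collection to HDF5 (footprints ``A``, traces ``C``, id/label tables).

    The layout round-trips bit-exactly through :func:`load_cnmfe_output`.
    """
    g = collection.geometry
    K = len(collection)
    A = np.empty((g.n_pixels, K), dtype=float)
    C = np.empty((K, g.n_frames), dtype=float)
    for k, roi in enumerate(collection):
        A[:, k] = roi.footprint.ravel()
        C[k] = roi.trace
    str_dt = h5py.string_dtype(encoding="utf-8")
    try:
        with h5py.File(path, "w") as f:
            f.create_dataset("A", data=A)
            f.create_dataset("C", data=C)
            f.create_dataset("ids", data=np.array(collection.ids, dtype=object), dtype=str_dt)
            f.create_dataset(
                "labels", data=np.array(collection.labels, dtype=object), dtype=str_dt
            )
            f.attrs["height"] = g.height
            f.attrs["width"] = g.width
            f.attrs["n_frames"] = g.n_frames
            f.attrs["frame_rate"] = g.frame_rate
    except OSError as exc:
        raise RoicurateError(f"cannot write collection to {path!r}: {exc}") from exc


def load_labels(path: str) -> dict[str, str]:
    """Read a label CSV (header ``id,label``) into an id -> label mapping.

    Labels are case-folded; only ``include``/``exclude`` are accepted.
    Duplicate ids are an error, not a silent overwrite.
    """
    df = pd.read_csv(path, dtype=str)
    missing = {"id", "label"} - set(df.columns)
    if missing:
        raise LabelError(f"label file {path!r} lacks column(s) {sorted(missing)}")
    mapping: dict[str, str] = {}
    for row_num, (roi_id, raw) in enumerate(zip(df["id"], df["label"]), start=2):
        label = str(raw).strip().lower()
        if label not in ("include", "exclude"):
            raise LabelError(
                f"{path!r} line {row_num}: unknown label {raw!r} for id {roi_id!r} "
                "(expected include/exclude)"
            )
        if roi_id in mapping:
            raise LabelError(f"{path!r}: duplicate id {roi_id!r}")
        mapping[str(roi_id)] = label
    return mapping


def apply_labels(collection: ROICollection, labels: dict[str, str]) -> None:
    """Attach labels to a collection in place; unknown ids are an error."""
    known = set(collection.ids)
    unknown = sorted(set(labels) - known)
    if unknown:
        raise AlignmentError(f"label ids not present in collection: {unknown}")
    for roi in collection:
        if roi.id in labels:
            roi.label = labels[roi.id]
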
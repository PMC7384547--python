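"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`RoicurateError` so callers (and the CLI) can catch one type.
"""


class RoicurateError(Exception):
    """Base class for all roicurate errors."""


class MissingDatasetError(RoicurateError, KeyError):
    """A named HDF5 dataset is absent from the container."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class ShapeMismatchError(RoicurateError, ValueError):
    """Array shapes are inconsistent (K mismatch, wrong feature dimension, ...)."""


class OrientationError(RoicurateError, ValueError):
    """A square matrix makes ROI-vs-frame orientation ambiguous; pass an explicit flag."""


class LabelError(RoicurateError, ValueError):
    """Bad or missing curation labels (unknown token, duplicate id, unlabeled ROI)."""


class AlignmentError(RoicurateError, ValueError):
    """Two label lists do not cover the same ROI ids."""


class DegenerateInputError(RoicurateError, ValueError):
    """An input is structurally valid but degenerate (e.g. all-zero footprint)."""


class StratificationError(RoicurateError, ValueError):
    """A class has too few members to stratify a split or CV folds."""


class GeometryError(RoicurateError, ValueError):
    """Requested geometry does not fit the field of view."""


class SpecError(RoicurateError, ValueError):
    """A simulation or classifier spec is internally inconsistent."""


class SizeError(RoicurateError, ValueError):
    """A learning-curve subsample size is too small to train on."""


class BundleFormatError(RoicurateError, RuntimeError):
    """A persisted classifier bundle is unreadable or from an incompatible format."""


class UndefinedEffectError(RoicurateError, ArithmeticError):
    """Cohen's d is undefined because the pooled standard deviation is zero."""


class PluginError(RoicurateError, RuntimeError):
    """An external AutoML backend was requested but none is registered."""
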
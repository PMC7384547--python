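"""Synthetic labeled ROI datasets with simulated-negative corruption.

Positive ROIs emulate what a curator accepts: a compact, roughly elliptical
Gaussian footprint (neuronal soma seen through a miniscope) and a calcium
trace with a stable baseline plus sparse fast-rise / slow-decay transients,
the GCaMP6f signature.  Negatives are manufactured from positives by four
corruption modes:

``spatial``
    rescale the footprint about its peak by a factor drawn from
    {1/3, 1/2, 2, 3}, pushing it outside the plausible soma size range;
``trace``
    add framewise Gaussian noise (default 2x the trace's own sd), destroying
    the stable baseline;
``both``
    both of the above;
``merged``
    sum the footprint and trace of two units, emulating two cells wrongly
    extracted as one.

By default 15% of ROIs are corrupted, matching the include/exclude mix of a
typical manually curated 1p dataset; modes are drawn uniformly.  Everything
is a pure function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GeometryError, ShapeMismatchError, SpecError
from .io_cnmfe import FOVGeometry, ROI, ROICollection

CORRUPTION_MODES = ("spatial", "trace", "both", "merged")

# Footprint pixels below this fraction of the peak are zeroed, giving blobs
# compact support (real CNMF-E footprints are sparse).
_SUPPORT_CUTOFF = math.exp(-4.5)  # ~3 sigma


def _default_mode_weights() -> dict[str, float]:
    return {m: 1.0 for m in CORRUPTION_MODES}


@dataclass(frozen=True)
class SimSpec:
    """Conditions for one simulated ground-truth dataset.

    Parameters
    ----------
    n_rois : int
        Total ROI count (positives + corrupted negatives).
    fov : FOVGeometry
        Field of view; default 64 x 64 px, 500 frames at 5 fps.
    neg_fraction : float
        Fraction of ROIs corrupted into negatives (default 0.15).
    mode_weights : dict
        Relative draw weights over the four corruption modes (default
        uniform).
    spatial_factors : tuple of float
        Candidate rescale factors for the ``spatial`` mode.
    trace_noise_sd : float
        Noise magnitude for the ``trace`` mode, as a multiple of each
        trace's own standard deviation (default 2).
    transient_rate : float
        Calcium-event probability per frame (default 0.02, i.e. 0.1 Hz at
        5 fps — a typical CA1 pyramidal-cell event rate).
    rise_frames, decay_frames : float
        Time constants of the double-exponential transient kernel, in
        frames.  Defaults 2 and 10 frames (0.4 s rise, 2 s decay at 5 fps),
        consistent with GCaMP6f kinetics at miniscope frame rates.
    footprint_radius : float
        Gaussian sigma of the soma blob, pixels.
    baseline : float
        Baseline fluorescence level (arbitrary units).
    obs_noise_sd : float
        Observation noise sd on positive traces; small relative to
        transient amplitude so baselines read as stable.
    """

    n_rois: int = 1000
    fov: FOVGeometry = field(default_factory=lambda: FOVGeometry(64, 64, 500, 5.0))
    neg_fraction: float = 0.15
    mode_weights: dict[str, float] = field(default_factory=_default_mode_weights)
    spatial_factors: tuple[float, ...] = (1.0 / 3.0, 0.5, 2.0, 3.0)
    trace_noise_sd: float = 2.0
    transient_rate: float = 0.02
    rise_frames: float = 2.0
    decay_frames: float = 10.0
    footprint_radius: float = 4.0
    amplitude_range: tuple[float, float] = (0.5, 1.5)
    baseline: float = 1.0
    obs_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.neg_fraction < 1.0:
            raise SpecError(f"neg_fraction must be in [0, 1), got {self.neg_fraction}")
        weights = np.array([self.mode_weights.get(m, 0.0) for m in CORRUPTION_MODES])
        if (weights < 0).any() or weights.sum() <= 0:
            raise SpecError("mode_weights must be nonnegative and not all zero")
        if any(f <= 0 for f in self.spatial_factors):
            raise SpecError("spatial_factors must all be positive")
        if any(f == 1 for f in self.spatial_factors):
            raise SpecError("spatial factor 1 is the identity and not a corruption")

    @property
    def n_negatives(self) -> int:
        # round-half-away-from-zero so 0.15 * 1000 -> 150 exactly
        return int(math.floor(self.neg_fraction * self.n_rois + 0.5))


@dataclass
class CorruptionRecord:
    """Provenance of one ROI's label: which mode (if any) produced it."""

    roi_id: str
    mode: str = "none"
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("none",) + CORRUPTION_MODES:
            raise SpecError(f"unknown corruption mode {self.mode!r}")


def transient_kernel(rise_frames: float, decay_frames: float, length: int | None = None) -> np.ndarray:
    """Difference-of-exponentials calcium kernel, peak-normalized to 1."""
    if length is None:
        length = int(math.ceil(8 * max(decay_frames, rise_frames))) + 1
    t = np.arange(length, dtype=float)
    k = np.exp(-t / decay_frames) - np.exp(-t / rise_frames)
    peak = k.max()
    if peak <= 0:
        raise SpecError("degenerate kernel: decay_frames must exceed rise_frames")
    return k / peak


def simulate_calcium_trace(
    spec: SimSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one positive trace; returns (trace, event_frame_indices)."""
    n = spec.fov.n_frames
    events = rng.random(n) < spec.transient_rate
    event_frames = np.flatnonzero(events)
    amplitudes = np.zeros(n)
    if event_frames.size:
        lo, hi = spec.amplitude_range
        amplitudes[event_frames] = rng.uniform(lo, hi, size=event_frames.size)
    kernel = transient_kernel(spec.rise_frames, spec.decay_frames)
    signal = np.convolve(amplitudes, kernel)[:n]
    noise = rng.normal(0.0, spec.obs_noise_sd, size=n) if spec.obs_noise_sd > 0 else 0.0
    return spec.baseline + signal + noise, event_frames


def simulate_footprint(spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw one compact anisotropic-Gaussian soma footprint."""
    h, w = spec.fov.height, spec.fov.width
    r = spec.footprint_radius
    margin = int(math.ceil(1.5 * r))
    if 2 * margin >= min(h, w):
        raise GeometryError(
            f"footprint_radius {r} does not fit a {h}x{w} field of view"
        )
    cy = rng.uniform(margin, h - margin)
    cx = rng.uniform(margin, w - margin)
    sy = r * rng.uniform(0.75, 1.25)
    sx = r * rng.uniform(0.75, 1.25)
    theta = rng.uniform(0.0, math.pi)
    amp = rng.uniform(0.8, 1.2)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = dy * math.cos(theta) + dx * math.sin(theta)
    v = -dy * math.sin(theta) + dx * math.cos(theta)
    fp = amp * np.exp(-0.5 * ((u / sy) ** 2 + (v / sx) ** 2))
    fp[fp < amp * _SUPPORT_CUTOFF] = 0.0
    return fp


def simulate_positive_roi(spec: SimSpec, rng: np.random.Generator, roi_id: str = "roi") -> ROI:
    """Generate one include-worthy ROI, fully determined by the rng state."""
    fp = simulate_footprint(spec, rng)
    trace, _ = simulate_calcium_trace(spec, rng)
    return ROI(id=roi_id, footprint=fp, trace=trace, label="include", source="simulated")


def corrupt_spatial(roi: ROI, factor: float, order: int = 1) -> ROI:
    """Rescale the footprint about its peak by ``factor``; trace untouched.

    The footprint is resampled (spline ``order``, default bilinear), then
    re-embedded in the original field of view with the peak pixel kept at
    its original location; overhang is cropped, exposed regions are zero.
    """
    if factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    fp = roi.footprint
    h, w = fp.shape
    pr, pc = np.unravel_index(int(np.argmax(fp)), fp.shape)
    zoomed = ndimage.zoom(fp, factor, order=order)
    zoomed = np.clip(zoomed, 0.0, None)
    if not np.any(zoomed > 0):  # pathological shrink of a tiny blob
        zoomed = np.array([[fp[pr, pc]]])
    zr, zc = np.unravel_index(int(np.argmax(zoomed)), zoomed.shape)
    out = np.zeros_like(fp)
    r0, c0 = pr - zr, pc - zc
    rs, re = max(r0, 0), min(r0 + zoomed.shape[0], h)
    cs, ce = max(c0, 0), min(c0 + zoomed.shape[1], w)
    if rs < re and cs < ce:
        out[rs:re, cs:ce] = zoomed[rs - r0 : re - r0, cs - c0 : ce - c0]
    return ROI(id=roi.id, footprint=out, trace=roi.trace.copy(), label="exclude", source=roi.source)


def corrupt_trace(roi: ROI, noise_sd: float, rng: np.random.Generator, sd_floor: float = 1.0) -> ROI:
    """Add i.i.d. Gaussian noise with sd ``noise_sd x sd(trace)``; footprint untouched.

    A constant trace (sd 0) falls back to the absolute ``sd_floor`` so the
    corruption is never a no-op.
    """
    if noise_sd <= 0:
        raise ValueError(f"noise_sd must be positive, got {noise_sd}")
    base_sd = float(np.std(roi.trace))
    scale = noise_sd * (base_sd if base_sd > 0 else sd_floor)
    noisy = roi.trace + rng.normal(0.0, scale, size=roi.trace.size)
    return ROI(id=roi.id, footprint=roi.footprint.copy(), trace=noisy, label="exclude", source=roi.source)


def corrupt_both(
    roi: ROI, factor: float, noise_sd: float, rng: np.random.Generator
) -> ROI:
    """Spatial rescale followed by trace noise (the two act on disjoint parts)."""
    return corrupt_trace(corrupt_spatial(roi, factor), noise_sd, rng)


def corrupt_merge(roi_a: ROI, roi_b: ROI) -> ROI:
    """Sum two units' footprints and traces: two cells extracted as one ROI."""
    if roi_a.footprint.shape != roi_b.footprint.shape:
        raise ShapeMismatchError(
            f"footprint shapes differ: {roi_a.footprint.shape} vs {roi_b.footprint.shape}"
        )
    if roi_a.trace.size != roi_b.trace.size:
        raise ShapeMismatchError(
            f"trace lengths differ: {roi_a.trace.size} vs {roi_b.trace.size}"
        )
    return ROI(
        id=roi_a.id,
        footprint=roi_a.footprint + roi_b.footprint,
        trace=roi_a.trace + roi_b.trace,
        label="exclude",
        source=roi_a.source,
    )


def emulate_1p(roi: ROI, spatial_factor: int, temporal_factor: int) -> ROI:
    """Block-average footprint and trace, emulating 1p optics from 2p data.

    Spatial and temporal extents are truncated to whole blocks; block means
    conserve mean fluorescence up to that edge truncation.
    """
    sf, tf = int(spatial_factor), int(temporal_factor)
    if sf < 1 or tf < 1:
        raise ValueError("downsampling factors must be >= 1")
    h, w = roi.footprint.shape
    if sf > min(h, w) or tf > roi.trace.size:
        raise ValueError(
            f"factor ({sf}, {tf}) exceeds image/trace extent ({h}x{w}, {roi.trace.size})"
        )
    h2, w2 = h // sf, w // sf
    fp = roi.footprint[: h2 * sf, : w2 * sf].reshape(h2, sf, w2, sf).mean(axis=(1, 3))
    t2 = roi.trace.size // tf
    trace = roi.trace[: t2 * tf].reshape(t2, tf).mean(axis=1)
    return ROI(id=roi.id, footprint=fp, trace=trace, label=roi.label, source=roi.source)


def make_simulated_ground_truth(spec: SimSpec) -> tuple[ROICollection, list[CorruptionRecord]]:
    """Build a fully labeled collection with ``round(neg_fraction * n_rois)`` negatives.

    Corrupted ROIs are chosen uniformly at random; each gets exactly one
    mode drawn by ``mode_weights``.  Merged ROIs consume a sacrificial
    partner generated on the spot, so the headline ROI count is unchanged.
    Deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rois
    n_neg = spec.n_negatives
    weights = np.array([spec.mode_weights.get(m, 0.0) for m in CORRUPTION_MODES], dtype=float)
    probs = weights / weights.sum()
    if n_neg > 0 and n < 2 and probs[CORRUPTION_MODES.index("merged")] > 0:
        raise SpecError("merged corruption needs n_rois >= 2")

    rois = [simulate_positive_roi(spec, rng, roi_id=f"roi{i:05d}") for i in range(n)]
    records = [CorruptionRecord(roi_id=r.id) for r in rois]

    corrupt_idx = rng.choice(n, size=n_neg, replace=False) if n_neg else np.array([], dtype=int)
    modes = rng.choice(CORRUPTION_MODES, size=n_neg, p=probs)
    for idx, mode in zip(corrupt_idx, modes):
        roi = rois[idx]
        if mode == "spatial":
            factor = float(rng.choice(spec.spatial_factors))
            rois[idx] = corrupt_spatial(roi, factor)
            params = {"factor": factor}
        elif mode == "trace":
            constant = float(np.std(roi.trace)) == 0.0
            rois[idx] = corrupt_trace(roi, spec.trace_noise_sd, rng)
            params = {"noise_sd": spec.trace_noise_sd, "absolute_floor": constant}
        elif mode == "both":
            factor = float(rng.choice(spec.spatial_factors))
            rois[idx] = corrupt_both(roi, factor, spec.trace_noise_sd, rng)
            params = {"factor": factor, "noise_sd": spec.trace_noise_sd}
        else:  # merged
            partner = simulate_positive_roi(spec, rng, roi_id=f"{roi.id}_partner")
            rois[idx] = corrupt_merge(roi, partner)
            params = {"partner_id": partner.id}
        records[idx] = CorruptionRecord(roi_id=roi.id, mode=str(mode), parameters=params)

    return ROICollection(geometry=spec.fov, rois=rois), records


def save_corruption_manifest(records: list[CorruptionRecord], path: str) -> None:
    """Write the per-ROI corruption manifest as CSV (id, mode, parameters)."""
    rows = [
        {
            "id": rec.roi_id,
            "mode": rec.mode,
            "parameters": ";".join(f"{k}={v}" for k, v in sorted(rec.parameters.items())),
        }
        for rec in records
    ]
    pd.DataFrame(rows, columns=["id", "mode", "parameters"]).to_csv(path, index=False)
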
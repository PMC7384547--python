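# Methods

## Scope and model

`roicurate` classifies putative neurons ("ROIs") extracted by CNMF-E from
1-photon calcium imaging movies as *include* (neuronal) or *exclude*
(artifact). An ROI is a pair: a non-negative spatial footprint image (the
unit's pixel weights in the field of view) and a calcium trace (its inferred
fluorescence time series). The classifier operates on a fixed-length vector
per ROI and is deliberately simple — conventional estimators on nearly raw
pixels and frames — because the curation decision is driven by coarse,
low-level properties (soma size and compactness, baseline stability,
transient shape) rather than by fine image structure.

## Preprocessing

* **Footprint crop.** The footprint is cropped to `crop_size × crop_size`
  (default 80) centered on its peak-intensity pixel, so the peak sits at
  `(crop_size//2, crop_size//2)`. Peak ties break to the smallest row, then
  smallest column — deterministic and independent of memory layout. Regions
  of the window outside the FOV are filled with `pad_value` (default 0,
  matching the empty background the crop removes). The crop preserves the
  global maximum by construction. All-zero footprints are loadable and
  flagged, but cropping one is a `DegenerateInputError`: there is no peak to
  center on.
* **Trace standardization.** The first `trace_len` frames (default 500 =
  100 s at 5 fps) are kept; shorter traces are right-padded with
  `pad_value` *before* normalization (recordings vary in length; padding
  preserves dataset size). Normalization is per-trace min-max to `[0, 1]`;
  constant traces map to all-zeros. Min-max is a documented choice among
  reasonable per-trace normalizations (a `"none"` escape hatch exists); it
  is the common convention when traces from different sessions arrive on
  incommensurable fluorescence scales.
* **Assembly.** Row-major flattened crop, then trace: `6400 + 500 = 6900`
  features at the defaults. Datasets are split 80/20 by a stratified,
  seed-deterministic split; the `modality` switch (`spatial`, `trace`,
  `combined`) restricts the feature block to compare information content.

Indexing is 0-based and half-open throughout; FOV images are row-major
(row = y). MATLAB-origin files (MAT v7.3 = HDF5) are handled by the
`matlab_cnmfe` dialect, which undoes MATLAB's transposed storage of 3-D
stacks; 2-D matrix orientation is resolved by matching the ROI count K
between footprint and trace matrices, and genuinely ambiguous square
matrices require an explicit orientation flag rather than a guess.

## Synthetic ground truth

The generator provides labeled data with known truth; its defaults are the
study conditions for every test in this repository.

* **Positives.** Footprints are anisotropic Gaussian blobs (σ ≈
  `footprint_radius`, default 4 px, random orientation and ±25%
  eccentricity) truncated at 3σ to compact support, with random centers
  placed so the blob fits the FOV (default 64×64). Traces are a constant
  baseline plus transients: per-frame Bernoulli events (default rate
  0.02/frame = 0.1 Hz at 5 fps, a typical CA1 pyramidal-cell event rate),
  uniform amplitudes 0.5–1.5, convolved with a peak-normalized
  difference-of-exponentials kernel (rise 2 frames, decay 10 frames ≈ 0.4 s
  and 2 s at 5 fps, consistent with GCaMP6f kinetics), plus Gaussian
  observation noise (sd 0.05) small enough that baselines read as stable.
* **Negatives.** A fraction `neg_fraction` (default 0.15, the include/
  exclude mix of typical curated 1p datasets; `round()` so 7200 → 1080 and
  1000 → 150) of ROIs is corrupted, one mode each, drawn by `mode_weights`
  (default uniform):
  * `spatial` — bilinear rescale about the peak by a factor from
    {⅓, ½, 2, 3}, re-embedded at the original peak position. The factor set
    is symmetric up/down scaling past plausible soma sizes. Nearest-neighbor
    resampling is available for exact small-case checks.
  * `trace` — i.i.d. Gaussian noise at `2 × sd(trace)` per frame, chosen so
    the corrupted trace visibly violates baseline stability while staying
    in a realistic amplitude range; constant traces fall back to an
    absolute sd floor so the corruption is never a no-op.
  * `both` — composition of the two (they commute: disjoint parts).
  * `merged` — pixelwise/framewise **sum** of two units. Sum rather than
    mean because CNMF-E's generative model is additive in sources; the
    partner is generated sacrificially so the headline ROI count and
    positive/negative arithmetic are unaffected.
* **2p emulation.** `emulate_1p` block-averages footprints and bin-averages
  traces (mean-preserving up to edge truncation), the standard way to make
  2p-derived ROIs resemble the coarser 1p optics before corruption.

What the generator does **not** emulate: overlapping footprints and shared
neuropil contamination, photobleaching drift, motion artifacts, correlated
noise across ROIs, and the genuinely ambiguous edge cases on which human
raters disagree. Synthetic positives and negatives are therefore more
separable than real curation data: tests passing on this generator
demonstrate the pipeline's correctness and its qualitative behavior
(combined features ≥ single modalities, early learning-curve plateau), not
the F1 a lab should expect on its own recordings.

## Classification

Families: `decision_tree` (unrestricted depth, min leaf 1) and `knn`
(k = 5) — the conventional out-of-the-box settings — optionally preceded by
PCA fitted on training rows only (no test leakage; asserted by a test that
permutes test rows and compares fitted components). Model selection uses
stratified k-fold CV (default 10 folds, 1 repeat; repeated CV pools all
fold scores) on the include-class F1, or F-beta when the cost of false
negatives and false positives differs. Confidence is the predicted class's
probability: leaf class fraction for trees, neighbor vote fraction for KNN.
Note a fully grown tree yields degenerate confidences (≈1.0 everywhere);
certainty analyses should use an estimator with graded probabilities, as
the acceptance script does with KNN.

`external_automl` is a registry seam (`register_automl_backend`): an
external engine receives the same `LabeledDataset` and returns an estimator
honoring the scikit-learn contract; no AutoML search ships in this package.

Bundles persist as a zip of metadata JSON plus a pickled pipeline. Archive
member timestamps are fixed at the zip epoch and the `created` field
defaults to unset, so the same fit always serializes to identical bytes —
reproducibility is preferred over automatic provenance stamping (pass
`created=` to stamp explicitly). A format-version field guards against
loading incompatible archives.

## Evaluation

* **Confusion / PRF.** Include is the positive class. Row-proportion
  matrices normalize per true class. `F_β = (1+β²)PR/(β²P+R)`; 0/0 cases
  return 0 with a `degenerate` flag rather than raising.
* **Cohen's d.** `(mean_a − mean_b) / pooled sd`, sample variances with
  `ddof=1`; zero pooled sd raises. In `certainty_analysis`, groups with
  fewer than two members yield `d = None` (undefined marker, not an error).
* **Learning curves.** For each size, a stratified subsample of the
  training rows is drawn — nested by default (each size's sample contains
  the previous one's), which reduces curve variance; independent draws are
  available. The test split is fixed across sizes. Sizes leaving any class
  with fewer than two members are rejected.
* **PELT.** Exact penalized change-point detection with the Gaussian
  mean-shift (L2) cost and pruning constant 0; it provably returns the
  exhaustive-search optimum, and the test suite checks that equality on
  random short series. Default penalty `2·log(n)·var(series)` — the
  standard mean-shift scaling, exposed as a parameter. The "plateau size"
  reported is the training size at the *last* detected change point, with
  all change points returned alongside.

## Problem sizes

The bundled tests and the acceptance script run the full study at 2,000
simulated ROIs (80/20 split, 6,900 features), learning-curve sizes
50–1,600, and the corruption-arithmetic checks at 7,200 and 1,000 ROIs on a
reduced 32×32 FOV (the count bookkeeping is geometry-independent). These
sizes give stable estimates (held-out F1 sds of a few 10⁻³ across seeds)
while keeping a full run near one minute on a single CPU.

## Known limitations

* Synthetic separability overstates real-world F1 (see above).
* Min-max trace normalization amplifies noise on event-free traces; at the
  default event rate such traces are vanishingly rare, but real silent
  cells would surface in the review queue rather than being auto-included.
* `corrupt_spatial` near the FOV edge clips the rescaled blob; this mirrors
  real oversized extractions but means the area-scaling law holds only away
  from edges.
* Pickled pipelines are a Python/scikit-learn artifact: bundles are
  portable across machines but not across incompatible scikit-learn
  versions (the recorded version in the metadata makes the mismatch
  diagnosable).
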
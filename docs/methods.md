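# Methods

This note documents the models, conventions and design choices behind
`rtname`, in the order data flows through the pipeline.

## Data model and DICOM layer

Structures live in the DICOM patient coordinate system (LPS,
millimetres). Only axial series are supported; a non-axial or
mixed-orientation series is rejected with "inconsistent series" rather
than silently resampled, because downstream conventions (slab assignment,
flattening order) assume identity direction cosines. Slices are ordered
by z ascending with instance number breaking ties. Rescale slope and
intercept are applied at read time, so voxels are Hounsfield Units; the
synthetic writer uses slope 1 / intercept 0 with signed 16-bit pixels,
making the HU round trip exact.

The physician-given name is preserved byte-for-byte at read time.
Normalisation of any kind is an explicit, separate step — the text model
needs the raw variability, and silent cleaning at the I/O boundary is a
classic source of irreproducibility.

A frame-of-reference mismatch between an RT-STRUCT and its CT series
warns and keeps the record (multi-vendor exports are inconsistent in
practice); a `strict` flag upgrades the warning to an error. Ground-truth
standard labels ride along in the RT ROI Observations sequence
(ROI Observation Label) in synthetic files, and the reader recovers them
when present.

## Geometric featurization

Each structure is rendered onto a fixed grid (default 96 × 96 × 48) that
spans the planning image's bounding box — from the outer corner of the
first voxel to the outer corner of the last, so the box covers whole
voxels. The grid inherits the box anisotropically: each axis is divided
into the configured number of cells regardless of the box's physical
aspect ratio. Rasterization happens directly at the target resolution: a
cell is set iff its centre lies inside or on the boundary of a filled
contour polygon, with a contour at height z assigned to the slab whose
z-interval contains z, and multiple polygons in one slab OR-combined.
Rasterizing at native CT resolution and pooling down would be an equally
defensible choice; direct rasterization was chosen because it is
deterministic, convention-free, and checkable against a brute-force
point-in-polygon oracle (the test suite does exactly that on random
star-shaped polygons).

Conventions fixed for reproducibility (serialized SVD models depend on
them):

* boundary cell centres count as inside;
* the bony-anatomy threshold is exclusive — HU exactly 1300 maps to 0,
  1301 to 1 — with nearest-neighbour sampling at cell centres;
* flattening is slab-major: flat index = (k·ny + j)·nx + i, k (z)
  slowest, i (x) fastest; the default grid flattens to 442,368 entries,
  and structure⊕bone concatenation (structure first) to 884,736;
* contours (or parts of contours) outside the image box are clipped
  silently — real plans contain couch and marker structures beyond the
  field of view — and contours with fewer than 3 points are skipped with
  a warning.

## Text model

Names are lowercased and nothing else. Each whitespace token is wrapped
in boundary markers ("<bldr>"), decomposed into character n-grams for
n = 2..5 plus the whole wrapped token, and hashed (FNV-1a 64-bit) into
2^20 buckets. Only buckets seen in training get an embedding row
(initialised uniform ±1/dim from the seeded generator); the document
vector is the mean of its n-gram rows, and a linear softmax layer on top
is trained by plain SGD on cross-entropy, learning rate 0.5 decaying
linearly to zero over 25 epochs. These hyperparameters are the standard
defaults for supervised subword embedding classifiers on short text; for
clinical structure names the corpus is tiny and results are insensitive
to them over a wide range. Training is single-threaded NumPy and bitwise
reproducible for a fixed seed.

A name with no in-vocabulary n-gram embeds to the zero vector, which the
softmax maps to the exact uniform prior — a deliberate, testable fallback
for out-of-vocabulary inputs.

## Dimensionality reduction

Truncated SVD of the raw {0,1} occupancy matrix, without mean-centering:
centering would densify an extremely sparse matrix and the downstream
random forest does not need it. Small matrices (n·d ≤ 4·10^6) are
decomposed exactly by dense LAPACK and truncated; full-size feature
matrices use a seeded randomized range-finder (7 power iterations). Every
model applies a fixed sign convention — the largest-magnitude entry of
each component is made positive — so serialized models are identical
across solvers and runs. The SVD is always fit on training rows only;
held-out rows are projected with the frozen components to avoid leakage.

The late/single-view image branch uses k = 100 components, the
intermediate branch k = 50; one decomposition is computed at the larger
rank and truncated for the smaller, which is exactly the leading
components of the same factorization. Whether the bony-anatomy block is
included in the SVD input is a config switch (`include_bone`); the
default is structure-only, because in the synthetic cohorts all patients
share a common frame and the skeleton adds little location information,
while doubling the feature length. With heterogeneous real-world imaging
the bone block is the mechanism that anchors structures to the skeleton,
and the switch exists for that purpose.

## Integration

Intermediate integration concatenates document vector (first) and
reduced geometry vector (second) into a 250-dim feature for one random
forest. Late integration fuses the two single-view posteriors
element-wise: AVG divides the element-wise sum by the number of views
(always a valid distribution); MAX takes the element-wise maximum and
argmaxes it **without renormalizing** — renormalization cannot change the
argmax, and the raw maxima are easier to interpret. All argmax ties break
by labelset order, making every prediction deterministic.

The ensemble is a 100-tree random forest, unlimited depth, sqrt-feature
subsampling, fixed seed, probabilities aligned to the task's fixed label
order (classes absent from training get probability 0). Tree ensembles
are insensitive to the concatenation order; it is fixed anyway so that
serialized bundles are stable.

## Evaluation

Macro precision, recall and F1 average per-class scores with equal class
weight over the union of labels present in the truth or the predictions
— not over the full label set — and a per-class ratio with a zero
denominator contributes 0. This union convention matters: a test set
missing one class entirely (e.g. an institution that never delineates the
large bowel) is evaluated over N−1 classes, which is the behaviour that
makes the majority-baseline closed forms (macro P = a/N, R = 1/N,
F1 = (2a/(1+a))/N, with a the majority fraction) come out right. Accuracy
is the multiclass trace/total. Report display uses half-away-from-zero
rounding to 3 decimals; JSON reports keep full precision.

Splits: stratified k-fold (k = 5 default) at the structure level —
stratification is by standard label, and patient-level grouping is
available via the center-based schemes; leave-one-center-out
cross-validation; and whole-center holdout (default 10 of 40 centers),
which is the headline evaluation because it measures cross-institution
generalisation. No patient ever straddles train and test since patients
belong to exactly one center.

## Synthetic cohorts

The generator's defaults are the study conditions the test suite and the
acceptance benchmark run under:

* 40 centers × 5 patients, prostate task (the lung task is generated the
  same way but has no engineered ambiguity);
* 7 labeled OAR/PTV structures per prostate patient plus 15–24 "other"
  structures (random boxes/ellipsoids anywhere in the body with
  planning-style names like "CTV45_OPT", "Marker1", "ROI_7"), giving an
  "other" fraction near 0.73 — the imbalance regime of real plans;
* per-center naming: each center fixes one preferred alias per class from
  a table of clinically observed aliases, perturbed per structure by case
  flips (p = 0.10), alias swaps (p = 0.10) and generic suffixes
  (p = 0.05);
* ambiguity rate 0.5: half the centers use the bare alias "bowel", each
  meaning either the small or the large bowel (chosen 50/50). This is the
  engineered failure mode for text: a cross-center label conflict that no
  amount of text training can resolve, while the two bowel classes are
  generated at distinct locations (> 20 mm apart by construction) so the
  geometry view can;
* phantoms: 96 × 96 × 48 voxels at 4 × 4 × 5 mm; air background
  (−1000 HU), soft-tissue body column (0 HU), vertebral column and (for
  the pelvis) femoral-head spheres at 1500 HU, Gaussian HU noise
  (σ = 15, far from the 1300 HU bone threshold); one jittered ellipsoid
  per OAR/PTV class (centre jitter σ = 8 mm, size jitter ±15%), contours
  traced per slice as 32-vertex polygons.

All randomness flows from one seed through named substreams (center
profiles / per-patient geometry / per-patient naming), so any patient can
be regenerated independently and cohorts are byte-identical across runs.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: realistic organ shapes and HU
textures, inter-patient anatomical variation beyond jitter, vendor
quirks in DICOM encoding, truly unseen naming conventions at test
centers (test centers draw from the same alias table as training
centers), or the messiness of real "other" structures. Synthetic
accuracies are accordingly much higher than anything achievable on
clinical data; the benchmark's claims are directional (every model beats
the baseline; intermediate integration is at least as good as the image
view and within 0.02 macro-F1 of the text view; late-MAX fusion does not
lose precision on the ambiguous classes), not absolute.

## Problem sizes and numerics

The full benchmark (40 × 5 patients, ~5200 structures, 442,368 features)
featurizes in ~30 s and trains all branches in about a minute on one
CPU; the determinism check runs the whole pipeline twice at a reduced
size (4 centers, 24 × 24 × 12 grid), since bitwise reproducibility is
scale-independent. Degenerate inputs are rejected loudly rather than
patched: single-slice series ("degenerate extent"), single-class
training sets ("degenerate task"), k outside [1, min(n, d)] for the SVD,
mismatched vector lengths everywhere.

## Known limitations

* Only axial, single-frame-of-reference CT series are supported; no MRI,
  no dose/DVH data.
* Early integration (concatenating raw text and image features) is
  deliberately not implemented — the 442,368-long geometry vector makes
  it impractical and it is outside the package's scope.
* Late fusion weights both views equally; a weighted average is exposed
  nowhere because choosing weights fairly would require a validation
  protocol the package does not prescribe.
* The alternative classifier sweeps (KNN, SVM variants, logistic
  regression) and tf/tf-idf text weighting pipelines are out of scope;
  the classifier behind the ensemble interface is pluggable if needed.
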
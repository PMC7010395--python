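# Methods

`finid` implements a fully automated contour-based photo-identification
pipeline for great white shark dorsal fins: detection of the fin outline in a
natural image as an *open contour stroke* of a region hierarchy, biometric
encoding of that outline, and individual identification against a catalogue
of labelled reference fins. This note records the models, the numerical
choices, and what the synthetic benchmarks do and do not demonstrate.

## Curve scale space

A contour is an ordered polyline `C(u) = (x(u), y(u))`, resampled uniformly
in arc length before any filtering so that filter scales expressed in
*samples* are geometrically meaningful. The corner response is the squared
difference of two Gaussian-smoothed copies of the curve,

    D(u, σ) = [G(mσ)*x − G(σ)*x]² + [G(mσ)*y − G(σ)*y]²,

a band-pass curvature-saliency signal: σ controls localisation, m the width
of the pass band. Keypoints are local maxima of D ranked by **prominence**
(peak height above the larger of the minima of the two flanking intervals,
each interval ending at the nearest strictly higher sample). Two details
matter:

* *Open signals*: an interval that reaches the signal end contributes a
  reference minimum of zero, so end-dominated peaks are scored by their
  absolute height. A consequence worth knowing: prominences of open signals
  are **not** invariant to adding a constant to D; circular (closed) signals
  are.
* *Numerical floor*: maxima whose prominence is below `1e-9·max(|D|, 1)` are
  float noise on numerically constant responses (e.g. a perfect circle) and
  are suppressed.

Gaussian kernels are truncated at 4σ and renormalised. Closed curves are
padded circularly; open curves by **odd (antisymmetric) reflection**, which
preserves linear ramps — a straight curve has exactly zero response, so open
ends create no spurious corners. Ties in prominence break toward the lower
vertex index; everything is deterministic.

## Fin detection as contour strokes

Region hierarchies come from a pluggable backend (any algorithm producing
nested regions with levels in [0, 1]); the built-in fallback floods the
Sobel gradient and merges watershed basins weakest-boundary-first. From a
hierarchy the detector keeps the top k = 12 regions after descending to a
pool of 200 unique regions and rejecting those smaller than 0.1 % of the
image or duplicating a kept region at IoU > 0.95 (the rejection thresholds
are declared defaults, configurable).

Each region boundary (traced with interior on the left; reversal detectable
by the sign of the shoelace area) is resampled to 128 vertices and
keypointed with σ = 1, m = 4, n = 7. Strokes are the boundary arcs between
every *ordered* keypoint pair — (n² − n)·k = 504 candidates for a full pool —
cut from the **full-resolution** boundary (keypoints are only localised on
the 128-sample curve; resampled arcs would smooth away exactly the trailing-
edge detail the biometrics need).

Stroke features (180-dim): a 20-word bag of dense opponent-colour patch
descriptors sampled in a ±4 px band at patch sizes 16/24/32/40 (direction-
independent), concatenated with a 20 × 8 spatial/orientation histogram of
boundary normals (direction-dependent); each part L2-normalised. The
appearance descriptor is a per-channel gradient-orientation histogram in
opponent colour space with a seeded k-means codebook — a deliberately simple
dense descriptor honouring the "dense local descriptor in an opponent colour
space, 20-word dictionary" contract. A 500-tree random forest regresses
stroke quality; greedy NMS suppresses strokes overlapping a kept one by more
than 0.2 (overlap = matched pixels within 2 px over the smaller stroke).

Stroke quality (`F_inst`) is the bipartite boundary-matching F-measure: both
curves are rasterised **and thinned to 1-px-wide chains** (the boundary-
benchmark convention — without thinning, a sub-pixel-wiggly ground-truth
polyline rasterises double-thick and one-to-one matching caps F near 0.85
for geometrically identical curves), then matched one-to-one within a
tolerance of 0.0075 × image diagonal. Detection is summarised by AP at a
quality threshold t and by `AP_vol`, the trapezoidal mean of AP over the
threshold grid; a perfect candidate generator and detector scores exactly 1.

## Biometric encoding

A detected fin contour is resampled to 1024 vertices and keypointed at
σ = 2, m = 8; the n most prominent maxima (default n = 50) subdivide it into
n(n−1)/2 subsections (1225), each resampled to 256 vertices. Two descriptor
types are computed at filter scales S = {1, 2, 4, 8} (in subsection-sample
units, giving scale normalisation):

* **DoG norm** — the L2-normalised response vector with m = 2; rotation
  invariant by construction. Straight subsections (zero response) are
  flagged and excluded from matching.
* **Normal descriptor** — the subsection is rigidly moved so its chord lies
  on the +x axis (reflection resolved by forcing nonnegative mean turning),
  smoothed at σ, and the two components of the per-vertex unit normals
  concatenated (512-dim, L2-normalised). A literal smoothed-coordinates
  variant is available behind `variant="smoothed-coords"`; the unit-normal
  reading is the default because the descriptor is explicitly a vector of
  boundary normals.

Reference fins are encoded in both traversal directions, queries in one, so
matching never needs to compare direction flags.

## Identification

**LNBNN baseline.** For query descriptor d and class c,
`f(d, c) = max(0, δ(NN_C̄) − δ(NN_c))` with δ the squared Euclidean distance
to the nearest reference of the class (NN_c) or of all other classes
(NN_C̄); scores are summed per (type, scale) and combined with unit scale
weights. Nearest neighbours are exact (blocked matrix products); approximate
indexes may be plugged in for large catalogues, but every test and benchmark
uses exact search. Ties in the final ranking break toward the lower class
id. Evaluation reports pooled AP over all (query, class) scores, mAP (the
unweighted mean of per-individual APs, each individual ranked over all
queries by its score column), and top-1 accuracy.

**Fin space.** The tip (located by the coarse-scale curvature maximum at
σ = 16, m = 2, or supplied as ground truth) splits the contour into leading
and trailing edges; each edge is divided into 5 equal arc-length partitions.
A subsection *occupies* a partition when it covers strictly more than half
of it; the occupied set is a contiguous run, and the 55 possible runs are
the spatial bins. Global filter scale `σ_g = σ/256 · p` (p = subsection
length as a fraction of contour length) falls into one of 5 logarithmically
spaced half-open bins spanning the attainable range — descriptor scales are
geometric, so log spacing gives each octave equal resolution. With two
descriptor types the space has 2 × 55 × 5 = 550 bins.

Instead of pooling `f(d, c)` into one scalar per class, each score is added
to the bin of the matched *reference* descriptor, giving a 550-dim scoring
vector per (query, class) whose total equals the LNBNN class score exactly
(references that occupy no partition are dropped from binned catalogues so
this conservation is exact). A 500-tree random forest maps scoring vectors
to P(query-is-same-class), trained with two-fold cross-validation split **by
individual** (never by query), negatives down-sampled 5:1 per query
(seeded), and balanced class weights; evaluation uses the fold model that
never saw the query's individual. Per-bin identification AP (`
measure_bin_distinctiveness`) quantifies where on the fin individuality
lives.

## Synthetic data

Real curated fin catalogues are not redistributable, so benchmarks run on a
seeded generator that reproduces the *structure* of the problem: each
individual has a persistent signature (apex position, aspect ratio, edge
curvatures, and 5–12 trailing-edge notches with positions uniform on the
edge, log-normal depths ≈ 2 % of base length, and widths 1–4 % — drawn once
per individual; populations are redrawn until trailing edges are mutually
distinct). Sightings perturb the signature with in-plane rotation, scale,
an out-of-plane shear proxy, smooth bending, smoothed contour jitter,
waterline occlusion (fraction of the contour hidden from below; every query
keeps ≥ 25 % of the trailing edge visible) and splash clutter. The fin is
rendered attached to a body continuation so that no closed region of the
image is the fin alone — detection must carve it from a region boundary.
Each sighting ships ground truth: the visible contour, the tip arc position,
and a region hierarchy (whole image, fin+body above water, water, splash
distractors).

Presets: `easy` (rotation ≤ 0.08 rad, scale 0.95–1.05, jitter ≤ 0.2 px,
occlusion ≤ 0.1, no splash) is the designed-separable capability floor;
`standard` (rotation ≤ 0.35, scale 0.75–1.25, shear ≤ 0.15, jitter ≤ 0.5 px,
occlusion ≤ 0.5, splash) is the realistic operating point; `hard` goes
beyond it. One reference (zero nuisance) per individual, all other
sightings are queries — the one-shot protocol.

**What the benchmarks show and don't.** Passing the synthetic benchmarks
demonstrates that the geometry pipeline — keypoint stability, subsection
matching, scale combination, fin-space pooling — recovers identity under
controlled nuisance of realistic magnitude. It does not demonstrate
performance on natural photographs: the generator has no photometric
variation to speak of, its segmentation hierarchies are exact, its occlusion
is a clean horizontal cut, and notch statistics are a convenience model, not
shark biology.

## Problem sizes and determinism

Benchmarks use 20 individuals × 6 sightings on 256 × 256 canvases, encoding
with 16 fin keypoints (120 subsections per fin) — the package's desk-scale
configuration; the package *defaults* keep the full published operating
point (50 keypoints, 1225 subsections). Detection capability is measured on
50 standard-preset sightings via the ground-truth hierarchies; the best
candidate per fin is found exactly using a many-to-one F upper bound with
best-first exact verification. All randomness flows from explicit seeds
(population, sightings, k-means, forests, fold splits); two runs with the
same configuration produce identical outputs.

## Known limitations

* The fallback segmentation backend is a stand-in for a learned boundary
  detector and will not produce fin-quality hierarchies on real photographs.
* The appearance channel is a simplified dense descriptor; swapping in a
  full opponentSIFT implementation is a backend change behind the same
  dictionary contract.
* Tip localisation by coarse curvature assumes the apex is the dominant
  bend; heavily occluded contours should supply the tip externally.
* `measure_bin_distinctiveness` recomputes restricted nearest neighbours per
  bin and is intended for analysis at catalogue scale, not per-query use.
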
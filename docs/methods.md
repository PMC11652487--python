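# Methods

This note records the model, the numerical conventions and the deliberate
design choices behind `trapquant`, at the level of detail a maintainer or a
reviewer of results needs. Nothing here states an empirical number that the
test suite or `scripts/acceptance.py` does not itself compute.

## Pipeline model and assumptions

An imaged field of view carries one DNA channel and one NET-protein channel
(extra channels may be marked ignored). The pipeline assumes:

1. NET-associated protein staining delineates the object footprint (cell
   body or NET), and DNA staining delineates chromatin within it.
2. One protein-connected component corresponds to one object, except when it
   contains several well-separated nuclei (handled by watershed splitting).
3. NETosis manifests morphologically as growth of the protein footprint,
   growth of DNA relative to protein, loss of nuclear circularity, and
   increased spread of the boundary radius — the four classification
   criteria, all monotone "increase" criteria.

Intensities are kept on their native scale; nothing is normalized at read
time. This is what makes a configuration transferable across datasets
acquired with one imaging protocol, and non-transferable otherwise.

## Segmentation conventions

* **Otsu.** 256-bin histogram over the image's value range; the threshold is
  the bin center maximizing between-class variance (first maximum on ties);
  foreground is strictly above the threshold. A constant image yields an
  empty mask plus a warning, not an exception.
* **Adaptive rule orientation.** Foreground iff `p >= m * (1 - t/100)`.
  Negative `t` therefore *raises* the bar above the local mean; `t = 0`
  marks everything at or above the local mean. The rule is deliberately
  inclusive at equality so batch and exploratory runs agree bit-for-bit.
* **Window semantics.** `window` is a full side length; the neighborhood is
  the Chebyshev ball of radius `window // 2` (so an even window behaves as
  the next smaller odd one); the default window is `round((H + W) / 2 / 8)`
  (half away from zero), clamped to ≥ 3. Edges are mirror-padded
  (symmetric), which avoids darkened borders. Local sums use an int64
  integral image: for integer images the local mean is bit-identical to a
  direct per-pixel average, which is what makes the oracle-equivalence tests
  exact rather than approximate.
* **Connectivity** is 8-connected everywhere.
* **Pairing.** Each DNA component goes to the protein component with
  maximal pixel overlap; ties go to the lower protein label (deterministic).
  Components below `min_object_area` (default 20 px, configurable) are
  logged and dropped as debris; DNA without protein and protein without DNA
  are logged with reasons, never silently discarded.
* **Splitting.** A protein component with ≥ 2 DNA components is split only
  when the *minimum* pairwise centroid distance strictly exceeds
  `split_distance` (default 5 px; equality does not split). Markers are the
  DNA components; the elevation map is the negated Euclidean distance
  transform of the protein mask — geometry-based rather than
  intensity-based, so the split is robust to staining heterogeneity. Basins
  partition the protein mask exactly (pixel conservation) and each DNA
  component keeps all its pixels.
* **Object identity.** Ids are the field id plus a running index in raster
  order of each object's first protein pixel, so they depend on geometry,
  not on labeling traversal order.

## Feature conventions

* Areas are raw pixel counts; `area_ratio = dna_area / protein_area`.
* `dna_deformation = P² / (4πA)` (inverse circularity: 1 for a disk,
  growing with irregularity) computed on the largest 8-connected DNA
  component, with the Crofton 4-direction perimeter estimator (masks padded
  by one pixel first, so components touching the crop edge keep their full
  boundary). The digitized-disk bias of the estimator is within the
  [0.95, 1.10] band asserted in the tests.
* Radius spread: boundary pixels are DNA pixels 8-adjacent to background
  (the crop border counts as background); distances are measured to the
  mean coordinate of *all* DNA pixels; the *population* standard deviation
  is reported. The coefficient of variation (`dna_radius_std / mean
  radius`) is computed and exposed for scale-robust configurations, but the
  default criterion uses the raw std in pixels. A single-pixel DNA mask is
  flagged degenerate: deformation 1, radius features 0.
* One caveat worth knowing: for a *perfect disk* the boundary-radius spread
  is pure digitization noise (a few tenths of a pixel, independent of
  radius), so the std scales with object size only when the spread is
  genuinely geometric. The scale-equivariance test therefore uses star
  shapes, not disks.
* **Radial profiles.** A square crop of half-side `crop_radius` (default
  40 px, zero-padded at image borders) centered on the pixel nearest the
  object centroid is binned by Euclidean distance into `n_bins` (default
  16) equal-width annuli; each bin reports its mean intensity, empty bins 0,
  pixels at distance ≥ `crop_radius` are discarded. Rotating the crop by
  any multiple of 90°, or transposing it, permutes pixels within bins, so
  profiles are exactly invariant (bin sums of integer images are exact in
  float64). The embedding input is the DNA profile concatenated with the
  protein profile (32 dimensions by default), fixed across a dataset so
  inputs are commensurable.

## Classification and summaries

Criteria are joined by conjunction — an object is a NET iff every *enabled*
criterion has `value >= threshold`. Inclusive `>=` at the boundary is the
documented convention. Disabled criteria are recorded as passing with an
`enabled=false` flag in the output table. Consequences asserted as
properties: raising any enabled threshold never increases the NET count, and
disabling a criterion never decreases it. "Percent object area covered by
NETs" is the union-mask (DNA ∪ protein) area of NET-classified objects over
that of all objects; an empty dataset reports zeros with an explicit flag
rather than NaNs.

## Validation and automatic thresholds

Only NET and Neutrophil labels enter the confusion matrix (NET → TP/FN,
Neutrophil → FP/TN); the other four labels are reported descriptively via
per-label NET-prediction rates. FDR uses the convention 0/0 → 0 (no
positive predictions ⇒ no false discoveries). Sampling is uniform without
replacement (NumPy PCG64, seed recorded), with optional per-dataset quotas
that must sum to the request. Annotations from several annotators are pooled
by `validate`; `validate_per_annotator` splits them — no adjudication or
majority vote is attempted.

Threshold fitting is a deterministic search over the canonical candidate set
per feature: midpoints between consecutive sorted unique training values,
plus finite sentinels one unit below the minimum (always-pass) and above the
maximum (always-fail). Finite sentinels stand in for ±∞ because
configuration thresholds must be finite. The search starts from the best
single-feature classifier (all other features at the always-pass sentinel)
— so the final training accuracy can never fall below the best
single-feature accuracy — and then repeatedly solves every unordered *pair*
of features exactly by vectorized exhaustive 2-D search given the other
thresholds, until a full sweep brings no improvement (at most 10 sweeps).
Ties always resolve toward higher thresholds. Pairwise rather than
one-at-a-time ascent was chosen because it is provably exact whenever at
most two features carry information (it *is* the exhaustive grid there) and
is never worse elsewhere; one-at-a-time ascent measurably stalls in local
optima on small overlapping-class instances. The `max_accuracy_fdr0`
objective maximizes accuracy over candidates with zero training FDR, which
is always feasible (predicting nothing has FDR 0).

The batch replacement for interactive threshold tuning is the `configure`
heuristic: thresholds at the per-feature 99th percentile of a
negative-control dataset, on the reasoning that a negative control should
yield ≈ 0% NETs. It is a starting point, meant to be refined by `autofit`.

## Embedding

Profiles are standardized per dimension (zero-variance dimensions left at
zero) before embedding. PaCMAP is used when the `pacmap` package is
importable; otherwise the first two principal components are used, with the
method recorded in the result and a warning emitted — the fallback is never
silent. Under PCA the component signs are fixed deterministically
(largest-magnitude loading positive) so coordinates reproduce across
platforms. Clusters are an external input — polygons (simple, boundary
inclusive, first match wins) or a label vector — mirroring manual selection
of apparent clusters; no automatic clustering is performed.

## Synthetic fixtures

The generator emulates the two stain patterns at the level the algorithm
consumes: neutrophils as concentric DNA/protein disks (DNA radius 5–6.5 px,
protein 9–11 px), NETs as star-like blobs `r(θ) = r₀(1 + irregularity ·
Σ low-order sinusoids)` (r₀ 11–13 px, irregularity 0.5, seeded phases) with
protein halos 4–5 px larger at 70% intensity (diffuse relative to cell
bodies). Objects sit on a seeded, jittered grid whose pitch guarantees
center separation greater than twice the worst-case radius, so fields never
contain accidentally merged objects; merged-object behavior is tested with
explicitly constructed fixtures instead. Gaussian read noise (sd 60 on a
16-bit scale, ~2% of the DNA foreground mean 3000 over background 100) is
applied last; Poisson noise is available but off by default to keep
exact-count tests stable. The NET count per field is `round(n_cells ·
net_fraction)` — fixed, not binomial — so the true NET percentage of a
fixture is known exactly.

Default study conditions used by the test suite and the acceptance script:
768×768 px fields with 67 objects each (three fields ≈ 200 objects), 30%
NETs, seeds fixed in the callers. With these geometries the NET and
neutrophil distributions of `protein_area` and `dna_radius_std` are
separated by more than three population standard deviations, which is what
entitles the tests to demand perfect training accuracy from `auto_thresholds`.

What the generator does **not** emulate: intact-NETotic intermediates,
overlapping or embedded cells, clusters of nuclei inside one NET, uneven
illumination, out-of-focus light, or camera-specific noise. Passing tests
demonstrate algorithmic correctness on the model's own terms, not
performance on real micrographs — on real data the feature distributions
overlap and accuracy is an empirical question for annotation-based
validation.

## Degenerate inputs and numerical notes

* Constant channel → empty mask + warning (Otsu) or all-pass/all-fail by
  the rule (adaptive); blank fields yield zero objects, not errors.
* Empty datasets and all-excluded datasets run to completion with flagged
  zero summaries.
* All tie-breaks (Otsu argmax, overlap assignment, largest-component choice,
  fitting candidates) resolve deterministically and are documented at the
  definition site.
* CSV outputs are sorted on (dataset, field, object id) with zero-padded
  object indices; two runs with identical inputs, configuration and seeds
  are byte-identical.

## Known limitations

* Physical pixel size is ignored; features are in pixel units and
  thresholds are protocol-specific.
* The deformation measure uses the largest DNA component only; fragmented
  chromatin contributes to areas and radius spread but not to deformation.
* Multi-annotator disagreement is surfaced, not adjudicated.
* 3-D stacks, deconvolution, illumination correction and learned
  segmentation are out of scope.
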
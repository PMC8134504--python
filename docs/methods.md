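# Methods

This note documents the models, conventions and numerical choices behind
`mammoquant`, and what the synthetic benchmarks do and do not demonstrate
about real data.

## Whole-mount segmentation

The chain is fixed in order: gamma adjustment → PCA grayscale → CLAHE →
wide-Gaussian background subtraction → Otsu binarisation → closing →
small-object removal → nipple-component selection.

*Gamma (default 0.45).* Applied to the globally min-max-normalised RGB
image. Normalising first means any positive affine transform of the raw
intensities (scanner gain/offset) cancels before the non-linear step, so
the final mask is invariant to such transforms; this is tested. Gamma can
be excluded from the analysis chain (`apply_gamma=False`) for users who
treat it purely as a display aid.

*PCA grayscale.* The projection onto the first eigenvector of the 3×3
pixelwise RGB covariance concentrates the stain contrast in one channel.
The eigenvector's sign is arbitrary, so it is oriented to correlate
positively with Rec. 709 luminance — carmine-dark epithelium is then always
the low/"foreground" class downstream. A constant image has zero
covariance and raises a degenerate-input error.

*CLAHE.* Tile 64 px with scikit-image's fractional clip limit, default
0.01. Higher clip limits amplify pure-stroma noise tiles to full range
and destabilise the global Otsu cut; 0.01 preserves local contrast
enhancement without that failure mode at ~10 µm/px scan scale.

*Background subtraction.* `img − gaussian(img, σ)` with reflective
boundaries, σ = 20 px. Not idempotent; applied exactly once in the chain.

*Otsu.* Implemented directly on an explicit histogram (256 bins over the
observed range) so the tie-break is defined: the lowest cut maximising
between-class variance. A property test checks exact agreement with an
exhaustive search over random histograms.

*Cleanup.* Closing (disk, radius 2 px) repairs noise-pitted duct walls;
components below 64 px are dropped; the component nearest the nipple is
kept and the nipple snapped onto it. Radius 0 skips the closing — on a
noiseless two-level scan the chain then reproduces the true mask exactly,
while the default radius trades a fraction of a percent of Dice (fork
crotches get filled) for robustness to noise.

*Lymph node.* The node is usually the darkest feature. Multilevel Otsu is
swept over k = 2…6 classes; connected components of the darkest class
outside the tree mask are scored `solidity × exp(−(area − A₀)²/(2τ²))`
(defaults A₀ = 2000 px, τ = 1500 px, acceptance 0.8, minimum 50 px). The
first accepted component wins, else the global best, else the node is
reported absent — a valid outcome, since "loop until the boundary is
right" is not an algorithm. The score is an explicit, tunable stand-in for
that visual judgement.

## Morphometrics

*Boundary and area.* The tree outline is a concave hull of the mask's
boundary-pixel centers, computed with GEOS (`shapely.concave_hull`) using
`ratio = 1 − shrink_factor`, so shrink 0 is the convex hull and 1 the
tightest outline; default 0.5. The hull is buffered by 0.5 px with mitre
joins so pixel squares (not centers) are covered — a filled n×n mask
yields exactly (n·px)² of area. We chose the GEOS hull over a hand-rolled
alpha shape for robustness; the shrink-factor semantics are identical.

*Extension.* Max distance from the nipple to a boundary vertex; the
arg-max vertex is the leading edge. Monotone under adding farther
vertices; matches a brute-force vertex scan by construction (tested).

*Branch points.* Topology-preserving thinning; raw forks are skeleton
pixels with ≥ 3 skeleton neighbours (8-connectivity). Thinning produces
small clusters of such pixels at real forks, so raw points are merged by
single-linkage clustering at the merge radius (default 5 px) to their
centroid. "Manual refinement" is an explicit exclusion list: merged
points within the merge radius of an exclusion are dropped, keeping the
correction auditable and replayable. All merged, non-excluded forks count
as primary branches; no Strahler-style hierarchy is imposed.

*Dirichlet territories.* Voronoi cells of the branch points, clipped to
the boundary polygon; unbounded cells never escape the gland. Cell areas
are matched to sites by point-in-cell tests; duplicates and out-of-bounds
sites are errors. Areas sum to the boundary area (conservation is
tested against a 2000×2000 nearest-site grid oracle). The CV of the
areas summarises branching evenness.

*Signed node distance.* Both the leading edge and the node centroid are
projected on the unit nipple→leading-edge axis; the difference (µm) is
positive once the growth front passes the node. Rotation-invariant by
construction (tested to 1e−6 relative).

## Cyst intensity and protrusion dynamics

Masks are inputs, as in outlined-region practice; automatic protrusion
segmentation is out of scope.

*Rim band.* The "body restricted to 10 µm around the mask" is a band:
dilation of the body by round(width/px) px (disk) minus body minus
protrusions. It equals the set of non-body pixels within the width of the
body (distance-transform identity, tested).

*Size-matched region.* The compared body region is the connected run of
band pixels nearest the protrusion root (the band pixel closest to the
protrusion), grown in geodesic order along the band until it matches the
protrusion's pixel count. If the band is smaller than the protrusion the
whole band is used and a warning logged. This keeps the comparison local
and insensitive to total band size.

*Background correction.* `correct_background` subtracts a wide Gaussian
(default σ = 50 px) and clips at zero. It is a preprocessing step for
images with shading, and is deliberately *not* applied inside the ratio
computations by default: on an evenly illuminated scene, high-pass
subtraction brightens structures jutting into dark matrix relative to
structures embedded in signal, biasing protrusion/body ratios upward by
tens of percent. Callers with shaded images pass a sigma explicitly or
pre-correct the channel. The correction is accurate (region means
preserved within 2%) when structures are small relative to σ.

*Tracking.* Greedy frame-to-frame linking by IoU (default threshold 0.3),
highest IoU first. Tracks are contiguous: one missed frame closes a track,
matching retraction semantics; a reappearing protrusion is a new track.
Lifetime counts both birth and death frames times the frame interval.
Length is the maximum geodesic distance from the body boundary within
body ∪ protrusion, so curved protrusions are measured along their extent.

## Proteomic screen

Pipeline order: impute → group-zero filter → summed-EIC normalisation.
Filters always act on the pre-imputation zero flags (`original_zero`),
never on current values. The order is configurable; imputation first
matches the description of the clustering preprocessing, and the filter is
order-independent because it reads only the flags.

*Imputation.* Zeros become half the global minimum positive intensity;
idempotent; flags preserved.

*Differential calls.* For a pairwise comparison, proteins observed
(nonzero pre-imputation) in fewer than 3 of the pooled 10 samples are
excluded; we read the "3 of 10" rule as the two 5-sample groups pooled.
Welch's unequal-variance two-tailed t-test per protein; both groups
constant and equal gives p = 1 by convention. Log2 ratios use
post-imputation group means; a protein whose original values are all zero
in exactly one group gets the ±10 sentinel instead ("uniquely observed"),
and |log2| is capped at 10. Significance: p < 0.05 or |log2| ≥ 2.
Q-values default to Benjamini-Hochberg; a Storey π₀-smoother variant is
available since the original analysis used an external q-value service
whose exact variant is unknown.

Welch's test with n = 5 per group is intrinsically slightly conservative
(measured size ≈ 0.041–0.046 at the generator's default 25% CV log-normal
noise, vs ≈ 0.044 even for near-normal data), which the type-I-error
check reflects.

*Clustering.* Sample profiles, distance 1 − Pearson r, average linkage
(UPGMA) via scipy; deterministic tie behaviour by sample index; Newick
export for interoperability. The optimal-cluster-number question is
exposed only as a pluggable hook (silhouette by default) and is not part
of the validated surface.

*Stage classifier.* scikit-learn random forest: bootstrap resampling,
√p feature subsets, default 5000 trees, single integer seed; per-sample
class probabilities are the fraction of trees voting, and out-of-bag
accuracy is reported. Training requires exactly two labelled stages with
≥ 2 samples each.

*Group comparisons.* One-way ANOVA with Tukey-Kramer adjusted pairwise
p-values (scipy's studentized-range implementation; unequal n supported);
two-sided Wilcoxon rank-sum (exact for small untied samples); tie-corrected
Kruskal-Wallis with hand-implemented Dunn z-tests (raw and
Bonferroni-adjusted p-values) since no installed package provides Dunn's
procedure.

## Synthetic generators

The generators define the benchmark conditions; their defaults are fixed,
not tuned per test.

*Whole mounts.* 512×512 px at 10.5 µm/px (a 2400 dpi scan), tree intensity
60 vs stroma 200 with additive Gaussian noise sd 8 (8-bit, clipped —
noise tests use sd small relative to the 140-level contrast), 7
bifurcations, segment length 60 px with 0.88 per-generation decay, branch
angle 46°, duct width 5 px, one lymph node (intensity 30, radius 28 px).
The tree is a breadth-first bifurcating random walk with jittered angles;
segments are rejection-sampled (re-jittered, progressively shortened) so
that unrelated ducts keep ≥ 6 px clearance — overlapping ducts are exactly
the artefact that manual refinement removes in practice, and keeping the
layout overlap-free gives an unambiguous branch-count truth. A jammed
layout is re-drawn (deterministically, up to 8 times) before failing with
a generation error naming the offending segment. Truth branch points are
the recorded fork centers of the *rendered* tree: the centerline junction
plus h/tan(spread) along the parent direction (h = duct half-width), which
is where ducts of finite width visibly separate. Truth area and extension
are measured on the rendered mask (boundary-hull area; brute-force
boundary scan).

*Cysts.* A disk body (radius 60 px at 0.65 µm/px) whose reported mask is
drawn just inside the outer cell layer: fluorescent signal extends a
20 px shell beyond the mask, as an analyst's outline does, so the rim
band samples real signal. Protrusions are straight fingers at evenly
spaced angles (they never touch), intensity = ratio × body, present
exactly in frames [birth, death]. Truth lifetime is
(death − birth + 1) × interval; truth length is the finger length in µm.

*Abundances.* Per-protein log-baselines ~ N(13.8, 1.5²) (natural log,
spanning orders of magnitude), within-group noise sd 0.25 (~25% CV, a
typical label-free replicate CV), three groups × five samples, Bernoulli
dropout to exact zeros with provenance flags. Planted effects multiply one
group's values for chosen proteins; the expected log2 ratio is exact
because the effect is multiplicative.

*What passing does not show.* The generators omit stromal texture,
stain gradients, duct-width variation, TEB bulbs, overlapping independent
ducts, out-of-focus light, protrusion curvature and breathing, and the
correlated missingness of real label-free data. Recovery on these scenes
validates the measurement chain's correctness, not its robustness to
every real-world artefact; the exclusion-list mechanism exists precisely
for the artefacts the generator excludes.

## Problem sizes

The default benchmark sizes — 20 whole-mount seeds at 512², 20 cyst seeds
at 224², 2000-protein null matrices, 100 random histograms, a 2000×2000
Voronoi oracle grid, 1000-tree forests in tests (5000 remains the
analysis default) — were chosen so the full suite and the acceptance
script each complete in about a minute on one CPU while keeping every
statistical check well-powered.
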
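# Methods

`dicentric` scores dicentric chromosomes in Giemsa-stained metaphase
micrographs and converts the per-cell dicentric yield into an absorbed
radiation dose. This note records the model, the choices behind each stage,
and what the synthetic benchmarks do and do not establish.

## Scoring pipeline

### Foreground segmentation

Pixel intensities are clustered with k-means++ (k = 2, at most 40 iterations
with a 1.0-gray-level convergence epsilon, best of 3 restarts by
within-cluster sum of squares). Clustering runs on the 256-bin intensity
histogram with bin counts as sample weights, which is exact for 8-bit images
and independent of image size. The lower-mean cluster is the chromosome
foreground (Giemsa stains chromatin dark); a uniform image cannot be
clustered and returns an all-background mask with a warning. 8-connected
components below `min_area_px` (default 20 px) are discarded as stain
impurities. Objects are numbered 1..n by descending area.

### Clump triage

Each object is classified as a *single* chromosome, a *touching clump*
(separable), or an *overlapping/cross clump* (sent to a manual review
queue). The decision is topological:

* overlapping: the mask encloses a hole of at least `hole_min_px` (20 px) —
  the signature of two chromosomes crossing at a shallow angle — or its
  skeleton keeps at least 2 branch points *and* 4 endpoints after pruning
  twigs shorter than 9 px (an X shape);
* single: an unbranched skeleton (at most 2 endpoints), or a compact blob
  with solidity at or above 0.85;
* otherwise: touching clump.

Solidity alone cannot carry the decision: a strongly bent single chromosome
has solidity 0.5–0.7, well below any threshold that would still reject
clumps. Misrouting is self-limiting: a crossing sent to the splitter fails
(its stained cores are connected through the crossing) and lands in the
review queue anyway.

### Clump splitting: second-stage clustering + seeded watershed

Chromosome centers are stained darker than their edges, so k-means (k = 2)
restricted to the clump pixels and keeping the darker cluster "thins" every
chromosome to its core and breaks the light contact zones. If the cores stay
connected, the clustering is re-run with k = 3 keeping only the darkest
cluster (a thinner core) before giving up.

A chromosome's own core can also break where the stain lightens at a
centromeric constriction. Core fragments are therefore re-merged when the
gap between them is short (≤ 9 px) and runs *along* both fragments' local
axes (|cos| ≥ 0.7 between the gap direction and a principal-axis fit of the
fragment pixels within 8 px of the gap — a radius of about one band width,
so blunt fragment tips do not dominate the fit). Genuine contact between two
chromosomes is side-on and never merges. Borderline pairs (|cos| ≥ 0.5)
merge only if dilating their union bridges them into a single unbranched
band; side contacts form a branched T union instead.

The retained cores are the watershed seeds. Seeds grow simultaneously,
ring by ring, geodesically inside the clump mask (8-connected); a pixel
first reached on a given ring takes the smallest label among its
already-labeled neighbors. This equals a multi-source geodesic BFS with
ties broken toward the lower seed id — the property the test suite checks
against a brute-force oracle — and partitions the clump exactly, so the
split chromosomes keep the full original outline.

### Centerline

A chromosome whose minimum-area rotated bounding rectangle is at least 80%
filled is straight: its centerline is the rectangle's long symmetry axis
sampled at unit steps and clipped to the mask. The rectangle comes from the
corners of the boundary pixels' unit squares, so a solid axis-aligned
rectangle has a fill ratio of exactly 1.

Bent chromosomes are thinned to a skeleton after a cleanup pass
(3×3 morphological opening, 3×3 median border smoothing, hole filling —
holes are filled *after* the working crop so no enclosed pore survives to
make thinning cyclic). Side branches are pruned shortest-first until exactly
two endpoints remain; small cycles, which thinning occasionally leaves even
in hole-free masks, are broken and pruning continues. The path is then
extended at both ends along a total-least-squares slope fitted to the last
5 points, in unit steps while inside the mask (at most 20 px), because
thinning systematically stops short of the chromosome tips.

Finally the path is recentered: each point slides along its normal to the
midpoint of the perpendicular mask chord (two passes, recomputing normals
in between). This matters because thinning cuts the inner corner of bends,
and an off-center point inflates the distance-weighted width score below —
the sum of |t| across the chord grows with the square of the displacement —
which otherwise fakes width bumps at bends. Normals are perpendicular to
central-difference tangents over a 5-point window.

### Equivalent width and centromere detection

At each centerline point P_i the normal is walked in unit steps in both
directions; each step inside the mask contributes its nearest pixel's
inverted gray G = 255 − M at distance D from P_i. Background pixels never
contribute — with G = 255 − M a background pixel would otherwise contribute
the maximal value and invert the signal's meaning. The equivalent width is

    Y_i = Σ_j D_ij^m · G_ij^n        (defaults m = 1, n = 1; 0^0 := 1)

so with m = n = 0 it degenerates to the plain pixel-count width. A
centromere is both narrower and more lightly stained, so it is a local
minimum of Y.

Detection: (1) moving-average filter the profile (window 9 points — true
constriction dips are 8–10 px wide and survive, while the ~4-px lattice and
bend ripples that caused false calls at window 5 are suppressed); (2) fit an
ordinary-least-squares trend line and form the difference curve
trend − filtered; (3) differentiate and filter again to localize extrema;
(4) for each local minimum of the filtered profile measure the prominences
A and B to the nearest local maximum on the left and right (the profile end
value if a side has none); (5) accept when (A > T or B > T) and (A > T/2 and
B > T/2). Minima within 15% of either profile end are not candidates
(telomere ends taper and ripple); accepted minima closer than 10% of the
profile length merge, keeping the larger min(A, B). The count classifies the
chromosome: 0 none, 1 monocentric, 2 dicentric, ≥3 multicentric. A
configuration switch measures minima on the difference curve instead of the
filtered profile; the default is the filtered profile.

The threshold adapts to each chromosome: T_eff = T_rel · median(filtered
profile), T_rel = 0.45. Equivalent-width units scale roughly quadratically
with band width, so no single absolute T separates shallow ripples on wide
chromosomes from true centromere dips on narrow ones. T_rel was calibrated
once on a 200-phantom calibration corpus (seeds disjoint from every test
seed): accuracy plateaus over T_rel ≈ 0.30–0.65 and 0.45 is the plateau
midpoint. An absolute threshold (`T`, default 1200) is available by setting
`T_rel = None`.

### Dose estimation

With X dicentrics in M cells the yield is Y = X/M, inverted through the
linear-quadratic calibration curve Y = C + αD + βD² as

    D = (−α + sqrt(α² + 4β(Y − C))) / (2β).

The bundled gamma-ray curve is C = 0.000105, α = 0.0186 Gy⁻¹,
β = 0.0217 Gy⁻². Yields below C (possible at X = 0) give D = 0 with a
below-background flag. The 95% confidence interval uses the classical
tabulated Poisson limits (X_L, X_U) on an observed count, shipped verbatim
as `data/poisson_limits_table1.csv` for X = 0..159 and treated as canonical
(the table's Crow–Gardner-style construction produces tied, stepwise values
that a chi-square recomputation would not reproduce exactly). Y_L = X_L/M
and Y_U = X_U/M are pushed through the same inversion; calibration-curve
error is ignored (Merkle's simple variant). Counts beyond the table raise an
error by default; an explicit opt-in computes exact chi-square limits,
clearly not from the table. Simulated coverage at 2 Gy with 500 cells is
≈95%, checked at ≥93% to allow sampling error.

## Synthetic phantoms

No public corpus of scored Giemsa metaphases exists, so all benchmarks run
on rendered phantoms with exact ground truth. Each chromosome is a cubic
Bézier spine of bounded curvature; the band's half-width narrows by a
Gaussian bump (σ = 5% of arc length) at each centromere, the stain lightens
by +40 gray levels there, and the stain lightens quadratically toward the
band edge by up to +60 — the darker-core/lighter-edge structure the clump
splitter exploits, as in real Giemsa material. Defaults model a human
metaphase: 46 chromosomes of 45–90 px length and 7–11 px width on a
640×640 field, background 220±8, band cores 60±6, constriction depth 0.5,
10% of chromosomes placed in deliberate side contact, small dark specks as
impurities. Touching contacts are placed end-to-side and roughly transverse
(a T topology); end-to-end unions are excluded because they are
indistinguishable from one long chromosome by any segmentation method.
Crossings (overlap fraction) are off by default and used only in targeted
tests.

What the phantoms do not emulate: banding patterns, sister-chromatid
substructure, acentric fragments and other aberration types, nuclei and
cytoplasm, optics (defocus, vignetting, uneven illumination), and realistic
morphological variation of clumps. Passing benchmarks therefore demonstrate
the internal consistency of the pipeline under controlled conditions, not
clinical performance; the same pipeline on real slides would face harder
segmentation and an unknown error profile.

## Benchmark problem sizes

The acceptance checks use 200 single-chromosome phantoms (alternating
mono/dicentric) for classification accuracy (≥95%), 50 default-condition
metaphases for exact per-image dicentric-count recovery (≥80%), 100 random
masks up to 64×64 for watershed/BFS equality, and 1000 Poisson replicates
for interval coverage. These sizes give binomial standard errors of 1.5–6%
on the measured rates, adequate for the thresholds checked.

## Known limitations

* Overlapping/cross clumps are never resolved automatically; they are
  exported to a review queue, so dicentrics inside them are not counted
  until a human scores them. In the phantom benchmark this, plus occasional
  mis-splits of clumps whose cores break awkwardly, accounts for most
  per-image count misses.
* The end-margin exclusion (15%) means a genuinely near-telomeric
  constriction would be missed.
* Dose estimation assumes whole-body exposure (plain Poisson); partial-body
  (contaminated Poisson) models and curve-error-inclusive confidence
  intervals are out of scope.
* The dose table covers X ≤ 159; larger counts require the explicit
  chi-square opt-in.
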
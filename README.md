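# dicentric

Automated scoring of dicentric chromosomes in metaphase micrographs, and
cytogenetic radiation dose estimation from the resulting counts.

A dicentric chromosome — an aberrant chromosome with two centromeres, formed
when misrepair joins two broken chromosomes — is the classical biological
dosimeter: its frequency per cell rises with absorbed radiation dose. Manual
scoring of Giemsa-stained metaphase spreads is slow, so this package
automates the chain from raw micrograph to dose:

1. **Segmentation** — k-means++ intensity clustering (k=2) separates dark
   chromosomes from the light background; connected components below an area
   cutoff are dropped as stain impurities.
2. **Clump handling** — objects are triaged by shape topology. Touching
   clumps are split by a second, clump-local k-means that keeps only the
   darker chromosome cores, then regrown to the full outline with a seeded
   watershed (simultaneous ring-by-ring geodesic growth, ties to the lower
   seed id). Overlapping/cross clumps go to a `review_queue/` for manual
   scoring.
3. **Centerline** — straight chromosomes take the long axis of their
   minimum-area bounding rectangle; bent ones are thinned to a pruned
   skeleton, extended to the chromosome tips along the end slope, and
   recentered on the perpendicular mask chord.
4. **Centromere detection** — along the centerline, the *equivalent width*
   combines geometric width and staining depth:

       Y_i = Σ_j D_ij^m · G_ij^n ,   G = 255 − M   (defaults m = n = 1)

   summed over the perpendicular chord at point i. Centromeres are
   constrictions: local minima of the filtered profile whose prominences
   A (left) and B (right) satisfy (A > T or B > T) and (A > T/2, B > T/2).
   Two accepted minima ⇒ dicentric.
5. **Dosimetry** — with X dicentrics in M cells, the yield Y = X/M is
   inverted through a linear-quadratic calibration curve
   Y = C + αD + βD² (bundled gamma curve: C = 0.000105, α = 0.0186 Gy⁻¹,
   β = 0.0217 Gy⁻²). 95% confidence limits come from the classical
   tabulated Poisson limits on X (bundled for X = 0..159), divided by M and
   pushed through the same inversion.

Because no public corpus of scored metaphases exists, the package ships a
synthetic phantom generator (`dicentric.phantoms`) that renders
Giemsa-like metaphases — dark bent bands with width-and-stain constrictions
at known centromere positions, controlled touching/crossing contacts,
background noise and impurity specks — with exact ground truth, so every
stage is benchmarked end to end. See `docs/methods.md` for the model,
parameter rationale, and what the phantom benchmarks do and do not show.

Intended users: researchers in biological dosimetry and chromosome image
analysis who want a tested, scriptable reference pipeline.

## Worked example

Generate five synthetic metaphases with ground truth, score them, and
compare the detections against the truth:

```bash
dicentric phantom generate --out phantoms --n-images 5 --seed 7
dicentric score --in phantoms --out results --seed 7
dicentric evaluate --phantom-dir phantoms
```

The score step writes per-object crops and JSON records under
`results/objects/`, unsplittable clumps to `results/review_queue/`, one CSV
row per metaphase to `results/cells.csv`:

```
image_id,n_objects,n_dicentrics,n_flagged
phantom_10,45,2,1
phantom_11,47,3,0
phantom_7,46,2,0
phantom_8,40,2,2
phantom_9,46,3,0
```

and a cohort dose estimate to `results/dose_estimate.json`. Each phantom
was generated with 2 true dicentrics among 46 chromosomes; two images here
picked up one false positive each, and `n_flagged` counts clumps exported
for manual review. The evaluate step prints detection metrics against the
generated truth:

```json
{"TPR": 1.0, "PPV": 0.8333333333333334, "tp": 10, "fp": 2, "fn": 0}
```

(TPR: detected true dicentrics / all true dicentrics; PPV: detected true
dicentrics / all detections; a detection matches truth at mask IoU ≥ 0.5.)

For dose estimation from counts alone — say 40 dicentrics found in 500
scored cells:

```bash
dicentric dose-estimate --dicentrics 40 --cells 500
```

```json
{
  "X": 40, "M": 500,
  "Y": 0.08,
  "D": 1.5375,
  "Y_L": 0.05794, "Y_U": 0.10744,
  "D_L": 1.2593, "D_U": 1.8364,
  "below_background": false
}
```

Read: a yield of 0.08 dicentrics/cell corresponds to an estimated acute
gamma dose of 1.54 Gy, with a 95% confidence interval of 1.26–1.84 Gy from
the Poisson uncertainty on the count of 40 (tabulated limits 28.97–53.72),
ignoring calibration-curve error.

The same functionality is available as a library:

```python
from dicentric.phantoms import PhantomSpec, make_metaphase
from dicentric.pipeline import process_image
from dicentric.dosimetry import confidence_interval

image, truth = make_metaphase(PhantomSpec(rng_seed=7))
result = process_image(image)
print(result.cell.n_dicentrics, truth.n_dicentrics)
est = confidence_interval(X=40, M=500)
```

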
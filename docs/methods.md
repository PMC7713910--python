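# Methods

`pitfallid` implements a feature-vector identification pipeline for bulk
invertebrate samples: many specimens from one pitfall-trap collection event
are photographed together (dorsal and ventral), each specimen is segmented
and measured, and classical machine-learning classifiers are trained on the
resulting 68-variable morphometric/color vectors. This note records the
models, conventions, parameter choices, and the limits of what the synthetic
validation shows.

## Image measurement

Segmentation thresholds a batch image to dark-object foreground, either with
a global Otsu threshold on luminance (default; operator-free and
reproducible) or with manual per-channel bands that mirror interactive color
thresholding. Connected components are 8-connected; components below
`min_area_px` (default 50 px) are treated as debris. Coordinates are
0-based, row-major, origin top-left; bounding boxes are half-open.

Per region, the size/shape descriptors are the classic particle-analysis
set, in millimetre units via the known pixels-per-mm scale:

* **area** = pixel count / resolution²;
* **perimeter** from the 8-direction chain code of the Moore-traced outer
  boundary, axial step 1 and diagonal step √2, scaled by the 0.948 corner
  correction. That factor is exactly the reciprocal of the mean chain-code
  overestimate for straight edges at uniform random orientation
  ((4/π)·∫₀^{π/4}(cosθ+(√2−1)sinθ)dθ ≈ 1.055), the same convention behind
  ImageJ-style traced perimeters. Interior holes are not traced;
* **width/height** as bounding-box extents;
* **Feret / min Feret** as the max/min caliper diameters of the convex hull
  of the pixel *corner* points (each pixel treated as a unit square).
  Corner-point hulls make a filled axis-aligned rectangle's solidity exactly
  1 and avoid the systematic >1 solidities that pixel-center hulls give
  small regions;
* **major/minor/angle** from the ellipse with the region's second-order
  central moments, each pixel contributing a unit-square term (+1/12 per
  axis); axes are 4·√λ of the covariance eigenvalues, angle measured
  counter-clockwise from the x-axis in degrees [0, 180);
* **circularity** 4π·area/perimeter², **aspect ratio** major/minor,
  **roundness** 4·area/(π·major²), **solidity** area/hull area.

Single-pixel or collinear regions have no meaningful ellipse or hull and
raise a degenerate-geometry error rather than returning junk.

Color statistics per RGB channel over region pixels use population moments:
mean, sd, integrated density (pixel count × mean), skewness m₃/m₂^1.5,
excess kurtosis m₄/m₂²−3, min and max. Zero-variance regions define
skewness and kurtosis as 0.

Dorsal/ventral pairing mirrors the ventral centroids horizontally (the
ventral photograph is the physical mirror of the dorsal layout) and solves
the minimum-total-centroid-distance assignment (Hungarian). For the
grid-like layouts this pipeline targets, that coincides with reading-order
matching; a count mismatch is an error that names the unmatched regions. A
per-image linear white-balance hook exists but defaults to identity;
physical color-chart calibration is out of scope.

## Data preparation

Species with fewer than 31 observations (i.e. ≤ 30) are set aside: too few
to train on, but retained as "novel" species for the open-set evaluation.
The remaining table is split 70:30 into train/test by simple random
sampling, repeated 10 times. Splits are deliberately *not* stratified, so
training compositions vary between repeats; a species that misses a
training subset entirely is recorded as a warning. Features are z-scored
with the per-feature mean and sample (ddof = 1) standard deviation of the
**training rows only** — fitting the scaler on the pooled split is available
as an explicit fidelity flag, since protocols that standardize before
splitting leak test statistics. Constant features are centered and passed
through with scale 1, with a warning.

## Classifiers

Five families, all consuming the standardized vectors and all emitting a
specimens × classes probability matrix whose rows sum to 1:

| family | probability semantics | tuned parameter |
|---|---|---|
| KNN | neighbor-vote fractions, Euclidean distance | k ∈ 1..25 |
| LDA | shared-covariance Gaussian posterior | — |
| NB  | per-feature Gaussian naive Bayes posterior | — |
| RF  | 500 trees, tree-averaged class probabilities | mtry ∈ 1..10 |
| ANN | one logistic hidden layer, softmax outputs | hidden ∈ 1..25 |

Gridded algorithms pick the value maximizing top-1 accuracy. The default
(`inner-cv`) uses 5-fold cross-validation inside the training set. A
`paper-fidelity` mode instead selects on a supplied evaluation set —
reproducing protocols that tuned on the test split — and marks the fitted
model's metadata with `leakage: True` so reports stay honest about it.

The ANN is trained with L-BFGS; the stopping rule is loss change < 1e-5 or
10,000 epochs, and hitting the epoch cap counts as a stop. Genuine optimizer
failures (non-finite loss) get up to 3 seeded restarts, then an error. A
singular LDA within-class covariance triggers a ridge-shrinkage refit with a
warning. Random-forest probabilities are scikit-learn's tree-averaged
probabilities; with fully grown trees the leaves are near-pure, so these are
effectively vote fractions.

Probability ties are broken by descending training-class frequency, then
lexicographic class name, making every top-k set deterministic. The chance
reference ("by chance") classifier always predicts the most frequent
training species, lexicographic-first on ties.

## Evaluation protocols

Five metrics: top-1 and top-3 accuracy, and macro-averaged precision,
recall and F1. Macro averages run over the union of classes present in the
truth or the predictions of that repeat; a class never predicted has
precision 0, and F1 is 0 where its denominator vanishes. Reported values
are means of per-repeat metrics, never metrics of pooled predictions.

**Hierarchical.** One species-level model per repeat; its ranked species
predictions and the true labels are lifted through the taxonomy to each
higher rank. Duplicate lifted labels collapse to their best-ranked
occurrence before counting top-k, so "top-3" always means three *distinct*
taxa. Lifting can only merge distinct wrong species into the right higher
taxon, so top-1 accuracy is non-decreasing in rank — a structural
invariant, tested per repeat.

**Single-level.** A fresh model per rank, trained on labels relabeled at
that rank and scored only there. To keep a 6-rank × 10-repeat × 5-algorithm
run tractable, each single-level model reuses the hyperparameter selected
at species level for the same repeat rather than re-running the grid; ranks
with a single class report trivially perfect metrics and are flagged
`degenerate`. At the species rank the two modes are the same model by
construction.

**Local species pools.** Each collection site has a known species pool.
Classes outside a specimen's site pool are removed and the survivors keep
their original probability ordering (renormalized for reporting). Rows with
zero probability mass inside the pool are ranked by training-class
frequency — a deterministic, documented fallback. Sites whose pool
intersected with the model's classes contains exactly one species are
guaranteed perfect accuracy and are excluded from the pooled local
statistic (their per-site value is still reported). Local accuracy is a
species-level quantity only.

**Novel species.** Models are forced to make species-level calls on the
rare species they never saw. A rank is measurable for a specimen only when
its true label at that rank is shared with at least one training species;
accuracy is reported per rank over measurable specimens, together with the
measurable counts.

## Synthetic data

The generator emulates the statistical shape of a continental pitfall-trap
survey rather than its pixels:

* **Taxonomy** — a random nested hierarchy with configured taxon counts per
  rank. The full-scale emulation preset uses 64 species, 32 genera, 19
  tribes and 8 subfamilies, 3,270 specimens across 18 sites and 398
  trapping events. Surjectivity is built by anchoring each higher taxon
  with one low-index (abundant) species and attaching the remainder at
  random, so rare species usually share their genus with a common anchor —
  as in real surveys, and necessary for the novel-species protocol to have
  measurable ranks.
* **Features** — per-species class-conditional Gaussians in the 68
  dimensions. Species means are built by a random-walk drift down the
  taxonomy (per-rank drift sds, defaults 0.15/0.05/0.35/0.2/0.25/0.4 from
  species to subfamily, within-species sd 1), so congeners sit closer than
  cross-tribe species and most confusion happens inside the genus/tribe —
  the same error structure the real pipeline shows. The default scales were
  chosen once to land species-level top-1 in the 0.8–0.9 range at the
  reduced scale, leaving visible headroom for the local-pool and
  hierarchical effects.
* **Abundance** — geometric rank-abundance law (log-series available). The
  emulation preset's ratio 0.91 puts ~60% of species at ≤30 observations,
  leaving ~25 trainable species; the reduced preset (600 specimens, 12
  species, ratio 0.8, 12 sites) leaves ~7–8.
* **Sites** — pool sizes lo + Binomial(hi−lo, p) with mean 3 in [1, 7];
  every observed species is guaranteed a site, pools are topped up with
  abundance-weighted extras, and each specimen lands uniformly on a site
  containing its species.
* **Images** — specimens rendered as rotated ellipses with per-specimen
  size and dorsal/ventral colors on a lightly textured near-white
  background, dorsal/ventral pairs mirrored. Ground truth (area, axes,
  aspect, mean colors, layout centers) is analytic, which is the point:
  testability outranks realism.

Everything is deterministic under a fixed seed, byte-for-byte.

What passing these tests shows — and does not. The synthetic features match
the *assumptions* of the classifiers (Gaussian classes, informative
everywhere), so synthetic accuracies are upper-bound-flavored and say
nothing about real accuracy on photographs of degraded specimens; the
rendered ellipses validate the measurement code, not robustness to glare,
shadows, touching specimens or pose variation. What transfers to real data
is the correctness of the measurements, the metric definitions, and the
protocol logic (lifting, pooling, novel-species bookkeeping), which are
exercised against analytic ground truth and brute-force oracles.

## Problem sizes and numerical choices

The standard desk-scale experiment is the reduced preset with 10 repeats,
all five algorithms, coarse tuning grids spanning each full range (k ∈
{1,3,5,9,15,25}, mtry ∈ {1,3,6,10}, hidden ∈ {2,6,12,20}) and
paper-fidelity grid selection; it completes in a few minutes on one CPU.
Full integer grids remain available through `ModelSpec`. Probability rows
are validated to sum to 1 within 1e-9; standardization is invertible to
1e-9; degenerate inputs (empty foreground, single-pixel regions, single
training class, unknown sites, infeasible pool ranges) raise typed errors
rather than propagating NaNs.

## Known limitations

* The perimeter estimator is a single global corner correction, not a
  per-configuration lookup; sub-percent biases remain for very small or
  very elongated regions.
* Dorsal/ventral matching assumes specimens are not repositioned between
  the two photographs beyond mirroring; heavily shuffled layouts would need
  the assignment cost to include size/shape terms.
* RF probabilities follow scikit-learn's tree-averaging convention.
* The generator's site pools are drawn independently of the feature
  distributions; real species pools correlate with geography and therefore
  with morphology in ways the synthetic data does not reproduce.
* On zero-signal data (all drift scales 0) no model beats the
  most-common-class baseline, but the flexible/parametric families (LDA,
  NB, the ANN) fit spurious structure in the 68 noise dimensions and land
  *below* it — several points below at desk-scale sample sizes. Only the
  one-sided statement "no signal ⇒ no advantage" is a reliable invariant;
  symmetric closeness to the baseline additionally needs sample sizes well
  beyond the feature count.
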
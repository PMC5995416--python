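# Methods

This note records the models, parameter defaults and numerical design
decisions behind `advafm`, in the package's own terms.

## 1. Synthetic topography (`advafm.synthetic`)

A fibril field is rendered as parallel half-cylinders (circular-segment
cross-section, apex height = radius) laid side by side perpendicular to a
mean orientation (default 30° ± 10° jitter per fibril). Centre-to-centre
spacing is `packing × (r_i + r_{i+1})`; the default `packing = 1.0` gives
the tangent, tightly packed regime typical of adventitia. The D-banding is
an axial raised-cosine *gap* pulse subtracted from the height: depth
20 nm, width `gap_fraction × D` (default 0.25), per-fibril random phase.
Fibril diameters follow a three-component Gaussian mixture (defaults:
means 101.5 / 133.3 / 165.7 nm, the low-stiffness group's weights
0.556 / 0.309 / 0.135; the high-stiffness preset shifts weight from the
thin to the middle component). The D-period is a single Gaussian
(62.4–62.5 ± 3 nm). Default scan geometry is 2 × 2 µm at 256 px/line
(7.8125 nm/px).

Realism limits: fibrils are straight and infinitely long, there is no
surface waviness, proteoglycan coating, tip-convolution or feedback
artefact, and noise is i.i.d. Gaussian. The renders are meant to exercise
the measurement chain, not to be photorealistic.

Force curves are forward-modelled from the same DMT law the fitting stage
inverts (64 points to 10 nm depth, adhesion −2 nN, optional Gaussian force
noise). The cohort generator draws per-patient PWV, true mean modulus,
per-image modulus means (within-patient SD = 0.5 × group SD), fibril
measurement populations with patient-level offsets, clinical covariates,
and seven SLRP abundances on a log2 scale with a −0.5 log2-fold shift in
the high group; a random ~12% of patients lack the whole proteomics panel.

**Seeding.** Every stochastic routine takes one integer seed; independent
substreams are derived as `sha256(f"{seed}:{name}") mod 2^31`, so streams
never collide and all derived seeds stay below 2³¹.

## 2. Morphometry (`advafm.morphometry`)

Pipeline: line-wise linear flattening → difference-of-Gaussians band
enhancement (detail σ 0.5 px minus background σ) → Otsu threshold →
optional morphological closing → 8-connected labelling with a 12-px area
floor → topology-preserving thinning → per-rectangle measurement →
validity filter (70–200 nm diameter, 45–80 nm D-period) → image QC.

Design decisions, with reasons:

* **Two-stage Otsu.** Band-enhanced packed fields are trimodal
  (inter-fibril grooves, gap zones, overlap zones); a single Otsu cut lands
  between the grooves and everything else. If the first cut leaves more
  than 55% foreground, Otsu is re-applied to the upper classes to separate
  gap from overlap. Bimodal images are unaffected.
* **Scale-aware defaults** (`MorphometryParams.for_scale`). The
  enhancement scale tracks D/4 in pixels. Closing (`seal_px = 1`) is only
  enabled when the D-period spans ≥ 12 px; at the native 7.8 nm/px scale a
  1-px closing bridges the 2-px grooves between adjacent fibrils and merges
  rectangles across fibrils, so sealing is off there.
* **Skeleton length = longest geodesic path.** Thinning a ragged rectangle
  leaves short side branches; total edge length overstates the rectangle
  length by tens of percent. The length used is the graph diameter of the
  8-connected skeleton (unit + √2 edge weights, double Dijkstra sweep —
  exact on trees, which thinned skeletons essentially are).
* **End-corrected joint solve.** Thinning shortens a w × l rectangle's
  skeleton to ≈ l − w, so the dimensions are recovered jointly from the
  geodesic length g and the pixel area A: `l = (g + √(g² + 4A))/2`,
  `w = A/l` (exact for ideal rectangles). Components with a point skeleton
  are measured as √A in both dimensions and flagged invalid.
* **Axis-aware assignment.** The dominant fibril axis is estimated from
  the image-averaged structure tensor (eigenvector of the smaller
  eigenvalue); the rectangle dimension within 45° of the axis is the
  length, the perpendicular one the diameter.
* **D-period as a repeat distance.** Rectangle length systematically
  underestimates D by the thresholded band-edge width (≈ 12–45% depending
  on scale). Whenever the axis is known, the D-period is measured as the
  centre-to-centre spacing to the nearest downstream rectangle of the same
  fibril (along-axis gap within 2 px … 2×80 nm, perpendicular offset
  < 0.4 diameters), which is immune to the threshold duty cycle. The
  compensated rectangle length is kept as `length_nm` and as the fallback.

Image QC flags a field unusable when the valid-segment fraction falls
below 0.25 or mask coverage below 0.2 (loosely packed or failed images);
unusable images are excluded from patient averaging.

Measured recovery on noiseless 512-px renders (20 seeds, seed 1):
median |relative error| 6.9% for diameter, 1.3% for D-period.

## 3. Nanomechanics (`advafm.nanomech`)

`F_adh` is the minimum recorded force; `F − F_adh` is regressed on
`δ^(3/2)` through the origin over the 10–90% window of the peak force above
adhesion (≥ 5 points required). `E_r = slope / ((4/3)√R · 10⁻³)` with the
MPa/nm/nN unit convention; `E = E_r (1 − ν²)`. Noiseless round-trip is
exact to machine precision over a grid of (E_r, R, F_adh).

Calibration against a reference sample of known modulus uses the median of
≥ 10 reference fits: `scale = E_known / median(E_measured)`, removing any
multiplicative gain error (deflection-sensitivity or spring-constant
miscalibration) exactly for noiseless data.

## 4. Cohort statistics (`advafm.cohortstats`)

All segment- and image-level measurements are averaged per patient before
group testing (measurements pool across a patient's usable images).

* **Mann-Whitney U** is exact for group sizes ≤ 12 without ties: the null
  distribution of U is built by the recurrence
  `N(u; n, m) = N(u − m; n − 1, m) + N(u; n, m − 1)` and the two-sided p is
  `2·min(P(U ≤ u), P(U ≥ u))` capped at 1. Ties or larger groups fall back
  to the tie-corrected normal approximation. The **Hodges-Lehmann** shift
  estimate is the median of all pairwise differences; the 95% CI takes the
  k-th and (nm+1−k)-th ordered differences with k from the exact (or
  normal) α/2 quantile of U.
* **Kolmogorov-Smirnov** (asymptotic p, ≥ 8 per sample) serves the pooled
  measurement-level distributions, where shape shifts can be significant
  even with equal means.
* **Spearman** uses the t-approximation, except for n ≤ 8 without ties
  where the full permutation null of the rank correlation is enumerated
  (the t-approximation is visibly off at such n).
* **Student's t** (pooled variance) covers clinical covariates, with an
  explicit degenerate branch for zero-variance inputs.
* **Benjamini-Hochberg** adjusts each analysis batch (statsmodels
  `fdr_bh`). Subgroup bins are half-open [lo, hi) with a closed last bin:
  diameter 70–120–150–200 nm, D-period 45–59–70–80 nm.

Under null simulation (n = 8/9, 1000 replicates) all three tests reject at
≤ 0.05 + 2 binomial SE; the exact/discrete tests are conservative by
construction, so rates sit slightly *below* 0.05 rather than within a
two-sided band of it.

## 5. Integration (`advafm.integration`)

The feature matrix is patients × (7 SLRPs, mean modulus, mean diameter,
mean D-period, PWV, age, BMI, total cholesterol, HbA1c); patients with any
missing value are excluded (≥ 3 complete required). PCA is mean-centred,
unit-variance (sample SD, n−1) via full SVD, with a deterministic sign
convention (the largest-magnitude loading of each component is positive;
scores flip accordingly). Group ellipses are normal-theory concentration
ellipses at level 0.67: centre = group mean, axes from the covariance
eigendecomposition scaled by √χ²₂(0.67). Empirical coverage on large
bivariate-normal draws is 0.671 (n = 40,000, seed 1).

## 6. Pipeline and IO

Simulated studies are laid out on disk as float32 TIFF height maps with
JSON calibration sidecars, long-format force-curve CSVs, a reference-curve
set with its known modulus, ground-truth tables, and a SHA-256 checksummed
manifest. Simulated force volumes are thinned to 16 curves per image (a
real map has 65,536); per-image modulus statistics are unaffected because
image means are drawn at cohort level. Analysis results are CSV tables with
a commented provenance header (`# advafm seed=N`).

## Limitations

* Generators and analyzers share the same forward models (DMT law, banded
  half-cylinder geometry), so recovery checks validate the inversion
  machinery, not model misspecification robustness.
* The exact Mann-Whitney implementation assumes no ties; continuous
  measurements make ties improbable but rounded inputs silently switch to
  the asymptotic path.
* Morphometry assumes a single dominant fibril orientation per image;
  crossing fibril plexuses would confuse the axis assignment.
* Clinical covariates are drawn independently per variable; real
  covariance structure (e.g. BMI-blood pressure) is not modelled.
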
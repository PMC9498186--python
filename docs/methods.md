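# Methods

## Measurement model

Every quantity is a first-order statistic of the gray values inside a pixel
region of an 8-bit frame. Regions are exact pixel sets; all accumulation is
integer (pixel count n, Σgray, Σgray²), so means, SDs and densities are
bit-for-bit reproducible and region subtraction is exact: the solid part's
moments are whole-lesion moments minus cystic moments, identical to
measuring the set-difference mask. Physical units enter only through the
calibration k (pixels/mm, default 12.2674, taken as given from the
machine's distance scale): area = n/k² mm², density = mean × k² Σgray·mm⁻².
The identity `density = mean × k²` is therefore structural, and is used
throughout the tests as the internal-consistency check connecting the
echogenicity and density columns of any results table.

### Conventions

* Pixel coordinates are (row, col), 0-based, with pixel centers at integer
  coordinates. One convention, used everywhere.
* Polygon rasterization: a pixel is a member iff its center is inside the
  polygon under the even-odd rule; centers exactly on an edge follow the
  half-open top-left rule (left/top in, right/bottom out). This makes the
  result orientation-independent and lets adjacent polygons tile without
  double-counting. An axis-aligned rectangle spanning centers r0..r1 ×
  c0..c1 rasterizes to exactly (r1−r0+1)(c1−c0+1) pixels.
* Region growing: the admissible set is anchored to the seed pixel's gray
  value, {p : |g(p) − g(seed)| ≤ T}, and the grown region is its connected
  component containing the seed. Anchoring to the seed (not a running mean)
  makes the result independent of visit order. Connectivity is 4 by default
  (prevents diagonal leaks through one-pixel walls; configurable to 8).
  Cystic growth is clipped to the lesion polygon by default — a cyst is
  part of the lesion — with a flag to disable.
* Multiple grown lobules are merged by union before measurement, so
  overlapping seeds never double-count pixels; the lobule count is the
  number of connected components of that union, not the number of seeds.
* SDs use the sample (n−1) denominator by default, matching mainstream
  image-measurement software; a switch selects the population form.
* Missing quantities (no cystic seeds, fully cystic lesion, no parenchyma
  block) are explicit missing values, never zeros.

### Degenerate inputs

Empty regions raise an empty-region error; SD needs n ≥ 2; a cystic part
that covers the whole lesion leaves the solid metrics missing rather than
producing a 0/0; a subtrahend mask with pixels outside its parent is
intersected first, with a warning carrying the discarded pixel count.

## Statistics

The two-sample route is gated on normality: Shapiro–Wilk at α = 0.05 on
each sample decides (the battery also reports Anderson–Darling,
D'Agostino–Pearson, and the Lilliefors form of Kolmogorov–Smirnov — the
composite-normality variant that mainstream packages implement — but these
do not gate; four tests with no stated combination rule cannot all gate).
Normal ⇒ Welch's unequal-variance t-test, the robust default when equal
variances are not asserted; otherwise a two-sided Mann–Whitney U (exact for
small tie-free samples, normal approximation with tie correction
otherwise). Samples below n = 8 (the smallest n at which all four battery
tests are defined) or constant samples route non-parametric with a warning.
Categorical composition uses Pearson's χ² without continuity correction,
warning when an expected count falls below 5. No multiple-testing
adjustment is applied; the comparison table records raw p-values. The
type-I error of the full routed procedure is verified by simulation to sit
in [0.03, 0.07] at α = 0.05.

Group summaries report n, mean, SD and SEM side by side. In the source
summary table the ± entries of the lesion rows are only plausible as SEMs
(± ≈ 1 gray level as an SD would be implausibly tight for 8-bit data),
while the parenchyma row is labelled SD; both readings are emitted so
either can be compared. Units of analysis are images by default; an
optional per-patient aggregation averages a patient's images first.

## Synthetic phantoms

The generator emulates exactly what the measurements consume: per-region
first-order gray statistics on a calibrated 8-bit frame. A phantom is a
bright parenchyma background, an elliptical lesion of darker solid tissue,
near-anechoic elliptical cystic lobules inside it, and optionally a
hyperechoic wall band. Pixel noise is an independent truncated normal on
[0, 255], rounded to integers, sampled by inverse CDF (exact and efficient
even when truncation removes most of the mass). Because truncation at 0
would otherwise drag the realized mean of near-anechoic regions upward by
1–2 gray levels, the generator solves for the pre-truncation location whose
truncated mean equals the requested mean; the requested `mean` is therefore
the realized one, while `sd` is pre-truncation. Every phantom carries truth
masks, realized statistics (recomputed exactly on those masks), and the
annotation a perfect annotator would produce: a 72-vertex polygon on the
lesion boundary, one seed per lobule placed at a representative pixel near
the lobule center (gray value closest to the lobule's realized mean), with
tolerance = half the solid–cystic mean gap, and three auto-placed 5-mm
parenchyma circles.

What the phantom does **not** model: spatially correlated speckle (a
Gaussian-smoothing option exists but is off by default — the measured
quantities are first-order, so correlation structure does not enter them),
attenuation, shadowing, reverberation, wall irregularity, or free-hand
lesion shapes. Passing tests therefore demonstrate correctness of the
measurement and statistics pipeline under the stated first-order model, not
robustness to real acoustic artifacts.

### Group parameterizations

`default_group_specs()` encodes the three diagnosis groups with group sizes
30/81/59 images (11/32/32 patients), per-group whole-lesion areas, area
ratios 57 %/39 %/61 %, lobule counts rounded to 2/2/1, cystic and
whole-lesion echogenicities, within-region pixel SDs from the inhomogeneity
rows, and parenchyma fields (68.9 ± 10.4, 68.3 ± 11.3, 69.4 ± 11.1).
Between-image spreads are SEM·√n. Two reconciliations were needed because
the printed summary rows are not mutually consistent:

* The mixture identity whole = f·cystic + (1−f)·solid cannot hold for all
  printed means simultaneously (composites are 19.0/28.1/20.4 vs printed
  18.8/27.8/19.8). Each image draws its whole-lesion target mean and cystic
  mean from the printed rows and *derives* the solid mean from the identity,
  preserving the whole-lesion rows — the headline comparisons — exactly;
  the marginal spread of solid means is then wider than the printed solid
  SEM row.
* The printed solid areas do not equal whole − cystic either (e.g. 196.1 ≠
  590.4 − 324.1 mm²). The package defines the solid part strictly as
  whole − cystic and does not emulate the discrepancy.

Per-image draws clip to physical ranges (area to [0.3, 2.2]× the group
mean, cystic mean to ≥ 2 gray, solid mean to ≥ cystic + 2). Lobules are
slotted as non-overlapping ellipses in lesion-normalized coordinates along
a random axis, shrunk if needed to stay inside the lesion, so containment
and disjointness are guaranteed by construction; the realized cystic
fraction (recorded in truth) can fall slightly below the requested one.

### Known behavior of the tracing-tool emulation

With tolerance = half the solid–cystic gap, the admissible band captures
P(|X−μ| ≤ T) of the cystic pixels; Dice ≥ 0.95 against the truth lobule
requires T ≥ 2σ, i.e. a mean gap of at least 4 pixel-SDs. At the study's
own parameters (gaps ≈ 20–33, cystic σ ≈ 7) recovery is partial, so
measured area ratios run a few points below the truth fractions — the same
under-segmentation a real operator would see at that tolerance. Group
orderings and the significance pattern of the whole-lesion metrics are
unaffected, which is what the end-to-end test asserts.

## Problem sizes used by the test suite

Simulation tests use geometry-scaled phantoms (frames 240×320 to 480×640,
lesion areas scaled by 1/16, full group sizes 30/81/59 and unscaled gray
parameters and between-image spreads), 10 seeded cohort replicates for the
significance-pattern check, 100 phantoms for segmentation recoverability,
300 replicates for the parenchyma homogeneity calibration, 1000 replicates
for the type-I error and the brute-force oracle equivalences. These sizes
are the package's choices for routine runs; all scale up linearly via the
corresponding parameters.
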
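# Methods

## Segmentation model

Frames are converted from sRGB to CIELAB (D65 white point) and the
lightness channel is discarded; classification operates on the a\*b\*
chromaticity pair, which is far less sensitive to illumination level than
RGB. Each frame is binarized independently by two-cluster k-means over the
in-arena pixels (scikit-learn, 10 restarts, centroid tolerance 1e-4, seeded
from config). k-means labels are arbitrary, so the cluster whose centroid
lies nearer (Euclidean in a\*b\*) to a *reference color* — the mean a\*b\*
of the known initial plasmodium disc in frame 0 — is taken as slime. This
rule makes the output invariant to label permutation and therefore to the
k-means seed. A frame whose in-arena pixels are chromatically identical
cannot be segmented and raises a "no chromatic contrast" error rather than
returning an arbitrary split.

Fitting per frame (rather than once globally) is an interpretation choice:
it tracks slow color drift and needs no global pass, at the cost of relying
on the reference-color rule for temporal consistency.

The raw slime mask is cleaned by removing 8-connected components and
filling holes of at most `min_blob_frac` of the arena area (default 1e-4,
i.e. a few pixels at typical working resolutions). Speckle of this size is
segmentation noise; real pseudopods are orders of magnitude larger.

**Trinarization.** Pixel history refines not-slime into mucus or
unexplored: frame 0 is slime/unexplored; thereafter a non-slime pixel is
mucus iff it was ever slime before. Two invariants follow by construction,
for any binarization input: the explored area (slime ∪ mucus) never
shrinks, and no pixel ever returns to the unexplored state.

## Growth accounting

Per interval, pixels are classified as primary growth
(unexplored → slime), secondary growth (mucus → slime) or refinement
(slime → mucus). Counting pixels gives the exact balance
slime(t) − slime(t−1) = primary + secondary − refinement on every interval.
Row 0 of the metric table carries the initial plasmodium footprint as
primary coverage, so cumulative primary growth equals the explored fraction
at every time and is bounded by 1; cumulative secondary growth may exceed 1
(each unit of area can be revisited many times — its magnitude measures the
cyclicity of exploration).

The extent of growth is the Euclidean distance from each grown pixel to the
nearest previous-slime pixel, via the exact distance transform
(`scipy.ndimage.distance_transform_edt`). The migration rate is the maximum
extent divided by the interval, 0 when nothing grew. Distances are computed
between pixel centers and scaled by `mm_per_px`, which comes from the known
arena diameter — never from image metadata. The distance-transform
formulation subsumes a contour-to-contour definition and stays well defined
under retraction and fragmentation.

The expansion region of an interval is the set of non-slime arena pixels
within the interval's maximum growth extent of the previous slime set. Over
it, `observed = #secondary / (#secondary + #primary)` and
`expected = mucus share of the region`: under uniformly random growth
placement the two agree in expectation, so a persistent excess of observed
over expected reveals a preference for previously explored (mucus-covered)
substrate. Either fraction is reported as missing (NaN) when its
denominator is zero; because single 5-minute intervals are often
degenerate, pooled fractions over a sliding 1-hour window are also
reported.

## Shape indices

- **Circularity** C = P²/(4πA) with P the total contour length over all
  components and A the total pixel area. The perimeter is measured on the
  marching-squares 0.5-level contour simplified by Douglas–Peucker with
  tolerance 1 px. Raw pixel-edge counting overestimates a smooth boundary
  by ~11% and the unsimplified iso-contour by ~6%, which would put a
  perfect disc at C ≈ 1.12; after simplification a rasterized disc of
  radius 100 px gives C = 1.004, a square 1.261 (4/π = 1.273), and two
  equal discs 2.02.
- **Eccentricity** E = √(1 − (b/a)²) from the ellipse with the same second
  central moments as the full foreground point set (disconnected
  components included). A single-pixel or degenerate mask has E = 0 by
  convention.
- **Solidity** S = foreground area / convex-hull area of the full
  foreground, pixels treated as unit squares (half-pixel hull offsets), so
  a plus-sign of five unit squares gives S = 5/7 against its octagonal
  hull.
- **Cluster count**: 8-connected components surviving erosion by a disc
  structuring element; thin bridges and fine stalks vanish, leaving one
  component per exploration front. Default radius: 2% of the arena radius
  (config-overridable); the erosion radius and the perimeter estimator are
  free choices documented here, not measured constants.

Multi-component frames use totals for P and A and the full point set for E
and S, consistent with the cluster count coexisting with whole-cell shape
indices.

## Spot analysis

The distance to the attractant is the minimum over slime pixels of the
Euclidean distance to the glucose-spot *edge*, clamped at 0 on overlap —
edge distance makes "reached" ≡ "distance 0" well defined. Whether the
experimental separation between plasmodium and spot is edge-to-edge or
center-to-center is ambiguous; the generator exposes it as an explicit
parameter (`spot_distance_mode`, default `"edge"`). Time to contact is the
first frame at or below a threshold (default 0 mm), censored at the final
frame otherwise. The across-replicate curve P(t) is the plain empirical
fraction of replicates with contact time > t; censored replicates count as
not-reached through the horizon. This is a direct counting definition, not
a Kaplan–Meier estimator, and no hazard model is fitted.

## Synthetic generator

The generator emulates the experimental geometry (14.5 cm arena, 2.5 cm
initial disc, 5-min sampling, 35 h → 420 frames) with a lattice simulation:

- **Frontier growth.** Candidate pixels lie within
  `growth_rate_mm_min × interval` of the current slime set; each grows with
  probability `grow_fraction × w / max(w)`. Weights w combine the substrate
  preference (`mucus_bias` on mucus vs 1 on unexplored), transient
  directional pseudopod lobes (Poisson births at `pseudopod_rate` per hour,
  ~1 h lifetime, Gaussian angular kernel), and optional chemoattraction
  toward a glucose spot. A capped fractional-advance carry accrues
  un-realized distance when the nominal per-step advance is below one
  pixel, so the front moves at the nominal speed at any resolution.
- **Withdrawal.** With probability `retraction_prob` per step a disc of
  radius `retract_radius_mm` is carved at a random frontier pixel, leaving
  mucus. The plasmodium has finite biomass: above `max_slime_frac` of the
  arena (default 0.35) withdrawal is forced (up to 8 carves per step),
  which bounds slime coverage and sustains the refinement/regrowth cycles
  seen in long recordings.
- **Sheet continuity.** Detached slime fragments and enclosed pockets at or
  below the speckle scale (`max(4 px, 1e-4 × arena area)`) are absorbed
  each step; a plasmodium is a continuous sheet and sub-resolution débris
  is not meaningful. This scale matches the segmentation cleanup threshold,
  so noise-free renders segment back to the ground truth exactly.
- **Rendering.** Per-class mean colors (defaults: yellow plasmodium, pale
  pink-gray mucus trace, blue-gray cellulose-agar substrate, pairwise
  ≥ 20 units apart in a\*b\*) plus i.i.d. Gaussian noise (`noise_sigma`,
  8-bit units, default 5), fixed dark color outside the arena. One seeded
  stream drives the dynamics in a fixed draw order (withdrawal, lobe
  births, growth selection); rendering uses independent per-frame streams
  derived from the same seed, so identical seeds give bit-identical output.

Named presets (`control`, `nutritive`, `highly_nutritive`, `adverse`,
`spot_experiment`) bundle parameters reproducing the qualitative treatment
orderings — e.g. `adverse` starts after a 3 h delay, withdraws often and
carries `mucus_bias = 5`. The values are illustrative, not fitted to any
measured curve.

**What the generator does not emulate:** protoplasmic streaming and vein
networks, oscillatory area dynamics, mass transport (area is capped, not
conserved), illumination drift or vignetting, optical blur (class noise is
pixel-independent, so segmentation at moderate noise is easier than on real
photographs), and salt-spot repulsion (a salt spot is geometric only).
Passing tests therefore certify the measurement chain — given imagery whose
classes are chromatically separable, the metrics are computed correctly —
not segmentation robustness on degraded real-world imagery.

## Calibration experiments and reference sizes

The reference experiments (`physatrack.benchmarks`) use problem sizes
chosen to make their statistical claims sharp at desk scale:

- *Ground-truth recovery*: 25-frame control-like runs at 192 px, noise-free
  and σ = 8; agreement is the worst frame's pixelwise match.
- *Migration recovery*: deterministic radial growth (all candidates grow,
  no withdrawal, no lobes) at 320 px, where one pixel per interval is
  0.097 mm/min — the quantization floor of the measurement.
- *Secondary-growth calibration*: ground-truth-label runs at 128 px pooled
  over three seeds (~250 valid intervals). The null configuration keeps
  growth placement as the only stochastic spatial mechanism: no lobes, no
  chemoattraction, and sheet-continuity engulfment off, because engulfment
  deterministically converts enclosed (mostly mucus) pockets and would
  confound the placement null by about +0.01. An interval enters the
  comparison when growth occurred and its expansion region contains both
  mucus and unexplored substrate.

## Degenerate inputs and tie-breaks

Empty slime masks raise errors in shape and distance computations (a lost
organism is a failed replicate, not a zero). Zero growth gives migration
rate 0 and an empty extent set; offset 0 gives an empty expansion region.
Quartile bands across replicates use the linear-interpolation convention.
Frame order is the lexicographic filename sort, overridable by an explicit
manifest; arena geometry is always supplied by the user (a Hough-based
autodetector exists as a convenience but is never the default).

## Known limitations

Segmentation assumes exactly two chromatic populations per frame; strong
mucus pigmentation intermediate between slime and substrate can shift the
k-means boundary when the slime area is very small. Sub-pixel migration
(< 1 px per interval) is reported quantized, alternating between 0 and one
pixel-equivalent. The expansion-region band edge carries a sub-pixel
discretization bias (< 2% of band area for bands ≥ 25 px wide). The
survival curve treats censoring by simple counting, which is the intended
estimand here but is not comparable to Kaplan–Meier output under heavy
censoring.
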
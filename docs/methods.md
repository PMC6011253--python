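# Methods

This note records the model behind `mana`, the parameters that matter, the
numerical choices made where the procedure is open to interpretation, and
what the synthetic benchmark does and does not establish.

## The segmentation model

The pipeline assumes H&E appearance: nuclei are the darkest coherent pixel
population (hematoxylin), background/cytoplasm the brightest (eosin), and a
single global gray threshold — chosen adaptively per image — captures nuclei
to first order. Shape assumptions enter only in the correction stages:
single nuclei are roughly elliptical, hence near-convex (solidity close
to 1), and fused clumps are betrayed by lower solidity and by multiple peaks
in the distance transform.

### Progressive weighted mean and threshold candidates

For an 8-bit image, `PWM(P)` is the mean gray value of all pixels ≤ P.
The curve is total on [0, 255]: below the first occupied class the formula
is 0/0, and those classes carry the first defined value so downstream code
never sees NaNs; they are excluded from the fit domain. Useful identities,
both enforced by tests: the curve is non-decreasing, and `PWM(255)` equals
the global mean gray level.

The curve is fitted with an order-15 least-squares polynomial over
[first occupied class, last occupied class]. The abscissa is affinely
mapped to [-1, 1] before fitting; on the raw 0–255 axis the normal
equations of an order-15 fit are numerically singular. If the occupied
range has fewer than 16 classes the order drops to (classes − 1) with a
warning.

Candidates are the real roots of the fitted second derivative that
(a) lie strictly inside the fit domain, (b) genuinely change sign (probed
at ±1e-4 of the domain span; tangential double roots rejected), and
(c) exceed a curvature floor of `1e-6 · amplitude / span²`. The floor
matters: fitting a high-order polynomial to a curve with no real curvature
(e.g. exactly linear) leaves round-off-level second-derivative wiggle that
would otherwise fabricate candidates. Roots are rounded half-up to integer
gray levels and deduplicated.

### Threshold selection

Each candidate is applied as `foreground = gray ≤ t` (the ≤/< choice is a
config switch; ≤ is the default) with 8-connected labeling, and the median
object area is computed **over objects that do not touch the image
border**; the candidate with the highest median wins, ties going to the
lower threshold (less foreground, fewer merged nuclei). The border
exclusion is load-bearing, not cosmetic: a candidate at or above the
background mode turns almost the whole image into one border-spanning
component whose area would otherwise win every time. Clearing
border-touching objects from the statistic (they stay in the returned mask)
restores the intended behavior — over-thresholded candidates score the tiny
median of their noise specks, and the plateau of thresholds that capture
whole nuclei scores the nucleus area. With no usable candidate at all the
tool falls back to Otsu's threshold with a warning; a constant image yields
an empty segmentation rather than an error.

The selected threshold is not unique in any deep sense: on clean bimodal
images the median-area landscape has a wide plateau (any threshold between
the nuclei mode and the background noise floor scores the same median), and
the winner can move along that plateau between runs on different renderings
of the same scene. F1 is insensitive to this; the across-scale threshold
spread reported by the acceptance script should be read with the plateau in
mind.

### Area-based correction

Size classes use the mean area `m` of the initial mask: small iff
`area < 0.25·m` (strict), big iff `area > 5·m` (strict). `m` is frozen at
its pre-correction value while big objects are split — recomputing it each
iteration would make the stopping rule self-referential. Splitting lowers
the threshold 1 gray level per iteration (the finest step available on
8-bit data) and re-labels only within the object's own pixel support;
pixels outside the object are never re-admitted. An object whose foreground
vanishes before ever satisfying the bound is kept as-is with a warning; one
that still violates the bound when the threshold bottoms out keeps its last
partition, flagged. Small fragments created by splitting are *not* deleted
here — the small-object erase runs once more after the watershed, and
running it early would change which areas enter that final mean.

### Solidity-adaptive watershed

Per object, seeds are the extended maxima (h-maxima, then regional maxima)
of the Euclidean distance transform, with suppression depth
`h = fraction · d_max`:

| parameter | default | meaning |
|---|---|---|
| `solidity_cutoff` | 0.95 | at/above: low sensitivity; below: high |
| `h_fraction_low` | 0.30 | deep suppression for near-convex objects |
| `h_fraction_high` | 0.15 | shallow suppression for ragged/fused objects |

These three are implementation-chosen (and so tagged in the config): the
underlying procedure specifies only that seed sensitivity increases as
solidity drops. They were calibrated on the synthetic fixtures by requiring
both directions at once — touching pairs must actually split (the
under-segmentation rate on crowded scenes drops from ~30% to ~19-21%), and
smooth convex nuclei must not be fragmented (mean F1 on well-separated
scenes stays above 0.95). A cutoff of 0.90 is too low in practice: a deeply
overlapping pair of ellipses is still ~0.92-0.96 solid, and with deep
suppression its two distance peaks merge into one seed. Deeper overlaps than
roughly 60% of the summed radii have a single distance peak and cannot be
split by any distance-based seeder; the residual US rate reflects that
geometric limit, not a tuning failure.

If suppression removes every maximum, the global distance maximum seeds the
object, so every object keeps ≥ 1 seed. The watershed floods the negated
distance transform from the seed markers within the object mask; every
object pixel is assigned to exactly one region (no unassigned ridge
pixels), so the output partitions the input object — a property fuzz-tested
across whole scenes. Finally, objects below a quarter of the post-watershed
mean area are erased.

### Evaluation conventions

A center matches a region iff it lies on that region's pixels (configurable
snap tolerance, default 0 — a center on an erased ridge or background pixel
counts as a segmentation error). With the default `per_center` convention
every matched center is a TP, so a fused pair contributes 2 TP and 2 US:
F1 deliberately penalizes only object-level errors (misses and ghosts),
while under-segmentation is visible in the CS/US split. The alternative
`per_region` convention (one TP per region) is available as a config
switch. CS + US + SE = N_GT holds by construction and is fuzz-tested.

## The synthetic benchmark

The generator emulates what the pipeline is sensitive to: dark bluish
elliptical nuclei (default RGB (70, 60, 140), major semi-axis 8–20 px,
eccentricity 0–0.6) on a pale pinkish background (default (230, 190, 200)),
per-nucleus color jitter (sd 10), per-pixel Gaussian noise (sd 6), a
minimum boundary gap of 6 px between non-touching nuclei, and touching
pairs placed at center distance `[0.8, 1.2]·(r1+r2)/1.5` whose overlap is
rendered at the channel-wise minimum of the two nucleus colors so each pair
forms one connected dark blob. Magnification is emulated by rendering one
sampled placement at 1×/2×/4× linear scale. Everything is bit-reproducible
from the spec seed.

It does **not** simulate chromatin texture, stain variation across a slide,
tissue architecture (glands, stroma, lumen), out-of-focus blur, or
annotation noise. Passing the synthetic benchmark therefore shows the
algorithm is internally correct and behaves as designed on images matching
its assumptions; it does not predict absolute performance on clinical
material, where contrast is weaker and the histogram messier.

Problem sizes used by the test suite and the acceptance script — 512×512
scenes with 100 nuclei, 10 scenes per condition, one multiscale scene up to
2048×2048 — were chosen so a full run completes in about a minute while
keeping per-image F1 granularity (one error ≈ 0.005) well below the margins
being checked.

## Known limitations

- Single global initial threshold: images whose nuclei intensity varies
  regionally (uneven staining) get no local adaptation before the big-object
  correction.
- Distance-based seeding cannot split overlaps with a single distance peak
  (see above); a shape-prior separator would be needed.
- 8-bit single-scene images only; no whole-slide tiling, no stain
  normalization or deconvolution.
- The solidity cutoff separates ragged singles from smooth pairs imperfectly
  by nature — the two distributions overlap — so a small rate of spurious
  splits (caught mostly by the final small-object erase) and of missed
  splits is inherent to the design.
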
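# Methods

## The measurement model

A wound photograph taken perpendicular to the wound plane maps physical
areas to pixel counts by a single unknown factor (px/cm)². Placing a
printed square fiducial of known side `s` (the patient-ID QR code,
default 1.2 cm) in the same plane identifies that factor: if the
fiducial occupies `A_qr` pixels and the wound `A_wound` pixels, the
wound's physical area is

    S_wound = A_wound · s² / A_qr .

The estimate is exactly invariant to uniform rescaling of the image
(camera distance, sensor resolution), which is the method's central
claim; it is *not* invariant to perspective tilt, which the model
assumes away (perpendicular shots only).

## Fiducial detection

The chain is classical binary image processing, self-implemented in
`binary_ops` so its semantics are pinned down exactly:

* **Grayscale**: BT.601 luma (0.299 R + 0.587 G + 0.114 B), rounded
  half-up. * **Otsu threshold**: exhaustive maximization of between-class
  variance over the 256-bin histogram; smallest maximizing threshold on
  ties; a constant image raises an explicit degenerate-histogram error.
* **Inverted binarization**: pixels ≤ t become foreground, so dark print
  becomes white in the mask. * **Closing** with a 3×3 square structuring
  element (configurable), computed on the zero-extended plane so closing
  is extensive even at the border. * **Border clearing**: any component
  with a pixel in the first/last row/column is deleted. * **Hole
  filling**: background not 4-connected to the border becomes
  foreground. * **Area filter**: components outside a configured range
  are dropped; by default the range is relative, [0.2 %, 25 %] of the
  image's pixels, which is scale-free and therefore works across a wide
  range of shot distances without tuning.

Foreground components use 8-connectivity and background 4-connectivity
(the standard duality). Morphology pads with background; pixel "area"
is the raw foreground count, with no sub-pixel correction.

Design choice — the *solid footprint* reading: hole filling is applied
to the border-cleared mask before the area filter and ranking, so the
QR code is counted as its full solid square footprint rather than as
its dark modules only. This is what makes the detection scale-invariant
(the footprint scales exactly as s², module-level rasterization does
not) and what makes the coin-validation arithmetic consistent: the
footprint of a 1.2 cm code at the coin's resolution, not the ~45 % of
it that is dark ink, is what stands in ratio to the coin's disc.

Candidate ranking prefers square bounding boxes (|log aspect| smallest)
among candidates whose extent (area / bbox area) is ≥ 0.85 — a filled
square has extent ≈ 1, a disc π/4 ≈ 0.785, so a coin in the same frame
cannot be mistaken for the fiducial. Exact score ties raise an
ambiguity error rather than guessing silently.

## Wound segmentation

Pixels are clustered with K-means (k-means++ initialization, 10
restarts, Lloyd iterations; fixed seed, default 0, so results are
reproducible) on CIELAB features. By default only the chroma channels
(a\*, b\*) are used: CIELAB separates lightness from color, and dropping
L\* makes the clustering insensitive to illumination gradients. k = 3
by default — wound, surrounding skin, and everything else are the three
dominant color regimes of a typical clinical frame; k is configurable.

The wound cluster is identified as the one with the highest mean a\*
(wounds are red; a\* is the green–red axis). When the top two clusters'
mean a\* are within 0.5 units the rule refuses to choose and the caller
must use the manual or seed-point strategy; this is deliberate, since a
wrong automatic choice is worse than an explicit hand-off. Pixels under
the detected fiducial's bounding box (expanded by 25 % of its side, to
cover the white sticker backing) are excluded from clustering so the
sticker cannot capture a cluster.

The raw cluster mask is cleaned by 3×3 opening (speck removal) and hole
filling, keeping the largest component by default. Boundaries are
traced per component by Moore-neighbor contour following (clockwise,
starting at the row-major-first pixel, stopping when the
pixel/backtrack state repeats), including inner contours around any
holes; the traced pixel set equals the neighbor-test boundary
definition (mask pixels with a background 4-neighbor or on the image
border). The wound's pixel area is the foreground count of the cleaned
mask, i.e. all non-black pixels of the wound cluster's mask.

## Calibration and reported values

Internally all quotients are kept at full floating precision. *Reported*
ratios and areas are truncated (toward zero) at 4 decimals, and percent
differences rounded to 1 decimal; truncation rather than rounding is the
package's reporting convention and is applied only at the reporting
boundary. The bundled reference constant for a US one-cent coin is
2.8488 cm² (geometric area of a 19.05 mm disc: 2.8502 cm²).

## Repeatability statistics

For an N-wounds × m-shots grid of calibrated ratios:
per-shot sample mean and SD (n−1 denominator); pairwise Pearson r;
pairwise paired t-tests, t = mean(d)/(sd(d)/√N) with df = N−1 and
two-sided p; one-way ANOVA across the m shot groups, df (m−1, m(N−1)).
The ANOVA is deliberately the plain between-shots one-way test on the
same wounds rather than a repeated-measures model: when wounds vary far
more than shots, it yields an F near 0 and p near 1, which is exactly
the signature of shot-interchangeability this battery is meant to
exhibit. Zero-variance configurations (identical columns, constant
differences) raise explicit degenerate-statistics errors rather than
returning NaN.

## Synthetic scenes

The generator emulates the clinical setup: an 8 × 8 cm field at a chosen
resolution (default 50 px/cm; camera height is simulated by scaling
px/cm), a skin-toned background, a reddish wound (ellipse or
fused-ellipse blob) of exactly known analytic area, a pseudo-QR fiducial
(dark 2-module frame, quiet ring, finder-like corner blocks, fixed
pseudo-random module fill — deterministic, never decoded) on a white
sticker, a few bluish clutter patches, and additive Gaussian sensor
noise (default SD 4 intensity units, a mild smartphone level; the
geometry seed and the noise seed are separate so the same physical scene
can be re-shot with fresh noise). Shapes are rasterized by the
pixel-center rule; blob areas are normalized to the requested cm² by
supersampled fixed-point iteration, so truth pixel areas converge to
`area × (px/cm)²` as resolution grows. The bench-validation scene
renders a copper-colored disc (a one-cent coin is copper, hence high
a\*, so the same wound-cluster rule applies to it) on a neutral gray
background.

What the generator does *not* emulate: perspective tilt, specular
highlights, shadows and illumination gradients, skin texture, wound
heterogeneity (slough, granulation, epithelium), motion blur and
compression artifacts. Passing tests on these scenes therefore
demonstrate the correctness and scale-invariance of the *algorithmic
chain*, not robustness to difficult clinical imagery; low-contrast
wounds are a known failure mode of color K-means generally.

## Problem sizes and study conditions used in validation

* Oracle equivalence: 100 random masks ≤ 16×16, every primitive
  bit-exact against brute-force loops; Otsu against exhaustive search
  on 100 random 8×8 images.
* Parameter recovery: a 1.5708 cm² ellipse and a 19.05 mm disc at
  50 px/cm, both recovered within 2 % (measured ≈ 0.03 % and 0.08 %).
* Distance invariance: the same scene at 0.7×, 1.0× and 1.4× resolution;
  CV of the three estimates < 2 % noiseless and < 5 % at noise SD 8
  (measured ≈ 0.1 %).
* Repeated shots: 10 wounds × 3 shots, each shot at an independent
  random scale drawn uniformly from [0.7, 1.4] (the "random heights"
  design); all pairwise r > 0.99, all paired-t p > 0.05, ANOVA p > 0.05
  at the seeded default conditions.
* Type-I calibration: 2000 null replicates (15 wounds, shared wound
  values, independent Gaussian shot noise), paired-t rejection rate at
  α = 0.05 within 3σ Monte-Carlo error of 0.05.

## Known limitations

* Perspective tilt biases areas by cos θ and is not corrected.
* The synthetic panel's measurement noise is sub-percent; at that
  precision the paired t-test becomes sensitive to tiny systematic
  rasterization differences between shots, and on some panel seeds an
  individual pair can dip below p = 0.05 with |mean difference| well
  under 1 % of the ratio. Real clinical variability is larger and
  less structured.
* The max-a\* cluster rule assumes the wound is the reddest large
  region; pale, necrotic or sloughy wounds need the manual or
  seed-point strategy.
* One fiducial per frame is assumed; two identical candidates raise an
  ambiguity error by design.
* QR decoding (patient identity), wound depth/volume, and tissue-type
  assessment are out of scope.
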
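# woundmetry

Fiducial-calibrated photographic wound planimetry.

Clinicians tracking chronic wounds need an objective area measurement, but
photographs taken by different people at different distances cannot be
compared directly: the same wound covers a different number of pixels in
every shot. `woundmetry` solves this the way a ruler in the frame would —
it uses the printed QR code on the patient-identification sticker, which
has a fixed physical size (1.2 cm × 1.2 cm by default), as a scale
reference, so any smartphone photo taken roughly perpendicular to the
wound yields a calibrated area in cm² regardless of camera distance or
resolution.

## Method

Three stages, each exposed as a library module:

1. **Fiducial detection** (`qr_reference`, built on the self-implemented
   primitives in `binary_ops`): grayscale conversion → Otsu threshold →
   inverted binarization (dark print becomes foreground) → morphological
   closing → removal of border-connected components → hole filling →
   area filter → squareness ranking. The retained region is the QR code's
   solid square footprint; its pixel count `A_qr` is the scale reference.
2. **Wound segmentation** (`wound_segmentation`): conversion to CIELAB,
   K-means clustering of the pixels on the chroma channels (a\*, b\*), with
   k = 3 by default; the reddest cluster (highest mean a\*) is taken as the
   wound, cleaned by opening + hole filling, and its outline is traced by
   Moore-neighbor contour following. The cleaned mask's pixel count is
   `A_wound`.
3. **Calibration** (`calibration`): with the fiducial's known physical
   area `S_qr` (cm²),

   `S_wound = A_wound × S_qr / A_qr`.

   Both pixel counts scale identically with camera distance, so their
   quotient — and the physical estimate — is distance-invariant.

A statistics layer (`repeatability`) assesses agreement across repeated
shots of the same wounds (per-shot mean ± SD, pairwise Pearson r, paired
t-tests, one-way ANOVA), and a synthetic scene generator (`synthetic`)
renders ground-truth-labeled test photographs — pseudo-QR fiducial, an
elliptical or blobby "wound" of known physical area, clutter, sensor
noise — at any simulated camera distance, so the whole pipeline is
verifiable without clinical data.

## Worked example

```python
from woundmetry import SceneSpec, render_scene, measure_image

scene = render_scene(SceneSpec(seed=0))     # 8x8 cm scene at 50 px/cm
meas, fid, wound = measure_image(scene.rendered)
print(meas.as_row())
```

prints

```
{'source': '', 'wound_px': 3926, 'fiducial_px': 3600, 'fiducial_cm2': 1.44,
 'ratio': 1.0905, 'actual_cm2': 1.5703}
```

The fiducial's 1.2 cm square was recovered as exactly 60 × 60 = 3600
pixels, the wound as 3926 pixels, and the calibrated estimate 1.5703 cm²
is within 0.03 % of the scene's analytic truth of 1.5708 cm².

The same workflows are available from the shell. The reference-coin
validation can even be run on raw pixel counts, without an image:

```bash
$ woundmetry validate --pixel-counts "10806/5470,13831/6958,12050/6190"
{"ratios": [1.9755, 1.9877, 1.9466], "mean_ratio": 1.9699,
 "estimated_area_cm2": 2.8366, "reference_area_cm2": 2.8488,
 "percent_difference": 0.4, ...}
```

i.e. three shots of a one-cent coin at different heights give ratios that
agree to ~1 %, and the mean ratio times the QR code's 1.44 cm² estimates
the coin's area within 0.4 % of its known 2.8488 cm². Other subcommands:
`woundmetry measure` (single photo, with optional step-by-step
intermediate images), `woundmetry repeat` (multi-shot repeatability
report) and `woundmetry fixtures` (materialize the synthetic test
scenes).

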
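# corneodeform

Analysis of air-puff tonometry corneal-deformation image sequences.

Non-contact tonometers of the Corvis ST type fire an air puff at the cornea
and record the resulting deformation with an ultra-high-speed Scheimpflug
camera: a sequence of cross-sectional grayscale images (nominally 140
frames of 200 × 576 pixels, one every 230 µs) in which the cornea appears
as a bright band over a dark background. `corneodeform` extracts the
anterior corneal contour from such a sequence, separates corneal bending
from whole-eye motion, and measures deformation parameters that the
instrument's own software does not report. It is aimed at researchers in
ocular biomechanics who work with the raw image sequences (exported as AVI
or frame stacks) rather than the device's summary numbers.

## Method

For each column *n* and frame *i*, the anterior contour row
*L*<sub>T</sub>(*n*, *i*) is found by 3×3×3 spatio-temporal median
filtering, Canny edge detection with a morphological close, and taking the
topmost edge row per column. The contour is then decomposed additively,

&nbsp;&nbsp;&nbsp;&nbsp;*L*<sub>T</sub> = *L*<sub>TD</sub> + *L*<sub>TR</sub> + *L*<sub>TO</sub>,

into the static shape *L*<sub>TD</sub> (the frame-0 contour), the whole-eye
reaction *L*<sub>TO</sub> (tracked at the left/right image borders, where
only sclera moves, and interpolated linearly across columns), and the
corneal deformation proper *L*<sub>TR</sub>. On that decomposition three
parameter families are computed per frame:

1. **Reaction vs. mirrored static position.** The deformation support is
   *L*<sub>TR</sub> > *p*<sub>r</sub> (threshold at the ≈2 px contour noise
   amplitude), cleaned by a 3×3 median; the contour over the support range
   is mirrored across the chord *L*<sub>OS</sub> through its extreme points
   *c*<sub>1</sub>, *c*<sub>2</sub>, giving *L*<sub>K</sub> and the area
   *L*<sub>g</sub> between the mirrored curve and the deformation.
2. **Corneal length changes.** Polyline arc lengths *L*<sub>DDTR</sub> (the
   deformed contour), *L*<sub>DDK</sub> (the mirrored contour) and the
   chord *L*<sub>DDS</sub> = |*c*<sub>1</sub>*c*<sub>2</sub>|, plus
   noise-robust variants *L*<sub>AATR</sub>, *L*<sub>AAK</sub> measured
   after degree-8 polynomial smoothing.
3. **Length-to-amplitude ratio.** *L*<sub>DDS/TR</sub>(*i*) =
   *L*<sub>DDS</sub>(*i*) / max<sub>n</sub> *L*<sub>TR</sub>(*n*, *i*); its
   two peaks, one on each side of the highest-concavity frame, mark the
   applanation instants *a*<sub>1</sub>, *a*<sub>2</sub> — the moments the
   central cornea is locally flat.

A synthetic phantom generator renders deformation sequences with an exact
contour model (parabolic arc + Gaussian indentation + delayed whole-eye
displacement) whose applanation frames are analytic, so the whole pipeline
is testable without clinical recordings. See `docs/methods.md` for the
model, parameter defaults and limitations.

## Worked example

Generate a phantom and analyze it:

```bash
corneodeform simulate --out sim --seed 1
corneodeform analyze --input sim/phantom.avi --out results --sweep 0.1,0.5,1,2,4,6
```

The analyze command prints (frame indices are 0-based):

```json
{
 "a1": 29,
 "a2": 111,
 "highest_concavity_frame": 71,
 "outputs": {
  "contours": "results/contours.csv",
  "parameters": "results/parameters.csv",
  "summary": "results/summary.json",
  "sweep": "results/threshold_sweep.csv"
 }
}
```

Here the air puff flattens the cornea at frame 29 on the way in and frame
111 on the rebound, with maximum indentation at frame 71; the phantom's
analytic applanation frames for these settings are 30 and 110, i.e. the
detected peaks land within one frame (≈230 µs) of ground truth.
`contours.csv` holds the four contour components per (frame, column),
`parameters.csv` the per-frame lengths and ratio, and
`threshold_sweep.csv` the peak positions as a function of the binarization
threshold *p*<sub>r</sub>.

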
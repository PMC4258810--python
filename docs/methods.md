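# Methods

## Image model and pre-processing

Input sequences are 8-bit grayscale cubes *L*(*m*, *n*, *i*) with row *m*
growing downward, column *n*, and frame *i* (nominal geometry 200 × 576 ×
140, one frame per 230 µs). The cornea is a bright band over a dark
background; the quantity of interest is the anterior band edge
*L*<sub>T</sub>(*n*, *i*) in pixel rows.

Pre-processing steps, in order:

1. **3×3×3 median filter** (replicate padding on all borders). Removes
   shot noise and small optical-path artefacts. At image borders the
   replicate padding can bias the band edge by one row, which is why
   contour-accuracy statements are made for detection on clean input (see
   Limitations).
2. **Edge detection.** Per frame, a Canny detector at `canny_sigma` = 2 px.
   Hysteresis thresholds are specified *relative to the frame's maximum
   Gaussian-gradient magnitude* (defaults 0.1 / 0.25): the band's contrast
   varies between recordings, and relative thresholds track it. A frame
   whose peak gradient falls below `min_edge_gradient` (0.04 on the 0–1
   intensity scale) is treated as structureless. Detection and the
   subsequent morphological close (disk, radius 3) run on a
   column-replicated image (pad 8) so border columns behave like interior
   ones; skimage's Canny cannot mark pixels on the image border.
3. **Component filtering.** After the close, only edge components spanning
   at least 10% of the columns are kept. The band's boundary lines span
   nearly the full width; noise specks do not. This removes rare
   catastrophic topmost-edge outliers and gives the natural failure mode
   for structure-free frames: no wide component → no edge columns →
   `ContourNotFoundError` naming the frame.
4. **Contour.** Per column, the topmost kept edge row plus 0.5 px. The
   half-pixel term aligns the detector's transition-centre convention with
   the first bright band row; it is a constant offset, not sub-pixel
   refinement — contour *differences* (everything downstream) remain
   integer-quantized. Columns without an edge are filled by linear
   interpolation from the nearest detected columns, constant at the ends.

## Decomposition

With the frame-0 contour as static reference, the whole-eye reaction
*L*<sub>TO</sub> is tracked where the air puff does not bend the surface:
the outermost `border_width` = 5 columns per side. Per frame, each border's
reaction is the median over those columns of
*L*<sub>T</sub>(*n*, *i*) − *L*<sub>T</sub>(*n*, 0); interior columns get
the linear interpolation between the left and right values. The median
over a small border band (rather than the single outermost column, which
`border_width` = 1 reproduces) suppresses single-column detection noise.
The corneal deformation is the remainder,
*L*<sub>TR</sub> = *L*<sub>T</sub> − *L*<sub>TD</sub> − *L*<sub>TO</sub>,
so the reconstruction identity is exact by construction.

## Deformation parameters

* **Support.** *L*<sub>W</sub> = [*L*<sub>TR</sub> > *p*<sub>r</sub>] with
  *p*<sub>r</sub> = 2 px by default — the noise amplitude of the extracted
  contour, so that only genuine deformation survives. A 3×3 median over
  the (frame, column) plane cleans speckle; the largest connected run of
  ones per frame is the deformation range (ties broken toward the run
  nearest the image centre, then leftmost — multiple equal runs are a
  degenerate case the data model does not otherwise distinguish).
* **Reflection.** The symmetry axis is the chord through the range's
  contour endpoints *c*<sub>1</sub>, *c*<sub>2</sub>. Contour points over
  the range are point-reflected across it. A reflection across a tilted
  axis is generally not single-valued per column, so the mirrored points
  are resampled onto integer columns by linear interpolation (all
  downstream formulas index by column). The axis endpoints are fixed
  points, so the mirrored curve meets the contour at the range boundaries;
  double reflection returns the contour to within the 0.5 px resampling
  tolerance. The area *L*<sub>g</sub> between the mirrored curve and the
  deformation (both after removing the static component) uses the
  trapezoidal rule on per-column absolute differences.
* **Lengths.** Arc lengths are polyline sums with unit column spacing.
  *L*<sub>DDTR</sub> is measured on *L*<sub>TD</sub> + *L*<sub>TR</sub>
  (whole-eye motion removed, so the length change reflects corneal
  bending only); *L*<sub>DDK</sub> on the mirrored contour; *L*<sub>DDS</sub>
  is the Euclidean distance between *c*<sub>1</sub> and *c*<sub>2</sub>.
  Raw polyline sums inflate under noise (each segment picks up
  √(1 + δ²)), so both curves are also fitted with a degree-8 least-squares
  polynomial (columns mapped to [−1, 1] for conditioning) and re-measured
  (*L*<sub>AATR</sub>, *L*<sub>AAK</sub>). Ranges narrower than degree + 2
  columns, or rank-deficient fits, fall back to the raw lengths and are
  flagged.
* **Ratio and applanation.** *L*<sub>DDS/TR</sub>(*i*) =
  *L*<sub>DDS</sub>(*i*) / max<sub>n</sub> *L*<sub>TR</sub>(*n*, *i*),
  defined only where the amplitude exceeds `ratio_min_amplitude` = 1 px
  (division-by-noise guard). The highest-concavity frame is the amplitude
  argmax; *a*<sub>1</sub> and *a*<sub>2</sub> are the global ratio maxima
  before and after it (global, not local, maxima: the ratio runs as a
  plateau between the applanations, and local-maximum scanning is unstable
  there). Because the detected contour is integer-quantized, the amplitude
  can plateau at its maximum over several frames; the middle frame of that
  plateau is taken as the highest concavity. Ratio ties break toward the
  frame closest to the peak. Fewer than five
  frames of defined ratio is reported as "no deformation" (clean empty
  result from the pipeline; an error from the detector when called
  directly).

## Phantom generator

The phantom renders what the camera sees from an exact contour model

m(n, i) = m_apex + (n − n_c)² / (2R) + A(i)·exp(−(n − n_c)²/(2σ²)) + d(i)

with a parabolic static arc (radius *R* = 900 px; at corneal curvature the
parabola/circle difference across the field of view is sub-pixel, and the
parabola makes the applanation condition analytic), a Gaussian indentation
of width σ = 60 px whose amplitude *A*(*i*) is a raised-cosine pulse over
frames [20, 120] peaking at 50 px, and a whole-eye retro-displacement
*d*(*i*) — a lower (8 px), delayed (25 frames) raised-cosine modelling the
sluggish eyeball reaction. Both vanish at frame 0. The apex of the model
contour is locally flat when *A*(*i*) = σ²/*R* (indentation curvature
cancels arc curvature); the first and last frames exceeding that level are
the analytic applanation frames (σ²/*R* = 4 px → frames 30 and 110 at the
defaults). Rendering draws a 12 px bright band (intensity 200 over
background 30) from round(m + jitter), with 0.5 px edge jitter and
Gaussian intensity noise (sd 6) — sized so the extracted contour carries
about 2 px of noise amplitude, the level the default *p*<sub>r</sub> is
meant to reject. All randomness derives from a single seed.

The eyeball reaction is modelled as a pure vertical translation, which the
border-tracking decomposition can recover exactly; real recordings may
contain rotation and lateral shift that it cannot. The phantom also has no
posterior corneal surface, no Scheimpflug optical distortion, no specular
highlights, and a deformation that is symmetric about the indentation
centre. Tests passing on phantoms therefore validate the geometry and
signal-processing chain, not robustness to every clinical artefact.

## Numerical choices

* All indices 0-based; serialized tables carry 0-based frame/column
  indices and floats at 17 significant digits (exact round-trip).
* The decomposition identity is exact up to floating-point association
  (checked at 1e−9).
* Frames whose deformation range spans fewer than 3 columns are skipped
  (no axis is defined); the degenerate-range error names the frame.
* The AVI codec writes uncompressed 8-bit palettized DIB frames; the
  reader accepts 8/24/32-bit uncompressed AVI and collapses color by
  BT.601 luminance. Compressed codecs are rejected with a message.

## Known limitations

* The applanation detector's peak position is intrinsically tied to the
  binarization threshold: analytically, the ratio width(A)/A for a
  Gaussian indentation peaks near A ≈ e^(1/2)·p_r. With the default
  p_r = 2 px this coincides with the phantom's curvature-cancellation
  amplitude σ²/R only for σ ≈ 52–72 px at R = 900 px, so recovery of the
  analytic applanation frames to ±2 frames holds near the default
  geometry (σ = 60) but degrades for much wider or narrower indentations.
  The same threshold dependence is why a threshold sweep is part of the
  toolkit: peak positions should always be read together with the
  p_r used.
* Small p_r values behave identically in pairs (the detected contour is
  integer-quantized, so all thresholds within one integer gap produce the
  same binary map); crossing an integer boundary can move a peak by a
  couple of frames even on a noise-free phantom.
* After the 3×3×3 median, replicate padding can bias the band edge by one
  row in the outermost columns; detection on clean input is within ±1 px
  of the true contour everywhere, the full chain within 1.5 px.
* Problem sizes in the test-suite: full-size (200×576×140) sequences are
  used for the noise-free and default-noise phantoms and for the 20-run
  applanation-recovery study; the 100-phantom arc-vs-chord study and the
  decomposition-identity study run on the analytic contour grids directly
  (rendering and edge detection add nothing to those properties).
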
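# Methods

`cimt` measures the intima–media thickness (IMT) of the common carotid
artery far wall in longitudinal B-mode ultrasound images. This note
documents the model behind each stage, the parameters that matter, the
synthetic phantom substrate the package is validated on, and the known
limitations.

## The measurement model

A longitudinal scan of the common carotid artery shows, in depth order:
the dark blood-filled lumen, the intima–media complex (IMC — a
medium-bright intima band over a dark media band), and the bright
adventitia. The IMT is the vertical distance between the lumen–intima
interface (LII) and the media–adventitia interface (MAI). Both
interfaces are near-horizontal, nearly parallel, and both are
dark-above/bright-below transitions — the three structural facts the
pipeline exploits.

The pipeline has six cascaded stages:

1. **ROI extraction by template matching.** A small template patch
   containing an IMC strip plus some lumen and adventitia is slid along
   seven evenly spaced vertical lines; on each line the center position
   minimizing the sum of absolute differences (SAD)

   `SAD(x, y) = Σ_{i,j} | f(i, j) − T(i', j') |`

   over the template footprint marks the IMC. A match is trusted only if
   its vertical position agrees within 2 mm with at least three other
   matches (the vessel is near-horizontal, so correct matches cluster in
   depth); at least four trusted matches are required, otherwise the
   image is rejected as unprocessable. A rectangle of half-height
   `d = 20 px` around the median trusted row, spanning the trusted
   columns, becomes the ROI.

2. **Bilateral speckle filtering.** Each ROI pixel is replaced by a
   normalized Gaussian-in-space × Gaussian-in-intensity weighted mean of
   its square neighborhood. The intensity (range) kernel stops smoothing
   across strong steps, preserving the thin interfaces while flattening
   speckle. The discrete realization uses a square window clipped and
   renormalized at borders — no invented padding values.

3. **Initial LII by thresholding.** The filtered ROI intensity histogram
   of a healthy wall is roughly tri-modal (dark lumen+media / intima /
   adventitia); a threshold `T1 = 0.1` below the intima mode separates
   lumen from intima. A per-column state machine traces the first
   super-threshold pixel into an eight-neighborhood-continuous rough
   boundary (±1 row per column, re-anchoring on equality), and
   morphological closing of the thresholded mask (square element,
   `r = 15 px`) bridges columns where artifacts locally erase the
   intima. The initial LII is the top contour of the closed mask, with
   any still-empty columns linearly interpolated.

4. **Initial MAI by parallel displacement.** The ROI is correlated with
   a vertical first-order derivative-of-Gaussian kernel (10×10, σ = 1),
   signed so dark-to-bright-downward edges respond positively. The
   initial LII is displaced downward through the physiological IMT range
   0.4–1.4 mm (7–23 px at 16.66 px/mm); the displacement whose line
   accumulates the strongest summed edge response is the initial MAI.

5. **Dynamic-programming refinement.** Each boundary is snapped to its
   exact location by maximizing

   `h(x_1..x_N) = Σ_k g(x_k) + λ Σ_k c(x_{k−1}, x_k, x_{k+1})`,

   with `g` the signed edge response, `λ = −0.2`, and `c` the discrete
   Williams–Shah-type curvature `‖ v_k/|v_k| − v_{k+1}/|v_{k+1}| ‖²`
   (zero for collinear points, 4 for a reversal). One pass lets each
   column move at most one pixel and finds the exact banded optimum by
   dynamic programming over consecutive-row-pair states (the pair state
   makes the three-point curvature term stage-decomposable); passes are
   iterated to a fixed point, so an estimate several pixels off walks
   onto the edge ridge while every pass stays globally optimal in its
   band. Energy is non-decreasing across passes by construction, and the
   implementation asserts it.

6. **Measurement and gate.** `IMT = mean_k |MAI(k) − LII(k)| / density`
   in mm. The measurement is accepted only if every per-column distance
   lies in 0.2–1.6 mm; collapsed (overlaid) or exploded boundaries are
   reported as failures, never as thickness values. Cohort agreement
   against ground truth uses the Pearson product-moment correlation and
   Bland–Altman analysis (bias, SD of paired differences, bias ± 1.96 SD
   limits of agreement, sample SD with n−1 denominator).

## Parameters

| name | default | unit | role |
| --- | --- | --- | --- |
| `roi_half_height` (d) | 20 | px | ROI half-height around the matched IMC row |
| `lii_threshold` (T1) | 0.1 | intensity | lumen/intima separation threshold |
| `closing_size` (r) | 15 | px | square closing element bridging intima gaps |
| `curvature_weight` (λ) | −0.2 | – | smoothness pressure of the DP objective |
| `sigma_spatial` | 3 | px | bilateral closeness kernel width |
| `sigma_range` | 0.1 | intensity | bilateral similarity kernel width |
| `window_radius` | 7 | px | bilateral window radius (≥ 2σ_spatial) |
| `band_halfwidth` | 1 | px | per-pass DP search band |
| `max_passes` | 20 | – | DP iteration cap |
| `imt_range_mm` | (0.4, 1.4) | mm | MAI displacement search range |
| `valid_range_mm` | (0.2, 1.6) | mm | per-column distance validity gate |
| `pixel_density` | 16.66 | px/mm | physical sampling density |

The first four reproduce the reference operating point of the method;
for a new scanner only the template and `T1` normally need adjusting
(`T1` can be taken adaptively from the first histogram valley when the
tri-modal structure is unambiguous — `adaptive_threshold=True`).
The bilateral kernel widths are tuning choices: σ_range = 0.1 is large
enough to pool speckle fluctuations (≈ 0.04–0.08 intensity units on the
phantoms) while far below the 0.3–0.4 inter-layer contrasts, so layer
interiors flatten and interfaces survive.

## Numerical choices

- All processing happens in float64 intensities on [0, 1]; 8-bit
  quantization only at file I/O.
- Coordinates are 0-based `(row, col)` with row = depth. Physical
  lengths convert via `mm × pixel_density` with no hidden rounding;
  displacement bounds round half-up.
- SAD ties break to the smallest row; equal MAI displacement sums break
  to the smaller displacement; equal-energy DP boundaries break to the
  lexicographically smallest row sequence (realized exactly by a
  backward value recursion plus greedy forward selection). On an exactly
  zero edge-response plateau the DP tie-break therefore drifts a
  boundary upward one pixel per pass — harmless wherever any edge
  response exists, and it is what collapses a spurious MAI onto the
  adventitia edge in the missing-intima failure mode.
- The 10×10 derivative-of-Gaussian kernel is sampled at half-pixel
  offsets (±0.5 … ±4.5) and applied by correlation; accumulation pairs
  the kernel's antisymmetric rows so a constant image yields an exactly
  zero edge map. The even kernel size implies a half-pixel localization
  offset that is common to LII and MAI and cancels in their distance.
- Curvature uses the squared magnitude of the normalized-vector
  difference; the plain magnitude is available as an option.

## The phantom substrate

The package is validated on synthetic phantoms, not clinical images.
`cimt.synthetic` renders the four tissue layers at defaults 0.05 / 0.45
/ 0.15 / 0.85 (lumen / intima / media / adventitia), with per-column
sub-pixel ground-truth boundaries (constant, sloped, or gently
sinusoidal), a 1-px linear ramp at each interface so edge responses peak
cleanly, multiplicative speckle `(1 + σ·N(0,1))` (unit-mean Rayleigh as
a variant), clipping, and 8-bit quantization. The default frame is
256 × 384 px at 16.66 px/mm — large enough for the full ROI geometry at
the thickest measurable wall, small enough that a 50-image cohort runs
in seconds. Cohorts draw IMT from a normal distribution truncated to
the measurable 0.2–1.6 mm range (default mean 0.67 mm, SD 0.13 mm — a
typical adult screening distribution) with per-phantom random slope and
depth jitter; sub-seeds derive deterministically from the cohort seed.
The failure-mode phantom renders the whole intima–media complex
echolucent (lumen running straight into the adventitia), which is what
makes such images clinically unmeasurable.

What the phantoms do *not* emulate: log-compressed Rayleigh speckle
statistics of real scanners, attenuation and focal-zone contrast drift,
plaque, vessel curvature beyond gentle slopes/sinusoids, and operator
variability. Passing phantom tests therefore demonstrates correctness
of the algorithmic chain and its failure gates, not clinical-grade
accuracy on scanner data.

## Known limitations

- **Plaque:** the LII threshold step assumes a clean dark lumen; plaque
  protruding into the lumen is traced as if it were the intima.
- **Speckled missing-intima images:** when the intima–media complex is
  invisible, the initial "LII" lands on the adventitia edge and the
  downward MAI search scans featureless tissue. Without noise the DP
  collapses both boundaries onto the one real edge and the 0.2–1.6 mm
  gate rejects the image; under speckle the MAI can lock onto noise
  ripples at a plausible distance, which the distance gate cannot catch.
  The histogram diagnostic (`HistogramAnalysis.ambiguous`) flags such
  ROIs — absent tri-modal structure — and should be honored in any
  unattended deployment.
- **Template portability:** the template encodes pixel density and
  contrast; images from a different scanner or depth setting need a new
  template (and possibly a new `T1`).
- The iterated ±1-band DP corrects at most `max_passes` pixels of
  initial estimation error.
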
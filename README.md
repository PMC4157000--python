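# cimt — automatic carotid intima–media thickness measurement

`cimt` measures the intima–media thickness (IMT) of the common carotid
artery far wall in longitudinal B-mode ultrasound images — a standard
early marker of cardiovascular risk that is tedious and
observer-dependent to trace by hand. The package is aimed at medical
image-analysis researchers who need a fully automatic, deterministic,
testable IMT pipeline plus a synthetic phantom generator with exact
ground truth for validating it.

## Method

The far wall shows a dark lumen, a medium-bright intima band, a dark
media band and a bright adventitia. The IMT is the distance between the
lumen–intima interface (LII) and the media–adventitia interface (MAI).
The pipeline:

1. locates the intima–media complex by sum-of-absolute-differences
   template matching on seven vertical lines, cross-validates the
   matches (agreement within 2 mm with ≥ 3 others, ≥ 4 survivors
   required) and cuts a rectangular ROI around them;
2. despeckles the ROI with an edge-preserving bilateral filter;
3. estimates the LII as the top contour of the intensity mask above a
   threshold `T1 = 0.1`, with morphological closing bridging local
   intima dropouts;
4. estimates the MAI by displacing the LII downward through the
   physiological 0.4–1.4 mm range and keeping the displacement with the
   strongest summed vertical-derivative-of-Gaussian edge response;
5. refines both boundaries with banded dynamic programming maximizing

   `h(x_1..x_N) = Σ_k g(x_k) + λ Σ_k c(x_{k−1}, x_k, x_{k+1})`,  λ = −0.2,

   where `g` is the signed edge strength and `c` a discrete three-point
   curvature — each ±1-pixel pass is solved exactly, and passes iterate
   to a fixed point;
6. reports `IMT = mean_k |MAI(k) − LII(k)|` in mm, rejecting any
   measurement whose per-column distances leave 0.2–1.6 mm, and computes
   Pearson-R / Bland–Altman agreement against ground truth for cohorts.

See `docs/methods.md` for the full model, parameters and limitations.

## Worked example

Generate a speckled 5-phantom cohort with known ground truth, build a
matching template, measure every image, and check agreement:

```sh
cimt simulate --out-dir cohort -n 5 --seed 1 --speckle-sigma 0.08 \
     --template-out tmpl.png
cimt batch cohort tmpl.png --out-csv results.csv \
     --gt-csv cohort/ground_truth.csv
cimt validate results.csv cohort/ground_truth.csv
```

which prints

```
5 phantoms written; ground truth in cohort/ground_truth.csv
template written to tmpl.png
5/5 images measured; results in results.csv
agreement (n=5): R=0.9992 bias=0.0023 mm sd=0.0092 mm LoA=[-0.0156, 0.0203] mm
n=5 R=0.9992 bias=0.0023 mm sd=0.0092 mm LoA=[-0.0156, 0.0203] mm
```

All five phantoms measure validly; the automatic IMT tracks the
ground truth with a bias of 0.002 mm (well under one pixel, 0.06 mm at
16.66 px/mm) and tight limits of agreement. A single image can be
measured with `cimt measure image.png tmpl.png`, and `--overlay`
writes the ROI with the refined boundaries burned in. The same
functionality is available as a library (`cimt.run_pipeline`,
`cimt.generate_cohort`, ...).

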
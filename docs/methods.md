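# Methods

This note documents the models, discretizations and design choices behind
`carotidseg`, and what the synthetic phantoms do and do not establish.

## Conventions

Images are 8-bit grayscale rasters, row-major, origin top-left; x runs
rightward over columns, y downward over rows.  Pixel boxes are half-open:
`PixelBox(left, top, width, height)` covers columns `left .. left+width-1`
and rows `top .. top+height-1`.  This one convention is used for masks,
detections, scanning windows and normalized labels alike; with it, a
full-image box normalizes to center (0.5, 0.5) and size (1.0, 1.0) exactly.
Binary masks rasterize analytic geometry by the pixel-center rule (a pixel
belongs to a region iff its index coordinate satisfies the region test),
which makes geometric oracles exact.  All windowed image operations use
reflect padding (`numpy.pad(mode="reflect")`), avoiding the dark-frame
artifacts that zero padding would inject into the snake's edge map.

## Synthetic phantoms

A phantom is a piecewise-constant intensity map — lumen 25, tissue 120,
wall rim 190 (thickness 4 px) — multiplied by unit-mean gamma speckle with
shape `L = speckle_looks` (default 4) and clipped to [0, 255].  This is the
standard fully-developed-speckle approximation with a single parameter: the
point contrast σ/μ of each region is 1/√L, so the lumen (mean 25, σ ≈ 12.5)
satisfies the scanning-window thresholds (mean < 60, σ < 15) by
construction, while tissue is heavily speckled (σ ≈ 60).  Transverse
phantoms are 176×176 with an elliptical lumen (semi-axes 30×25 px);
longitudinal phantoms are 224×160 with the lumen as a horizontal band (rows
84–128).  The default longitudinal phantom adds a *decoy*: a thinner dark
band (rows 48–68, 20 px high — thinner than the 30 px scanning window, as
the compressible jugular usually appears) with the same mean as the lumen,
reproducing the jugular-vein confound.  The decoy is deliberately included
in the oracle detection box for longitudinal runs, because a realistic
localization box around the vascular complex contains both vessels — that
confound is precisely what the mask generator exists to solve.

What the phantoms do **not** emulate: beam-dependent point-spread functions,
log-compression of the display dynamic range, intraluminal blood-flow
echoes, shadowing, curved or bifurcating vessels.  Passing on phantoms
therefore demonstrates the internal correctness and robustness of each
stage under speckle and the decoy confound — not clinical performance.

## Enhancement chain

Stages run in fixed order: bilateral → CLAHE → gamma → NLM → high-boost.

- **Bilateral**: normalized weighted average with spatial Gaussian σ_s = 3 px
  and range Gaussian σ_r; window radius ⌈3σ_s⌉.
- **CLAHE**: 8×8 tiles, per-bin clip at 0.02 × tile pixel count (the
  normalized-fraction dialect — 0.02 is only meaningful on that scale),
  excess redistributed uniformly, per-tile equalization LUTs interpolated
  bilinearly between tile centers (clamped at borders).  With one tile and
  clip 1 this reduces to plain global histogram equalization.
- **Gamma**: `255·k·(I/255)^γ` with γ = 1.2, k = 1 — normalization is by the
  fixed 8-bit range, not image min/max, so the transform is
  image-independent and monotone.
- **NLM**: search 21, patch 7; weights `exp(−d²/h²)` with d² the *mean*
  squared patch difference.  The sum-form distance with any practical h
  collapses all weights to zero at 7×7 patches; the mean form keeps h on the
  gray-level scale.
- **High-boost**: `I + α(I − G_σ·I)` with α = 1.5, blur σ = 2 px.

Denoiser strengths are matched to the imaging conditions the phantoms
define: σ_r = 60 and h = 60 gray levels, i.e. the speckle amplitude of the
tissue background (σ ≈ tissue_mean/√L = 60).  Much smaller range scales
leave the chain effectively non-denoising on fully developed speckle, at
which point CLAHE and high-boost only amplify noise and preprocessing stops
helping the contouring stage.

**Quality metrics and their direction.**  The report carries Shannon entropy
of the 256-bin histogram, population STD, and mean Sobel gradient magnitude,
before and after.  On clinical frames — low-contrast, blurry — enhancement
raises all three.  On the default phantoms the *input* is noise-saturated
(entropy ≈ 7.7 of 8 bits, STD ≈ 60, MGM ≈ 237, all dominated by speckle),
so a chain that genuinely denoises lowers them; no deterministic intensity
mapping can raise the entropy of an already near-uniform histogram.  The
package keeps the segmentation-first parameterization and reports the
decrease honestly; the increase reported on clinical material is a property
of that material, not of the chain alone.

## Snake (transverse)

The closed contour is n = 120 points with unit parameter spacing,
minimizing `Σ ½(α|Δx|² + β|Δ²x|²) + γ·E_ext(x_i)` with E_ext the negated,
σ = 1 px Gaussian-smoothed, squared gradient magnitude, normalized to
[−1, 0] so γ is scale-free against image contrast.  Internal terms advance
semi-implicitly through the cyclic pentadiagonal system
`x⁺ = (I + τA)⁻¹(x + τf_ext)`; the external force is bilinear interpolation
of −∇E_ext.  Defaults α = 1.5, β = 0.3, γ = 2, τ = 0.5: the tension must be
strong enough to carry the contour from the padded box across the weak
outer wall edge, while the (≈5× deeper) lumen-wall edge well holds it — the
ratio, not the absolute scale, is what matters.  A backtracking safeguard
halves τ whenever a step would raise the discrete energy, so the recorded
trace is non-increasing; evolution stops when the mean displacement falls
below 0.05 px or no energy reduction is possible.  Contours are rasterized
to masks by the even-odd (crossing-number) rule on pixel centers, which is
also well-defined for self-intersecting polygons; degenerate zero-area
contours yield an empty mask with a warning.

## Scanning-window mask generator (longitudinal)

`reduce(0.6, about the box center) → scan 30×30 windows at 5 px steps →
candidates where mean < 60 and σ < 15 → minimal mean+σ (ties: topmost,
leftmost) → widen ×4, keep height and vertical position, re-center
horizontally on the detection box, clip, re-validate (revert on failure)`.
"Reduce with 60 %" is read as *keep* 60 % (scale factor 0.6): removing 60 %
would often leave no room for a 30 px window.  The stride appends a final
flush offset when the region extent is not a multiple of the step, so the
region is always fully covered.  If no window passes the thresholds the
globally minimal-score window is used and the result flagged — robustness
over aborting.  Decoy rejection is emergent, not rule-based: the reduced,
centered region clips the decoy band to a sliver thinner than the window,
so every window touching it straddles the bright rim and fails the σ
threshold.

## Chan-Vese (longitudinal)

Intensities are normalized to [0, 1] internally, putting the weights on
order-1 scales: μ = 0.2, ν = 0, λ₁ = λ₂ = 1 (the same energy as the 8-bit
convention with μ = 0.2·255², up to the constant factor).  The level set
advances along the Euler-Lagrange flow with the smoothed Heaviside
`S_ε(t) = ½(1 + (2/π)·arctan(t/ε))`, ε = 1, and is reinitialized to a
signed distance function every 10 iterations (distance transform of the
sign — no extra PDE).

Two numerical choices matter:

1. **Monitored energy is the sharp (ε = 0) energy of the current
   segmentation.**  It depends only on `sign(V)`, so signed-distance
   reinitialization leaves it invariant and can run unconditionally, while
   the backtracking step control (halve dt on any would-be increase) makes
   the recorded trace exactly non-increasing.  Monitoring the smoothed
   surrogate instead either breaks monotonicity at reinitialization or, if
   reinitialization is gated on it, rejects the reset systematically until
   the front freezes.
2. **dt = 200 with convergence spanning a reinit cycle.**  The smoothed
   delta vanishes quadratically away from the zero level, so the front
   advances in bursts after each reinitialization and stalls before the
   next; a sign-change convergence test (tol = 2·10⁻⁵ of pixels) only
   counts after a quiet stretch longer than one full cycle.  Backtracking
   bounds the effective step, so the large nominal dt is safe.

Divergence — non-finite values, or magnitudes beyond any image-scale signed
distance (>10³⁰) — raises a `NumericalInstabilityError`, which the pipeline
surfaces as a structured `"failed"` result: non-convergence is an outcome
the ablation harness tabulates, not a crash.

Degenerate region means (an empty side under a whole-image initialization)
default to the global mean.  This makes the whole-image configuration
collapse gracefully: the force reduces to curvature flow, the evolution
stalls near its initialization, and the configuration scores worst — the
qualitative "whole-image initialization is unusable" outcome.

## Evaluation

Scores use the pixel-set formulas (Dice, sensitivity, specificity,
accuracy) and carry the equivalent TP/FP/FN/TN counts.  Conventions for
degenerate denominators (empty ground truth, both masks empty) are resolved
explicitly and flagged.  The paired t test is the classic two-sided test on
per-item differences; zero-variance differences map to p = 1 (zero mean) or
p = 0 (nonzero mean), flagged.

## Problem sizes and determinism

Phantom sizes (176×176, 224×160) and batch sizes (20 seeds per condition in
the acceptance script, 10–25 in property tests) were chosen so that each
stage's behavior is measured over many independent speckle realizations
while a full pipeline run stays under a second.  Every stochastic input is
a `numpy` `default_rng` seeded from the phantom spec or the script's
`--seed`; identical inputs give bit-identical outputs end to end.

## Known limitations

- The snake has no balloon force: initialization must surround the target,
  as the recovered ROI box does by construction.
- Single two-phase Chan-Vese: multi-vessel scenes are handled only through
  initialization, not through a multiphase model.
- The phantom's speckle is spatially uncorrelated and not log-compressed;
  enhancement parameters tuned here are a starting point, not a clinical
  calibration.
- The detector is an interface; no learned localization model ships with
  the package.
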
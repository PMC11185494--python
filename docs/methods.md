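# Methods

## The edge-decision model

The array is a grid of photodiode pixels; the luminance a pixel senses
is taken as its value I(x, y) directly (in hardware this is a dark
current, but any monotone transduction is equivalent for threshold
comparisons, so the identity mapping loses nothing). Edge decisions are
pairwise and strictly gated:

- center marked  ⇔  I(x, y) > Thr + I(neighbor)
- neighbor marked ⇔ Thr + I(x, y) < I(neighbor)

applied for the right neighbor (x+α, y) and the down neighbor (x, y+α)
of every center. Equality to the gate is never an edge (strict
inequalities), and for Thr > 0 at most one side of a pair can be marked.
At Thr = 0 each comparison marks exactly its brighter member — which
means a pixel strictly dimmer than all of its compared partners is
never activated, even on an image with no two equal adjacent values.

**Neighbor convention.** Right and down at distance α, out-of-bounds
comparisons skipped (no padding — padding would fabricate luminance
differences at the border). This makes every unordered adjacent pair
compared exactly once, and hides no directional bias: mirroring an
image mirrors its activation map (tested).

**Sticky activation and scan order.** A pixel marked by any comparison
stays active. Because the final map is a logical OR over a fixed set of
pairwise predicates, the scan order cannot change it; the per-cluster
sequential scan (raster from each cluster's seed pixel, `top-left` by
default, `center` selectable) exists to mirror how the chip schedules
decisions concurrently across clusters, and the test suite enforces
order-independence by comparing against exhaustive evaluation of all
pairs. Clusters partition the grid by ceiling division (45×45 into a
5×5 cluster grid gives 25 blocks of 9×9); comparisons read across
cluster boundaries, so edges straddling clusters are not lost.

**Threshold quantization.** Thr is an index on a quantized scale:
step = round((max − min)/n_steps) with n_steps = 15, so an image
spanning 24–229 gives a step of 14 and Thr = 4 gates differences above
56. `RPEDParams.for_image` computes the step from the image's own
range; the bare default step of 17 corresponds to the full 0–255 range.

**Baselines.** The conventional rule activates a *center* when its
absolute difference to any of its four neighbors (distance α) exceeds
the gate (`any-neighbor`), or to the mean of its in-bounds neighbors
(`mean-of-neighbors`); both forms circulate and both are exposed, with
`any-neighbor` the default. Light-intensity stimulation activates every
pixel above a luminance cut.

## Quality metrics

MSE/PSNR are standard, computed in float64 (no overflow of squared
8-bit differences); PSNR of a perfect reconstruction returns `inf` as a
documented sentinel rather than an arbitrary cap. R and L are
2^bit_depth − 1 (255 by default).

The SSIM here is the **global-statistics form**: one mean, variance and
covariance per image, combined once. Packaged SSIMs are windowed
(local statistics averaged over sliding windows) and give different
numbers; `ssim_windowed` wraps the packaged implementation (uniform
square window, configurable size) for side-by-side comparison, but the
global form is the default and is what the sweep tables report. Its
population statistics (ddof = 0) satisfy ssim(x, x) = 1 exactly.

The reference pair for scoring a stimulation strategy is the original
grayscale image vs the **gray-level stimulation frame** (active pixels
keep their sensed intensity, inactive pixels 0) — this matches the
gray-level percept the charge-proportional stimulation aims at. A
binary (0/full-scale) rendering is selectable for sensitivity analysis.

## Parameter sweeps and α selection

Sweep tables hold one metric row per parameter value with
forward-difference gradient columns: gradient(i) = value(i) −
value(i−1), NaN for the first row. The α-selection rule returns the α
with the maximal PSNR forward difference — PSNR keeps rising with α,
but activated pixels (hence power) rise too, so the operating point is
the steepest *rise*, not the maximum. Ties break toward smaller α
(lower power); under strictly linear growth this selects the smallest α
that has a defined gradient. The published gradient magnitudes for this
rule were printed under an unstated definition that does not equal the
forward differences of the published sweep values; the selection
*outcome* (α = 2) is the contract this package honors, not the gradient
magnitude.

## Hardware model

Power is linear: activated-pixel power = n·V·I (0.5 mW per pixel at the
5 V / 100 µA defaults); processing power = (neighbors + 1)·clusters·V·I
(3 driven pixels per decision for the two-neighbor rule → 37.5 mW at 25
clusters; 5 → 62.5 mW). Frame time is serial:
pixels × neighbors × 2 µs (8.1 ms for 2025 pixels at 2 neighbors,
16.2 ms at 4); a parallel variant dividing by the cluster count is
provided but not default, because the serial figure is what the
published arithmetic uses. All values are reported unrounded, in mW and
ms. The electrode geometry (80 µm × 84 µm pixels, 10 µm spacing) is
carried as metadata only and enters no computation.

## Sobel and Canny on tiny grids

Both use replicate-edge padding. Sobel thresholds the magnitude
√(Gx²+Gy²) of the standard 3×3 kernels; the default cut is 0.25 of the
maximum observed magnitude (contrast-adaptive — there are no published
parameter values for the comparison, so these defaults are this
package's own choice, configurable). Canny runs Gaussian smoothing
(σ = 1.0), Sobel gradients, non-maximum suppression with direction
quantized to 4 sectors (0°, 45°, 90°, 135°; no interpolation — at 45×45
sub-pixel localization is meaningless), then double-threshold hysteresis
(fractions 0.1/0.2 of peak magnitude) keeping weak pixels 8-connected
to strong ones. NMS breaks plateau ties asymmetrically (strict
comparison on one side) so an ideal two-pixel-wide gradient plateau
thins to a single line.

## Phantoms: what they emulate and what they do not

The phantom generator stands in for a projector-and-chip bench: simple
high-contrast patterns (step, stripes, disc, ring, ramp, checker, 5×7
bitmap letter glyphs) at prosthesis resolutions, with bright salt
speckle (each pixel independently replaced by a fixed amplitude with
probability p) emulating ambient noise; Gaussian noise and a Gaussian
blur (a crude stand-in for charge dispersion between electrodes) are
optional. Defaults: 45×45 grid, background 10, foreground 200,
noise-free. Generation is deterministic given the spec (including its
seed).

What phantoms do **not** model: the optical point-spread function,
projector geometry, the analog readout chain, and real-scene luminance
statistics. Passing tests on phantoms therefore demonstrate the
*algorithmic* claims (boundary-exact activation, noise rejection by the
luminance gate, activation-count orderings) — not perceptual quality on
natural images. For the same reason, published absolute PSNR/SSIM
values and activation counts for a specific photograph are not
reproduction targets here: they depend on an unspecified crop and
downsampling of a source image this package deliberately does not ship.
The analytic quantities (power, timing, ratios, quantization,
α selection) are reproduced exactly.

## Numerical and I/O choices

- Images are validated integer grids; all metric arithmetic is float64.
- Coordinates are 0-based (row, col), rows increasing downward,
  consistently across modules and file I/O.
- PGM (P2/P5) is the canonical interchange format; non-255 maxvals are
  rescaled by round-half-up exact integer arithmetic
  (v → (510·v + maxval) div 2·maxval). Activation maps are written
  as 0/255.
- Percentages are rounded to 2 decimals only at the reporting surface;
  unrounded values are retained internally.
- CSV/JSON artifacts are byte-deterministic for a fixed configuration
  and seed, and embed the parameter set that produced them.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
inputs: random images up to 16×16 for exhaustive-oracle equivalence
(1,000 images in the suite, 400 in the script), and 45×45 phantoms for
the sweep, noise and comparison studies — the same grid size as the
2025-pixel array the hardware arithmetic describes.

## Known limitations

- The sequential scan is faithful to the decision *order* of a cluster
  scan but is not a cycle-accurate chip simulation; no analog pixel
  circuit or Thr-presetting protocol is modeled.
- The global-statistics SSIM saturates on images whose means dominate
  (its c₁ term), and is less discriminative than windowed SSIM on
  structured errors; both are exposed for that reason.
- `quantize_threshold_step` rounds to an integer step, so for very
  narrow value ranges (range < n_steps/2) the step is 0 and every
  nonzero luminance difference passes a Thr·0 = 0 gate.
- The conventional-baseline variant used in published comparisons is
  not identifiable from the two circulating descriptions; both are
  implemented and selectable.
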
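# rped — edge-detection stimulation for subretinal prosthesis arrays

Subretinal prostheses replace lost photoreceptor function with an
implanted pixel array: each pixel senses luminance through a photodiode
and can inject stimulation current into the surviving retinal network.
Driving every lit pixel wastes power (a safety problem for wirelessly
powered implants, which heat surrounding tissue) and smears the percept
through inter-electrode crosstalk. Stimulating only *edge* pixels fixes
both, but the edge decision must run on-chip, in real time (retinal
cells follow stimulation at roughly 10–25 Hz), on grids of only a few
thousand pixels.

This package implements and evaluates a **two-neighbor, threshold-gated,
cluster-seeded edge-detection rule** for such arrays (RPED: retinal
prosthesis edge detection), alongside everything needed to study it:

- **`rped.core`** — the RPED rule: each center pixel I(x, y) is compared
  against only its right and down neighbors at distance α. The center is
  marked when I(x, y) > Thr + I(x+α, y) (or the same against the down
  neighbor); the neighbor is marked when Thr + I(x, y) < I(x+α, y) (or
  down). Activation is *sticky*: once a pixel is marked by any
  comparison it stays active, so the per-cluster scan order provably
  cannot change the result. Thr is expressed as an index into a
  quantized luminance scale (the image's value range divided into 15
  steps). Also: the conventional 4-neighbor stimulation baseline and
  plain light-intensity stimulation.
- **`rped.evaluation`** — MSE, PSNR = 10·log₁₀(R²/MSE), and a
  global-statistics SSIM
  (2μₓμᵧ+c₁)(2σₓᵧ+c₂) / ((μₓ²+μᵧ²+c₁)(σₓ²+σᵧ²+c₂)) with
  c₁ = (0.01·L)², c₂ = (0.03·L)²; Thr/α sweep tables with
  forward-difference gradients, and the α-selection rule (steepest PSNR
  rise).
- **`rped.baselines`** — Sobel and four-stage Canny detectors suited to
  tiny grids (replicate padding, 4-sector non-maximum suppression,
  8-connected hysteresis).
- **`rped.hardware`** — chip power/latency arithmetic: activated-pixel
  power n·V·I, per-cluster processing power, serial frame time
  (pixels × neighbors × comparison time).
- **`rped.phantoms`** — synthetic stimuli (step, stripes, disc, ring,
  ramp, checker, letter glyphs) with salt noise, so every experiment is
  reproducible without external images.
- **`rped.cli`** — the `rped` command: `detect`, `compare`, `sweep`,
  `phantom`, `power`.

## Worked example

Generate a 45×45 ring phantom speckled with bright ambient noise, then
run the two-neighbor rule on it:

```sh
$ rped phantom --pattern ring --height 45 --width 45 \
      --noise-p 0.03 --noise-amplitude 60 --seed 2 --out ring.pgm
wrote ring.pgm
$ rped detect --input ring.pgm --thr-index 1 --thr-step 100 --alpha 1 --out ring_rped
rped: n_active=112 ratio=5.53% psnr=16.4845 dB
```

Only 112 of 2025 pixels (5.53%) need to be driven: the ring's boundary
pixels, with the luminance gate of 100 rejecting the amplitude-60
speckle entirely. The PSNR of 16.48 dB scores the gray-level
stimulation frame (active pixels keep their sensed intensity, inactive
pixels off) against the original. `ring_rped_activation.pgm`,
`ring_rped_frame.pgm` and a JSON sidecar with metrics, power and the
full parameter set are written next to it.

The chip-level cost of a stimulation pattern follows from the hardware
model (5 V supply, 100 µA per electrode, 2 µs per comparison, 25 scan
clusters):

```sh
$ rped power --active 575 --neighbors 2
activated pixel power: 287.5 mW
processing power: 37.5 mW
frame time: 8.1 ms
```

The two-neighbor rule needs 3 driven pixels per edge decision (center +
2 neighbors) against 5 for the 4-neighbor rule — 37.5 mW vs 62.5 mW of
processing power — and 4 µs per pixel against 8 µs, so a 2025-pixel
frame finishes in 8.1 ms vs 16.2 ms, comfortably inside the 40 ms
budget of 25 Hz stimulation.

`rped compare` runs all five methods (rped, conventional, sobel, canny,
intensity) on one input and writes a CSV with one row per method;
`rped sweep` reproduces Thr/α sweep tables with gradient columns.

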
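"""Synthetic test images emulating chip-bench stimuli.

The chip experiments project simple high-contrast patterns — letters,
stripes, a circular hole — onto the pixel array, with bright ambient
speckle as the nuisance.  This module generates those stimuli directly
as luminance grids (pixel value standing in for photodiode current; any
monotone transduction is equivalent for threshold comparisons), plus the
standard preprocessing: luma grayscale conversion and block-mean
downsampling to prosthesis resolutions such as 45x45 or 40x40.

Noise is salt-type by default (each pixel independently replaced by a
bright amplitude with probability ``noise_p``), matching the bench's
bright ambient speckle; Gaussian noise is available as an option.
All generation is deterministic given ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GrayImage, partition_clusters

__all__ = ["PhantomSpec", "generate_phantom", "to_grayscale", "downsample", "GLYPHS"]

# 5x7 bitmap glyphs ('#' = foreground), enough for letter-pattern stimuli
GLYPHS: dict[str, tuple[str, ...]] = {
    "A": ("..#..", ".#.#.", "#...#", "#...#", "#####", "#...#", "#...#"),
    "E": ("#####", "#....", "#....", "####.", "#....", "#....", "#####"),
    "H": ("#...#", "#...#", "#...#", "#####", "#...#", "#...#", "#...#"),
    "L": ("#....", "#....", "#....", "#....", "#....", "#....", "#####"),
    "O": (".###.", "#...#", "#...#", "#...#", "#...#", "#...#", ".###."),
    "T": ("#####", "..#..", "..#..", "..#..", "..#..", "..#..", "..#.."),
    "U": ("#...#", "#...#", "#...#", "#...#", "#...#", "#...#", ".###."),
    "X": ("#...#", ".#.#.", "..#..", "..#..", "..#..", ".#.#.", "#...#"),
}

_PATTERNS = ("step", "stripes", "disc", "ring", "ramp", "checker", "glyph")


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of one synthetic stimulus.

    Geometry fields are interpreted per pattern: ``step_col`` (first
    foreground column of a vertical step), ``stripe_width``,
    ``radius``/``thickness``/``center`` (disc and ring; ``center=None``
    means the grid center), ``glyph`` (a key of :data:`GLYPHS`, scaled
    to fill the grid).  ``noise_p`` is the per-pixel salt probability,
    ``noise_amplitude`` the salt luminance.
    """

    pattern: str = "step"
    out_height: int = 45
    out_width: int = 45
    foreground: int = 200
    background: int = 10
    step_col: int | None = None
    stripe_width: int = 4
    radius: float | None = None
    thickness: float = 3.0
    center: tuple[float, float] | None = None
    glyph: str = "E"
    noise_p: float = 0.0
    noise_amplitude: int = 255
    noise_kind: str = "salt"
    gaussian_sigma: float = 0.0
    blur_sigma: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in _PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        for v in (self.foreground, self.background, self.noise_amplitude):
            if not (0 <= v <= 255):
                raise ValueError("luminances must lie in [0, 255]")
        if not (0.0 <= self.noise_p <= 1.0):
            raise ValueError("noise_p must lie in [0, 1]")
        if self.out_height < 1 or self.out_width < 1:
            raise ValueError("output dimensions must be >= 1")
        if self.noise_kind not in ("salt", "gaussian"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")


def _draw(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.out_height, spec.out_width
    fg, bg = spec.foreground, spec.background
    rr, cc = np.mgrid[0:h, 0:w]
    if spec.pattern == "step":
        col = w // 2 if spec.step_col is None else spec.step_col
        return np.where(cc >= col, fg, bg)
    if spec.pattern == "stripes":
        return np.where((cc // spec.stripe_width) % 2 == 1, fg, bg)
    if spec.pattern in ("disc", "ring"):
        cy, cx = spec.center if spec.center is not None else ((h - 1) / 2, (w - 1) / 2)
        radius = spec.radius if spec.radius is not None else min(h, w) / 4
        if not (0 <= cy - radius and cy + radius <= h - 1 and 0 <= cx - radius and cx + radius <= w - 1):
            raise ValueError("disc/ring extends outside the grid")
        d = np.hypot(rr - cy, cc - cx)
        if spec.pattern == "disc":
            return np.where(d <= radius, fg, bg)
        return np.where((d <= radius) & (d >= radius - spec.thickness), fg, bg)
    if spec.pattern == "ramp":
        span = max(w - 1, 1)
        return np.round(bg + (fg - bg) * cc / span).astype(np.int64)
    if spec.pattern == "checker":
        s = spec.stripe_width
        return np.where(((rr // s) + (cc // s)) % 2 == 1, fg, bg)
    # glyph: scale the 5x7 bitmap to fill the grid (nearest neighbor)
    if spec.glyph not in GLYPHS:
        raise ValueError(f"no glyph {spec.glyph!r}; have {sorted(GLYPHS)}")
    bitmap = np.array([[ch == "#" for ch in row] for row in GLYPHS[spec.glyph]])
    gi = np.minimum((rr * bitmap.shape[0]) // h, bitmap.shape[0] - 1)
    gj = np.minimum((cc * bitmap.shape[1]) // w, bitmap.shape[1] - 1)
    return np.where(bitmap[gi, gj], fg, bg)


def generate_phantom(spec: PhantomSpec) -> GrayImage:
    """Render a phantom: pattern first, optional blur, noise last."""
    img = _draw(spec).astype(np.float64)
    rng = np.random.default_rng(spec.rng_seed)
    if spec.blur_sigma > 0:
        # optional stand-in for charge dispersion between electrodes
        from scipy import ndimage

        img = ndimage.gaussian_filter(img, spec.blur_sigma, mode="nearest")
    if spec.noise_p > 0:
        if spec.noise_kind == "salt":
            mask = rng.random(img.shape) < spec.noise_p
            img = np.where(mask, spec.noise_amplitude, img)
        else:
            img = img + rng.normal(0.0, spec.gaussian_sigma, img.shape)
    return GrayImage(np.clip(np.round(img), 0, 255).astype(np.int64))


def to_grayscale(rgb: np.ndarray) -> GrayImage:
    """8-bit RGB -> luminance via the standard luma weights
    0.299 R + 0.587 G + 0.114 B, rounded to nearest integer."""
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB array")
    luma = arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114
    return GrayImage(np.round(luma).astype(np.int64))


def downsample(image: GrayImage, out_height: int, out_width: int) -> GrayImage:
    """Block-mean downsampling over a ceiling-division partition of the
    input grid, rounded to nearest integer."""
    if out_height > image.height or out_width > image.width:
        raise ValueError("upsampling not supported")
    blocks = partition_clusters(image.height, image.width, out_height, out_width)
    if any(r1 <= r0 or c1 <= c0 for r0, c0, r1, c1 in blocks):
        # ceiling-division exhausts the grid early, e.g. 5 rows into 4
        raise ValueError(
            "output size incompatible with ceiling-division block partition"
        )
    out = np.empty((out_height, out_width), dtype=np.int64)
    vals = image.values
    for idx, (r0, c0, r1, c1) in enumerate(blocks):
        out[idx // out_width, idx % out_width] = int(round(vals[r0:r1, c0:c1].mean()))
    return GrayImage(out, bit_depth=image.bit_depth)
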
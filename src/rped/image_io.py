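"""Reading and writing images (PGM P2/P5, PNG).

PGM is the canonical interchange format here: plain text (P2) variants
diff cleanly in tests, and the maxval header lets files with a reduced
dynamic range round-trip through the documented rescale
``v -> round(v * 255 / maxval)``.  PNG support (via Pillow) is a
convenience; RGB inputs are converted through the standard luma weights.

Arrays follow the package-wide convention: 0-based (row, col), rows
increasing downward.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image as PILImage

from .core import ActivationMap, GrayImage, StimulationFrame
from .phantoms import to_grayscale

__all__ = ["read_image", "write_image", "ImageFormatError"]


class ImageFormatError(ValueError):
    """Unreadable or unsupported image file."""


def _read_pgm(path: Path) -> GrayImage:
    data = path.read_bytes()
    magic = data[:2]
    if magic not in (b"P2", b"P5"):
        raise ImageFormatError(f"{path}: not a PGM file (magic {magic!r})")

    # header tokens (width, height, maxval) with '#' comments allowed
    tokens: list[int] = []
    pos = 2
    while len(tokens) < 3:
        if pos >= len(data):
            raise ImageFormatError(f"{path}: truncated PGM header")
        ch = data[pos : pos + 1]
        if ch == b"#":
            pos = data.find(b"\n", pos)
            if pos == -1:
                raise ImageFormatError(f"{path}: truncated PGM comment")
        elif ch.isspace():
            pos += 1
        else:
            end = pos
            while end < len(data) and not data[end : end + 1].isspace():
                end += 1
            try:
                tokens.append(int(data[pos:end]))
            except ValueError as exc:
                raise ImageFormatError(f"{path}: bad PGM header token") from exc
            pos = end
    width, height, maxval = tokens
    if not (1 <= maxval < 65536):
        raise ImageFormatError(f"{path}: invalid maxval {maxval}")

    if magic == b"P5":
        pos += 1  # single whitespace after maxval
        itemsize = 1 if maxval < 256 else 2
        raster = np.frombuffer(
            data, dtype=">u2" if itemsize == 2 else np.uint8,
            count=height * width, offset=pos,
        )
    else:
        raster = np.array(data[pos:].split(), dtype=np.int64)
        if raster.size != height * width:
            raise ImageFormatError(
                f"{path}: expected {height * width} samples, got {raster.size}"
            )
    vals = raster.astype(np.int64).reshape(height, width)
    if vals.max(initial=0) > maxval:
        raise ImageFormatError(f"{path}: sample exceeds maxval {maxval}")
    if maxval != 255:
        # exact integer rescale, round half up: round(v * 255 / maxval)
        vals = (vals * 510 + maxval) // (2 * maxval)
    return GrayImage(vals)


def read_image(path) -> GrayImage:
    """Load a PGM (P2/P5) or PNG file as an 8-bit GrayImage.

    Non-255 PGM maxvals are rescaled to 0-255 (round half up); RGB
    PNGs are converted with luma weights 0.299/0.587/0.114.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"{path}: no such file")
    suffix = path.suffix.lower()
    if suffix in (".pgm", ".pnm"):
        return _read_pgm(path)
    if suffix == ".png":
        try:
            with PILImage.open(path) as im:
                if im.mode in ("RGB", "RGBA"):
                    arr = np.asarray(im.convert("RGB"), dtype=np.int64)
                    return to_grayscale(arr)
                if im.mode in ("L", "1", "P"):
                    return GrayImage(np.asarray(im.convert("L"), dtype=np.int64))
                raise ImageFormatError(f"{path}: unsupported PNG mode {im.mode}")
        except ImageFormatError:
            raise
        except Exception as exc:
            raise ImageFormatError(f"{path}: cannot read PNG ({exc})") from exc
    raise ImageFormatError(f"{path}: unsupported extension {suffix!r}")


def _as_uint8(obj) -> np.ndarray:
    if isinstance(obj, ActivationMap):
        return np.where(obj.active, 255, 0).astype(np.uint8)
    vals = obj.values if isinstance(obj, (GrayImage, StimulationFrame)) else np.asarray(obj)
    if np.min(vals) < 0 or np.max(vals) > 255:
        raise ValueError("values outside [0, 255] cannot be written as 8-bit")
    return np.asarray(vals, dtype=np.uint8)


def write_image(obj, path, plain: bool = False) -> None:
    """Write a GrayImage / StimulationFrame / ActivationMap.

    Format by extension: ``.pgm`` (binary P5, or plain-text P2 with
    ``plain=True``) or ``.png``.  Activation maps are written as 0/255.
    """
    path = Path(path)
    arr = _as_uint8(obj)
    h, w = arr.shape
    suffix = path.suffix.lower()
    if suffix in (".pgm", ".pnm"):
        if plain:
            lines = [f"P2\n{w} {h}\n255\n"]
            lines += [" ".join(str(v) for v in row) + "\n" for row in arr]
            path.write_text("".join(lines))
        else:
            path.write_bytes(b"P5\n%d %d\n255\n" % (w, h) + arr.tobytes())
    elif suffix == ".png":
        PILImage.fromarray(arr, mode="L").save(path)
    else:
        raise ValueError(f"unsupported output extension {suffix!r}")
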
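"""Image I/O, gray conversion, and result overlays.

Conventions used throughout the package:

* images are ``numpy`` arrays of shape ``(H, W, 3)``, dtype ``uint8``,
  channel order RGB;
* masks are boolean arrays of shape ``(H, W)``;
* pixel coordinates are ``(x, y) = (column, row)``, 0-based, origin at
  the top-left corner.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = ["read_image", "to_gray", "write_overlay"]

#: Rec.601 luma weights for the R, G, B channels.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/JPEG/TIFF photograph as an 8-bit RGB array.

    Alpha channels are dropped (the acquisition protocol produces opaque
    photos), grayscale inputs are replicated across the three channels,
    and 16-bit inputs are rescaled onto 0-255.

    Raises
    ------
    IOError
        If the file does not exist or cannot be decoded; the message
        names the offending path.
    """
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except (FileNotFoundError, UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise IOError(f"cannot read image file: {path!s} ({exc})") from exc

    if arr.ndim == 2:  # grayscale, possibly 16-bit
        arr = _to_uint8(arr)
        return np.dstack([arr, arr, arr])
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return _to_uint8(arr[:, :, :3])
    raise IOError(f"cannot read image file: {path!s} (unsupported layout {arr.shape})")


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return (arr.astype(np.float64) / 257.0).round().astype(np.uint8)
    if np.issubdtype(arr.dtype, np.integer):
        hi = max(int(arr.max()), 255)
        return (arr.astype(np.float64) * (255.0 / hi)).round().astype(np.uint8)
    # float images are assumed to live on [0, 1]
    return np.clip(np.round(arr.astype(np.float64) * 255.0), 0, 255).astype(np.uint8)


def to_gray(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to 8-bit gray with Rec.601 luminance.

    ``gray = round(0.299 R + 0.587 G + 0.114 B)`` with round-half-up, so
    the conversion is monotone in every channel.
    """
    img = np.asarray(img)
    wr, wg, wb = LUMA_WEIGHTS
    lum = wr * img[..., 0] + wg * img[..., 1] + wb * img[..., 2]
    return np.clip(np.floor(lum + 0.5), 0, 255).astype(np.uint8)


def write_overlay(
    img: np.ndarray,
    grain_mask: np.ndarray,
    germ_mask: np.ndarray,
    path: str | os.PathLike,
) -> None:
    """Write a PNG with grain pixels tinted green and germ pixels red.

    Germ tinting takes precedence where the two masks overlap.  Pixels
    outside both masks are copied verbatim, so empty masks reproduce the
    input image bit-exactly.
    """
    img = np.asarray(img, dtype=np.uint8)
    grain_mask = np.asarray(grain_mask, dtype=bool)
    germ_mask = np.asarray(germ_mask, dtype=bool)
    if grain_mask.shape != img.shape[:2] or germ_mask.shape != img.shape[:2]:
        raise ValueError("overlay masks must match the image dimensions")

    out = img.astype(np.float64)
    green = np.array([0.0, 255.0, 0.0])
    red = np.array([255.0, 0.0, 0.0])
    out[grain_mask] = 0.45 * out[grain_mask] + 0.55 * green
    out[germ_mask] = 0.45 * img[germ_mask].astype(np.float64) + 0.55 * red
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)

    try:
        Image.fromarray(out, mode="RGB").save(path, format="PNG")
    except OSError as exc:
        raise IOError(f"cannot write overlay image: {path!s} ({exc})") from exc
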
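"""Image containers, mask I/O and shared coordinate conventions.

All pixel values live in [0, 1] (8-bit inputs are divided by 255).
Coordinates are 0-based row-major; rectangular windows are half-open
``[row0, row1) x [col0, col1)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image


class ImageIOError(IOError):
    """Raised when an image or mask cannot be read or written."""


class DegenerateInputError(ValueError):
    """Raised when an input is too degenerate for the requested operation
    (e.g. a constant map handed to Otsu, or an empty mask handed to the
    interior-rectangle search)."""


@dataclass(frozen=True)
class RGBImage:
    """An RGB image as an ``(H, W, 3)`` float array with values in [0, 1].

    Channel order is (r, g, b).  Images must be at least 2x2: the
    correlation-based light decision is undefined on a single pixel.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) array, got shape {px.shape}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("images must be at least 2x2 pixels")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel values must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class BinaryMask:
    """A {0, 1} mask, either in full-image coordinates or window coordinates."""

    values: np.ndarray
    frame: str = "full-image"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {v.shape}")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        if self.frame not in ("full-image", "window"):
            raise ValueError(f"unknown mask frame {self.frame!r}")
        self.values = v.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class RectWindow:
    """Axis-aligned rectangle, half-open ``[row0, row1) x [col0, col1)``, 0-based."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if not (0 <= self.row0 < self.row1 and 0 <= self.col0 < self.col1):
            raise ValueError(f"invalid window bounds {self!r}")

    @property
    def height(self) -> int:
        return self.row1 - self.row0

    @property
    def width(self) -> int:
        return self.col1 - self.col0

    @property
    def area(self) -> int:
        return self.height * self.width

    def fits_in(self, shape: tuple[int, int]) -> bool:
        return self.row1 <= shape[0] and self.col1 <= shape[1]

    def crop(self, arr: np.ndarray) -> np.ndarray:
        return arr[self.row0 : self.row1, self.col0 : self.col1]

    def as_dict(self) -> dict:
        return {
            "row0": self.row0,
            "col0": self.col0,
            "row1": self.row1,
            "col1": self.col1,
        }


def load_image(path: str | os.PathLike) -> RGBImage:
    """Load a PNG/JPEG file as an :class:`RGBImage`.

    8-bit channels are mapped to [0, 1] by division by 255; grayscale inputs
    are replicated to three channels; alpha channels are dropped.
    """
    try:
        with Image.open(path) as im:
            if im.mode in ("I", "I;16", "F"):
                raise ImageIOError(
                    f"unsupported bit depth (mode {im.mode}) in {os.fspath(path)!r}"
                )
            if im.mode != "RGB":
                im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.float64) / 255.0
    except ImageIOError:
        raise
    except (OSError, ValueError) as exc:
        raise ImageIOError(f"cannot read image {os.fspath(path)!r}: {exc}") from exc
    return RGBImage(arr)


def intensity_of(img: RGBImage) -> np.ndarray:
    """Per-pixel intensity: the unweighted mean of the r, g, b channels."""
    return img.pixels.mean(axis=2)


def save_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a full-image-frame binary mask as an 8-bit PNG with {0, 255} values."""
    if mask.frame != "full-image":
        raise ValueError("only full-image-frame masks are written to disk")
    try:
        Image.fromarray(mask.values * np.uint8(255), mode="L").save(path)
    except OSError as exc:
        raise ImageIOError(f"cannot write mask {os.fspath(path)!r}: {exc}") from exc


def load_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a {0, 255} PNG as a binary mask (any nonzero pixel counts as 1)."""
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except OSError as exc:
        raise ImageIOError(f"cannot read mask {os.fspath(path)!r}: {exc}") from exc
    return BinaryMask((arr > 127).astype(np.uint8))
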
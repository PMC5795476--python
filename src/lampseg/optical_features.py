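"""The four per-pixel optical feature maps used to recognize artificial light.

For every pixel x the maps are

* ``Ci`` — global intensity contrast: sum over all pixels y of |I_x - I_y|
  of the intensity map.  Artificial light produces locally intense pixels
  that stand out from the whole image, so lit pixels score high.
* ``Vc`` — channel variation: (r - i)^2 + (g - i)^2 + (b - i)^2 where i is
  the channel mean.  Reflected artificial light is close to achromatic
  (the lamp restores the red that water removes), so lit pixels score low,
  while the blue-green ambient background scores high.
* ``Dd`` — intensity-position map: a monotone function of the Euclidean
  distance to the brightest pixel of the image, modelling the radially
  decaying halo around the lamp's collimation point.
* ``Cr`` — red-channel contrast: the same point-to-point contrast sum
  applied to the red channel only.  Ambient underwater light is red-poor,
  so red contrast concentrates where the lamp shines.

The contrast sums are quadratic if evaluated naively; they are computed
exactly through a 256-level histogram (see :func:`global_intensity_contrast`).
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike

import numpy as np
from PIL import Image

from .image_model import RGBImage


def quantize_256(values: np.ndarray) -> np.ndarray:
    """Quantize a [0, 1] map onto the 8-bit grid as int64 levels 0..255."""
    return np.rint(np.clip(values, 0.0, 1.0) * 255.0).astype(np.int64)


def _contrast_from_levels(levels: np.ndarray) -> np.ndarray:
    # Sum_y |q_x - q_y| = Sum_b hist(b) * |q_x - b|; exact in int64 arithmetic.
    hist = np.bincount(levels.ravel(), minlength=256)
    bins = np.arange(256, dtype=np.int64)
    per_level = np.abs(bins[:, None] - bins[None, :]) @ hist
    return per_level[levels] / 255.0


def global_intensity_contrast(intensity: np.ndarray) -> np.ndarray:
    """Per-pixel sum of absolute intensity differences to every pixel.

    The map is evaluated on the 256-level quantization of the intensity,
    where the histogram identity makes the O(N^2) double sum an exact
    O(N + 256^2) computation.  The pixel itself is included in the sum
    (it contributes zero).
    """
    return _contrast_from_levels(quantize_256(np.asarray(intensity)))


def red_channel_contrast(img: RGBImage) -> np.ndarray:
    """Global contrast of the red channel alone (same sum as ``Ci``)."""
    return _contrast_from_levels(quantize_256(img.pixels[..., 0]))


def channel_variation(img: RGBImage, intensity: np.ndarray | None = None) -> np.ndarray:
    """Sum of squared deviations of r, g, b from their per-pixel mean (no root)."""
    i = intensity_mean(img) if intensity is None else np.asarray(intensity)
    return ((img.pixels - i[..., None]) ** 2).sum(axis=2)


def intensity_mean(img: RGBImage) -> np.ndarray:
    return img.pixels.mean(axis=2)


def brightest_point(intensity: np.ndarray) -> tuple[int, int]:
    """Coordinate of the intensity maximum; ties go to the first pixel in
    row-major scan order."""
    intensity = np.asarray(intensity)
    flat = int(np.argmax(intensity))
    return tuple(int(v) for v in np.unravel_index(flat, intensity.shape))


def intensity_position(shape: tuple[int, int], m: tuple[int, int]) -> np.ndarray:
    """Raw intensity-position map: exp(d(x, m) / d_diag).

    ``d`` is the Euclidean pixel distance to the brightest point ``m`` and
    ``d_diag = sqrt(H^2 + W^2)`` the image diagonal.  Dividing by the
    diagonal keeps the exponential in a representable range on images of
    any size; it is a strictly monotone rescaling of the distance, which is
    all the downstream correlation and strength computations depend on.
    The map attains its minimum exp(0) = 1 at ``m``.
    """
    h, w = shape
    mr, mc = m
    if not (0 <= mr < h and 0 <= mc < w):
        raise ValueError(f"brightest point {m} outside image of shape {shape}")
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    dist = np.hypot(rows - mr, cols - mc)
    return np.exp(dist / np.hypot(h, w))


def normalize_map(raw: np.ndarray) -> np.ndarray:
    """Min-max normalization to [0, 1]; a constant map normalizes to all zeros."""
    raw = np.asarray(raw, dtype=np.float64)
    lo = raw.min()
    span = raw.max() - lo
    if span == 0.0:
        return np.zeros_like(raw)
    return (raw - lo) / span


@dataclass(frozen=True)
class FeatureMaps:
    """The four optical feature maps, raw and min-max normalized.

    The normalized maps (``ci``, ``vc``, ``dd``, ``cr``) are what the light
    decision consumes: the discrimination score multiplies correlations
    between them and the strength map adds them, both of which require a
    common scale.
    """

    ci_raw: np.ndarray
    vc_raw: np.ndarray
    dd_raw: np.ndarray
    cr_raw: np.ndarray
    ci: np.ndarray
    vc: np.ndarray
    dd: np.ndarray
    cr: np.ndarray
    brightest: tuple[int, int]

    @property
    def shape(self) -> tuple[int, int]:
        return self.ci.shape


def compute_feature_maps(img: RGBImage) -> FeatureMaps:
    """Compute all four maps for an image and normalize them to [0, 1]."""
    inten = intensity_mean(img)
    ci_raw = global_intensity_contrast(inten)
    vc_raw = channel_variation(img, inten)
    m = brightest_point(inten)
    dd_raw = intensity_position(img.shape, m)
    cr_raw = red_channel_contrast(img)
    return FeatureMaps(
        ci_raw=ci_raw,
        vc_raw=vc_raw,
        dd_raw=dd_raw,
        cr_raw=cr_raw,
        ci=normalize_map(ci_raw),
        vc=normalize_map(vc_raw),
        dd=normalize_map(dd_raw),
        cr=normalize_map(cr_raw),
        brightest=m,
    )


def save_feature_maps(maps: FeatureMaps, path_prefix: str | PathLike) -> None:
    """Export the normalized maps as 16-bit grayscale PNGs plus one .npz archive."""
    prefix = str(path_prefix)
    arrays = {"ci": maps.ci, "vc": maps.vc, "dd": maps.dd, "cr": maps.cr}
    np.savez_compressed(
        prefix + "_features.npz",
        **{k: v for k, v in arrays.items()},
        ci_raw=maps.ci_raw,
        vc_raw=maps.vc_raw,
        dd_raw=maps.dd_raw,
        cr_raw=maps.cr_raw,
    )
    for name, arr in arrays.items():
        png16 = np.rint(arr * 65535.0).astype(np.uint16)
        Image.fromarray(png16).save(f"{prefix}_{name}.png")
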
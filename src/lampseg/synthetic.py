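"""Seeded synthetic underwater scenes with known ground truth.

Each scene realizes the optical regime the pipeline is built for:

* a **collimated spotlight**: a near-flat bright beam core surrounded by
  an exponentially decaying scattering halo, centered on the object, so
  the intensity of any point falls off with its distance from the
  brightest point;
* **red restoration** inside the lit disk — water attenuates red fastest,
  so the ambient background is red-poor and blue-green, while the lamp
  locally restores red and makes the lit region near-achromatic;
* a **hazy background**: blue-green veiling light whose weight grows with
  the distance from the lamp (a proxy for the longer unlit water path),
  plus a smooth reflectance texture so the background is not trivially
  uniform;
* additive Gaussian pixel noise, clipped to [0, 1].

An *unlit* control scene renders the same object under uniform ambient
illumination only; it is the negative class for the light decision.
Scenes are bit-reproducible from ``(spec, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from os import PathLike

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_model import BinaryMask, RGBImage

#: ambient transmission per channel; red attenuates fastest underwater
DEFAULT_ATTENUATION = (0.22, 0.85, 0.70)
#: blue-green veiling light mixed in by haze
VEIL_COLOR = (0.05, 0.45, 0.55)
#: spotlight spectrum before red boost (slightly red-deficient white)
SPOT_COLOR = (0.80, 1.00, 0.95)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene; identical spec => identical scene."""

    size: tuple[int, int] = (128, 128)
    light_center: tuple[int, int] = (64, 64)
    light_radius_frac: float = 0.9  # beam radius as fraction of min(H, W)/2
    core_frac: float = 0.7  # flat beam core as a fraction of the beam radius
    halo_decay: float = 16.0  # exponential falloff rate of the edge halo, per radius
    hot_frac: float = 0.75  # lamp-axis hot spot radius, as a fraction of the core
    hot_amp: float = 0.25  # relative extra brightness of the hot spot
    red_boost: float = 0.4  # extra red gain of the lamp inside the lit disk
    haze_level: float = 0.5  # veiling-light mix in [0, 1)
    attenuation: tuple[float, float, float] = DEFAULT_ATTENUATION
    object_shape: str = "disk"  # "disk" | "ellipse" | "blob"
    object_albedo: tuple[float, float, float] = (0.55, 0.50, 0.47)
    object_scale: float = 0.45  # object radius as fraction of the beam core
    background_albedo: tuple[float, float, float] = (0.45, 0.48, 0.46)
    texture_strength: float = 0.1  # relative amplitude of background texture
    ambient_level: float = 0.3
    spot_amp: float = 1.6
    noise_sd: float = 0.01
    seed: int = 0
    lit: bool = True

    def __post_init__(self) -> None:
        h, w = self.size
        r, c = self.light_center
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError("light_center outside the image")
        if not 0.0 < self.light_radius_frac <= 1.0:
            raise ValueError("light_radius_frac must lie in (0, 1]")
        if not 0.0 < self.core_frac <= 1.0:
            raise ValueError("core_frac must lie in (0, 1]")
        if self.halo_decay <= 0 or self.red_boost < 0 or self.noise_sd < 0:
            raise ValueError("halo_decay must be > 0; red_boost, noise_sd >= 0")
        if not 0.0 <= self.haze_level < 1.0:
            raise ValueError("haze_level must lie in [0, 1)")
        if self.object_shape not in ("disk", "ellipse", "blob"):
            raise ValueError(f"unknown object shape {self.object_shape!r}")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SceneBundle:
    """A rendered scene with its ground-truth object and spotlight masks."""

    image: RGBImage
    object_mask: BinaryMask
    lit_mask: BinaryMask
    spec: SceneSpec

    def save(self, path_prefix: str | PathLike) -> None:
        from .image_model import save_mask
        from PIL import Image

        prefix = str(path_prefix)
        arr = np.rint(self.image.pixels * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="RGB").save(prefix + "_image.png")
        save_mask(self.object_mask, prefix + "_object.png")
        save_mask(self.lit_mask, prefix + "_lit.png")
        with open(prefix + "_spec.json", "w") as fh:
            json.dump(self.spec.as_dict(), fh, indent=2)


def _object_mask(spec: SceneSpec, dist: np.ndarray, angles: np.ndarray,
                 rng: np.random.Generator, radius: float) -> np.ndarray:
    obj_r = spec.object_scale * radius
    if spec.object_shape == "disk":
        return dist <= obj_r
    if spec.object_shape == "ellipse":
        phi = rng.uniform(0, np.pi)
        # radial boundary of an ellipse with axis ratio 0.65 at orientation phi
        a, b = obj_r, 0.65 * obj_r
        r_bound = a * b / np.sqrt(
            (b * np.cos(angles - phi)) ** 2 + (a * np.sin(angles - phi)) ** 2
        )
        return dist <= r_bound
    # blob: disk boundary modulated by low-order harmonics
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    r_bound = obj_r * (1.0 + 0.18 * np.sin(3 * angles + p1) + 0.12 * np.sin(5 * angles + p2))
    return dist <= r_bound


def generate_scene(spec: SceneSpec) -> SceneBundle:
    """Render one scene; bit-reproducible from the spec (incl. its seed)."""
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    dr, dc = rows - spec.light_center[0], cols - spec.light_center[1]
    dist = np.hypot(dr, dc)
    angles = np.arctan2(dr, dc)
    radius = spec.light_radius_frac * min(h, w) / 2.0

    lit_disk = dist <= radius
    core_radius = spec.core_frac * radius
    obj = _object_mask(spec, dist, angles, rng, core_radius)

    # reflectance: textured background, distinct object albedo
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=8.0)
    tmax = np.abs(texture).max()
    if tmax > 0:
        texture /= tmax
    reflect = np.empty((h, w, 3))
    for ch in range(3):
        bg = spec.background_albedo[ch] * (1.0 + spec.texture_strength * texture)
        reflect[..., ch] = np.where(obj, spec.object_albedo[ch], bg)
    reflect = np.clip(reflect, 0.0, 1.0)

    # illumination: ambient (wavelength-attenuated) plus the collimated beam:
    # a gently decaying flat core with a brighter lamp-axis hot spot, then an
    # exponential scattering halo beyond the core edge
    illum = np.empty((h, w, 3))
    if spec.lit:
        spot = np.exp(
            -0.08 * dist / radius
            - spec.halo_decay * np.maximum(dist - core_radius, 0.0) / radius
        )
        hot_r = spec.hot_frac * core_radius
        spot = spot * (
            1.0 + spec.hot_amp * np.exp(-np.maximum(dist - hot_r, 0.0) / (0.1 * radius))
        )
    else:
        spot = 0.0
    for ch in range(3):
        amb = spec.ambient_level * spec.attenuation[ch]
        direct = spec.spot_amp * SPOT_COLOR[ch] * spot if spec.lit else 0.0
        if ch == 0 and spec.lit:
            direct = direct * (1.0 + spec.red_boost * lit_disk)
        illum[..., ch] = amb + direct

    img = reflect * illum
    veil = np.array(VEIL_COLOR)[None, None, :]
    if spec.lit:
        # veiling light grows with the distance from the lamp: farther points
        # see a longer unlit water path, hence more scattered ambient light
        haze = spec.haze_level * (0.3 + 0.7 * dist / dist.max())[..., None]
    else:
        haze = spec.haze_level
    img = (1.0 - haze) * img + haze * veil
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    lit_mask = lit_disk if spec.lit else np.zeros((h, w), dtype=bool)
    return SceneBundle(
        image=RGBImage(img),
        object_mask=BinaryMask(obj.astype(np.uint8)),
        lit_mask=BinaryMask(lit_mask.astype(np.uint8)),
        spec=spec,
    )


def default_suite(n: int, seed: int, size: tuple[int, int] = (128, 128)) -> list[SceneBundle]:
    """n lit scenes plus n unlit controls with randomized geometry and optics.

    Centers, radii, halo rates, red boosts, haze levels, shapes and albedos
    are drawn from the documented default ranges; everything is
    deterministic in ``seed``.  Lit scenes come first, then their controls.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = size
    shapes = ("disk", "ellipse", "blob")
    specs = []
    for k in range(n):
        center = (
            int(rng.integers(int(0.44 * h), int(0.57 * h))),
            int(rng.integers(int(0.44 * w), int(0.57 * w))),
        )
        jitter = rng.uniform(-0.02, 0.02, size=3)
        specs.append(
            SceneSpec(
                size=size,
                light_center=center,
                light_radius_frac=float(rng.uniform(0.85, 0.95)),
                core_frac=float(rng.uniform(0.66, 0.74)),
                halo_decay=float(rng.uniform(13.0, 19.0)),
                red_boost=float(rng.uniform(0.35, 0.45)),
                haze_level=float(rng.uniform(0.45, 0.60)),
                object_shape=shapes[k % 3],
                object_albedo=tuple(np.clip(np.array((0.55, 0.50, 0.47)) + jitter, 0, 1)),
                object_scale=float(rng.uniform(0.40, 0.50)),
                noise_sd=0.01,
                seed=int(rng.integers(0, 2**31 - 1)),
                lit=True,
            )
        )
    bundles = [generate_scene(s) for s in specs]
    from dataclasses import replace

    bundles += [generate_scene(replace(s, lit=False)) for s in specs]
    return bundles


def hazy_subset(bundles: list[SceneBundle], min_haze: float = 0.52) -> list[SceneBundle]:
    """The lit scenes whose veiling-light level is at or above ``min_haze``."""
    return [b for b in bundles if b.spec.lit and b.spec.haze_level >= min_haze]
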
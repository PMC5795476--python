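"""Artificial-light recognition from the optical feature maps.

Inside a region collimated by an underwater lamp the four feature maps are
strongly coupled: high-contrast pixels sit near the brightest point (halo),
red contrast rises with intensity contrast (red restoration), and channel
variation drops where contrast is high (achromatic lamp light).  Each
coupling is scored by the global two-dimensional Pearson correlation of the
corresponding map pair, and the discrimination score S multiplies the four
correlations, so all couplings must hold simultaneously for S to be large.
A threshold on S (default 0.6) decides whether artificial light is present;
if it is, a per-pixel strength map W = Ci + Cr - Dd - Vc localizes it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from os import PathLike

import numpy as np

from .optical_features import FeatureMaps, normalize_map

DEFAULT_THRESHOLD = 0.6


def corr2(a: np.ndarray, b: np.ndarray) -> float:
    """Two-dimensional correlation: the Pearson correlation of the flattened
    maps.  Returns 0 when either map is constant (no structure means no
    evidence either way)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("correlation needs at least 2 pixels")
    da = a - a.mean()
    db = b - b.mean()
    va = float((da * da).sum())
    vb = float((db * db).sum())
    if va == 0.0 or vb == 0.0:
        return 0.0
    return float((da * db).sum() / np.sqrt(va * vb))


@dataclass
class LightDecision:
    """Outcome of the artificial-light decision for one image.

    ``score`` is the product of the four correlations in ``corr_terms``
    (order: Ci vs 1-Dd, Ci vs Cr, Ci vs 1-Vc, Dd vs Vc); ``exists`` is 1
    iff ``score`` strictly exceeds ``threshold_used``.  ``w`` is the
    normalized strength map (identically zero when ``exists`` is 0) and
    ``w_raw`` the unclamped sum it derives from.
    """

    score: float
    corr_terms: tuple[float, float, float, float]
    exists: int
    w: np.ndarray
    w_raw: np.ndarray
    threshold_used: float

    def to_json_dict(self) -> dict:
        return {
            "S": self.score,
            "corr_terms": list(self.corr_terms),
            "exists": self.exists,
            "threshold": self.threshold_used,
        }

    def save_json(self, path: str | PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)


def discrimination_score(maps: FeatureMaps) -> tuple[float, tuple[float, float, float, float]]:
    """Score S: product of the four feature-map correlations.

    Computed on the normalized maps.  The four factors encode, in order:
    contrast concentrates near the brightest point; red contrast follows
    intensity contrast; contrast is high where channel variation is low;
    channel variation grows with distance from the brightest point.
    """
    terms = (
        corr2(maps.ci, 1.0 - maps.dd),
        corr2(maps.ci, maps.cr),
        corr2(maps.ci, 1.0 - maps.vc),
        corr2(maps.dd, maps.vc),
    )
    return float(np.prod(terms)), terms


def decide_light(score: float, threshold: float = DEFAULT_THRESHOLD) -> int:
    """1 if the score strictly exceeds the threshold, else 0."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    return 1 if score > threshold else 0


def strength_map(maps: FeatureMaps, exists: int) -> tuple[np.ndarray, np.ndarray]:
    """Strength of the artificial light: W = Ci + Cr - Dd - Vc, gated by the
    existence flag.

    Returns ``(w, w_raw)`` where ``w_raw`` is the gated signed sum of the
    normalized maps and ``w`` its nonnegative part min-max normalized, ready
    for Otsu thresholding (negative strength has no physical reading).
    """
    w_raw = (maps.ci + maps.cr - maps.dd - maps.vc) * float(exists)
    if not exists:
        return np.zeros(maps.shape), w_raw
    return normalize_map(np.clip(w_raw, 0.0, None)), w_raw


def recognize_light(maps: FeatureMaps, threshold: float = DEFAULT_THRESHOLD) -> LightDecision:
    """Full decision: score, existence flag and strength map for one image."""
    score, terms = discrimination_score(maps)
    exists = decide_light(score, threshold)
    w, w_raw = strength_map(maps, exists)
    return LightDecision(
        score=score,
        corr_terms=terms,
        exists=exists,
        w=w,
        w_raw=w_raw,
        threshold_used=threshold,
    )
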
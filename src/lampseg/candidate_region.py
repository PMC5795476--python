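"""Candidate object region from the light-strength map.

The strength map W is thresholded with Otsu's method, and the candidate
window is the largest axis-aligned rectangle wholly inside the resulting
foreground.  The window — not the ragged Otsu mask — is what the
segmentation stage operates on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from os import PathLike

import numpy as np

from .image_model import BinaryMask, DegenerateInputError, RectWindow
from .optical_features import quantize_256

logger = logging.getLogger(__name__)


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu threshold of a [0, 1] map on its 256-level quantization.

    Maximizes the between-class variance over all splits of the 256-bin
    histogram; ties are broken toward the lowest qualifying bin.  The
    returned threshold is the midpoint (k + 0.5)/255 above the maximizing
    bin k, so the foreground is ``values > threshold`` and the threshold
    lies strictly between the two classes.
    """
    levels = quantize_256(np.asarray(values))
    if levels.min() == levels.max():
        raise DegenerateInputError("Otsu threshold undefined on a constant map")
    hist = np.bincount(levels.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    omega0 = np.cumsum(hist)  # class 0 = bins <= k
    mu0 = np.cumsum(hist * np.arange(256))
    mu_total = mu0[-1]
    omega1 = total - omega0
    valid = (omega0 > 0) & (omega1 > 0)
    sigma_b = np.zeros(256)
    num = (mu_total * omega0 - mu0 * total) ** 2  # scaled numerator, same argmax
    sigma_b[valid] = num[valid] / (omega0[valid] * omega1[valid])
    k = int(np.argmax(sigma_b))  # argmax takes the first (lowest) bin on ties
    return (k + 0.5) / 255.0


def largest_interior_rectangle(mask: BinaryMask) -> RectWindow:
    """Maximum-area axis-aligned rectangle of all-foreground pixels.

    Stack-based histogram sweep, O(H*W): each row acts as the base of a
    column-height histogram, and the largest rectangle in each histogram is
    found with a monotone stack.  Equal-area ties are broken by smallest
    row0, then smallest col0, then larger height.
    """
    m = mask.values
    if m.sum() == 0:
        raise DegenerateInputError("interior rectangle undefined on an empty mask")
    h, w = m.shape
    heights = np.zeros(w, dtype=np.int64)
    # best key: (-area, row0, col0, -height); smaller is better
    best_key = None
    best: RectWindow | None = None
    for r in range(h):
        heights = np.where(m[r] > 0, heights + 1, 0)
        stack: list[tuple[int, int]] = []  # (start_col, height)
        for c in range(w + 1):
            cur = int(heights[c]) if c < w else 0
            start = c
            while stack and stack[-1][1] > cur:
                s, bar = stack.pop()
                key = (-bar * (c - s), r - bar + 1, s, -bar)
                if best_key is None or key < best_key:
                    best_key = key
                    best = RectWindow(r - bar + 1, s, r + 1, c)
                start = s
            if not stack or stack[-1][1] < cur:
                if cur > 0:
                    stack.append((start, cur))
    assert best is not None
    return best


@dataclass
class CandidateRegion:
    """Otsu foreground of the strength map plus its largest interior rectangle.

    ``fallback`` is set when Otsu output was degenerate (empty or full
    foreground, or a constant map) and the window defaulted to the whole
    image so that the pipeline always produces a segmentation.
    """

    otsu_mask: BinaryMask
    window: RectWindow
    otsu_threshold: float
    fallback: bool = False

    def to_json_dict(self) -> dict:
        d = self.window.as_dict()
        d["otsu_threshold"] = self.otsu_threshold
        d["fallback"] = self.fallback
        return d

    def save_json(self, path: str | PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)


def identify_candidate(w_map: np.ndarray) -> CandidateRegion:
    """Otsu-segment the strength map and window it with the largest interior
    rectangle; degenerate Otsu output falls back to the whole image."""
    w_map = np.asarray(w_map)
    h, w = w_map.shape
    whole = RectWindow(0, 0, h, w)
    try:
        thr = otsu_threshold(w_map)
    except DegenerateInputError:
        logger.warning("constant strength map; falling back to whole-image window")
        return CandidateRegion(
            BinaryMask(np.ones((h, w), dtype=np.uint8)), whole, float("nan"), True
        )
    fg = (w_map > thr).astype(np.uint8)
    n_fg = int(fg.sum())
    if n_fg == 0 or n_fg == h * w:
        logger.warning("degenerate Otsu foreground; falling back to whole-image window")
        return CandidateRegion(BinaryMask(np.ones((h, w), dtype=np.uint8)), whole, thr, True)
    mask = BinaryMask(fg)
    return CandidateRegion(mask, largest_interior_rectangle(mask), thr, False)
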
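"""Kernel graph-cut segmentation inside the candidate window.

The objective over a labeling v and per-region model values {u_l} is

    psi({u_l}, v) = sum_l sum_{p in R_l} d_K(I_p, u_l)
                    + alpha * sum_{(p,q) in N} min((v(p) - v(q))^2, r_max)

where d_K is the kernel-induced distance ||phi(a) - phi(b)||^2 for an RBF
kernel, N the unordered 4-connected neighbor pairs, and the smoothness term
a truncated squared label difference (Potts-equivalent for two labels).
Mapping the data through the kernel bounds the cost of outliers at 2, which
makes the piecewise-constant model robust to the heavy-tailed intensities
of hazy scenes.

Minimization alternates two descent stages: with the labeling fixed, each
u_l is updated by a weighted-mean fixed point (exact stationary condition
of the RBF data term); with the models fixed, the optimal binary labeling
is found exactly by a single s/t min-cut (alpha-expansion sweeps for more
than two labels).  Both stages are guarded so the energy trace never
increases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from os import PathLike

import numpy as np

from ._maxflow import grid_pairs, solve_binary
from .image_model import BinaryMask, RectWindow, RGBImage
from .candidate_region import otsu_threshold
from .image_model import DegenerateInputError


@dataclass
class KGCParams:
    """Parameters of the kernel graph-cut minimizer.

    alpha : smoothness weight (> 0); higher values produce smoother masks.
    sigma : RBF kernel width, in the [0, 1] units of the channels.
    r_max : truncation bound of the squared label difference (with binary
        labels any value >= 1 is equivalent to a Potts penalty).
    n_labels : number of regions (2 = object/background).
    max_iters : maximum two-stage iterations.
    tol : convergence threshold on the fraction of pixels changing label.
    seed : RNG seed for the optional k-means initialization.
    init : "otsu" (deterministic, default) or "kmeans".
    """

    alpha: float = 1.0
    sigma: float = 0.15
    r_max: float = 1.0
    n_labels: int = 2
    max_iters: int = 20
    tol: float = 1e-3
    seed: int = 0
    init: str = "otsu"

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.sigma <= 0 or self.r_max <= 0:
            raise ValueError("alpha, sigma and r_max must be positive")
        if self.n_labels < 2:
            raise ValueError("need at least 2 labels")
        if not 0.0 < self.tol < 1.0:
            raise ValueError("tol must lie in (0, 1)")


def kernel_distance(a: np.ndarray, b: np.ndarray, sigma: float) -> np.ndarray:
    """Kernel-induced squared distance ||phi(a) - phi(b)||^2 for the RBF kernel:
    2 * (1 - exp(-||a - b||^2 / sigma^2)).  Bounded above by 2."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    diff = a - b
    if diff.ndim == 0:
        sq = diff * diff
    else:
        sq = (diff * diff).sum(axis=-1)
    return 2.0 * (1.0 - np.exp(-sq / (sigma * sigma)))


def smoothness_penalty(u: np.ndarray, v: np.ndarray, r_max: float) -> np.ndarray:
    """Truncated squared label difference min((u - v)^2, r_max)."""
    d = np.asarray(u, dtype=np.float64) - np.asarray(v, dtype=np.float64)
    return np.minimum(d * d, r_max)


def total_energy(
    pixels: np.ndarray, labels: np.ndarray, models: np.ndarray, params: KGCParams
) -> float:
    """Energy of a labeling: per-pixel kernel distances to the region models
    plus alpha times the truncated smoothness over 4-neighbor pairs."""
    data = kernel_distance(pixels, models[labels], params.sigma).sum()
    pen = smoothness_penalty(labels[:, :-1], labels[:, 1:], params.r_max).sum()
    pen += smoothness_penalty(labels[:-1, :], labels[1:, :], params.r_max).sum()
    return float(data + params.alpha * pen)


def _region_energy(pts: np.ndarray, u: np.ndarray, sigma: float) -> float:
    return float(kernel_distance(pts, u, sigma).sum())


def update_region_params(
    pixels: np.ndarray,
    labels: np.ndarray,
    sigma: float,
    prev_models: np.ndarray | None = None,
    max_rounds: int = 50,
    rel_tol: float = 1e-6,
) -> np.ndarray:
    """Fit the per-region model values with the labeling held fixed.

    For each label the stationary condition of the RBF data term is the
    weighted mean u = sum_p w_p I_p / sum_p w_p with w_p =
    exp(-||I_p - u||^2 / sigma^2); it is iterated from the region mean until
    the relative change drops below ``rel_tol``.  The update is a descent
    step on the data term by construction: if the fixed point ever yields a
    higher energy than the incumbent, the incumbent is kept.

    Labels with no pixels keep their previous model when one is supplied;
    otherwise they are dropped and remaining labels are compacted (callers
    that need a fixed label count should pass ``prev_models``).
    """
    n_labels = int(labels.max()) + 1 if prev_models is None else len(prev_models)
    flat_px = pixels.reshape(-1, pixels.shape[-1])
    flat_lab = labels.ravel()
    models = []
    for l in range(n_labels):
        pts = flat_px[flat_lab == l]
        if pts.shape[0] == 0:
            if prev_models is not None:
                models.append(np.asarray(prev_models[l], dtype=np.float64))
                continue
            models.append(None)
            continue
        u = pts.mean(axis=0)
        best_u, best_e = u, _region_energy(pts, u, sigma)
        if prev_models is not None:
            prev_u = np.asarray(prev_models[l], dtype=np.float64)
            prev_e = _region_energy(pts, prev_u, sigma)
            if prev_e < best_e:
                best_u, best_e = prev_u, prev_e
            u = best_u
        for _ in range(max_rounds):
            w = np.exp(-((pts - u) ** 2).sum(axis=1) / (sigma * sigma))
            ws = w.sum()
            if ws <= 0.0 or not np.isfinite(ws):
                break
            u_new = (w[:, None] * pts).sum(axis=0) / ws
            delta = np.linalg.norm(u_new - u) / max(np.linalg.norm(u), 1e-12)
            u = u_new
            if delta < rel_tol:
                break
        e = _region_energy(pts, u, sigma)
        if e < best_e:
            best_u, best_e = u, e
        models.append(best_u)
    if any(m is None for m in models):
        survivors = [m for m in models if m is not None]
        if not survivors:
            raise DegenerateInputError("all label classes are empty")
        models = survivors
    return np.asarray(models, dtype=np.float64)


def optimal_labeling(pixels: np.ndarray, models: np.ndarray, params: KGCParams) -> np.ndarray:
    """Best labeling with the models held fixed.

    For two labels this is the exact minimizer, found by a single s/t
    min-cut on the 4-connected grid (the truncated squared difference is
    submodular on two labels).  For more labels, alpha-expansion sweeps run
    until no move decreases the energy; each candidate move is accepted
    only if it does.
    """
    h, w = pixels.shape[:2]
    n_labels = len(models)
    data = np.stack(
        [kernel_distance(pixels, models[l], params.sigma).ravel() for l in range(n_labels)],
        axis=1,
    )
    pairs = grid_pairs(h, w)
    if n_labels == 2:
        pen01 = params.alpha * float(smoothness_penalty(0.0, 1.0, params.r_max))
        costs = np.zeros((pairs.shape[0], 4))
        costs[:, 1] = pen01
        costs[:, 2] = pen01
        labels = solve_binary(data[:, 0], data[:, 1], pairs, costs)
        return labels.reshape(h, w)
    return _alpha_expansion(data, pairs, params, h, w)


def _alpha_expansion(
    data: np.ndarray, pairs: np.ndarray, params: KGCParams, h: int, w: int
) -> np.ndarray:
    n_labels = data.shape[1]
    labels = np.argmin(data, axis=1).astype(np.int64)

    def energy(lab: np.ndarray) -> float:
        pen = smoothness_penalty(lab[pairs[:, 0]], lab[pairs[:, 1]], params.r_max)
        return float(data[np.arange(lab.size), lab].sum() + params.alpha * pen.sum())

    cur_e = energy(labels)
    improved = True
    while improved:
        improved = False
        for a in range(n_labels):
            lp, lq = labels[pairs[:, 0]], labels[pairs[:, 1]]
            costs = params.alpha * np.stack(
                [
                    smoothness_penalty(lp, lq, params.r_max),  # keep, keep
                    smoothness_penalty(lp, a, params.r_max),  # keep, switch
                    smoothness_penalty(a, lq, params.r_max),  # switch, keep
                    np.zeros(pairs.shape[0]),  # both switch to a
                ],
                axis=1,
            )
            theta0 = data[np.arange(labels.size), labels]
            theta1 = data[:, a]
            move = solve_binary(theta0, theta1, pairs, costs)
            cand = np.where(move == 1, a, labels)
            e = energy(cand)
            if e < cur_e - 1e-12:
                labels, cur_e = cand, e
                improved = True
    return labels.reshape(h, w)


@dataclass
class SegmentationResult:
    """Final object mask plus the optimization record.

    ``mask`` is in full-image coordinates (zeros outside the window);
    ``labels`` and ``models`` are in window coordinates; ``energy_trace``
    records the objective after every descent stage and is non-increasing.
    """

    mask: BinaryMask
    labels: np.ndarray
    window: RectWindow
    energy_trace: list[float] = field(default_factory=list)
    models: np.ndarray | None = None
    n_iters: int = 0
    object_label: int = 1

    def save_trace_json(self, path: str | PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "energy_trace": self.energy_trace,
                    "n_iters": self.n_iters,
                    "object_label": self.object_label,
                    "window": self.window.as_dict(),
                },
                fh,
                indent=2,
            )


def _init_labels(inten: np.ndarray, params: KGCParams) -> np.ndarray:
    if params.init == "kmeans":
        rng = np.random.default_rng(params.seed)
        vals = inten.ravel()
        centers = rng.choice(vals, size=params.n_labels, replace=False)
        for _ in range(10):
            lab = np.argmin(np.abs(vals[:, None] - centers[None, :]), axis=1)
            for k in range(params.n_labels):
                if (lab == k).any():
                    centers[k] = vals[lab == k].mean()
        return lab.reshape(inten.shape).astype(np.int64)
    try:
        thr = otsu_threshold(inten)
    except DegenerateInputError:
        return np.zeros(inten.shape, dtype=np.int64)
    lab = (inten > thr).astype(np.int64)
    if params.n_labels > 2:
        # split the brighter class into quantile bands for the extra labels
        bright = inten[lab == 1]
        qs = np.quantile(bright, np.linspace(0, 1, params.n_labels)[1:-1])
        lab = lab + np.searchsorted(qs, inten) * (lab == 1)
        lab = np.clip(lab, 0, params.n_labels - 1)
    return lab


def segment(
    img: RGBImage,
    window: RectWindow,
    params: KGCParams | None = None,
    strength: np.ndarray | None = None,
) -> SegmentationResult:
    """Segment the object inside the candidate window.

    Crops the image to the window, initializes labels by Otsu on the window
    intensity, and alternates model fitting and optimal labeling until the
    labeling stabilizes.  The label whose mean strength-map value is higher
    (mean intensity when no strength map is given) is designated the object;
    the window-frame mask is embedded back into full-image coordinates with
    background zeros outside.
    """
    params = params or KGCParams()
    if not window.fits_in(img.shape):
        raise ValueError(f"window {window} does not fit image of shape {img.shape}")
    crop = window.crop(img.pixels)
    inten = crop.mean(axis=2)
    labels = _init_labels(inten, params)
    models = update_region_params(crop, labels, params.sigma,
                                  prev_models=np.tile(crop.reshape(-1, 3).mean(0),
                                                      (params.n_labels, 1)))
    trace = [total_energy(crop, labels, models, params)]
    n_iters = 0
    for n_iters in range(1, params.max_iters + 1):
        new_labels = optimal_labeling(crop, models, params)
        e_lab = total_energy(crop, new_labels, models, params)
        if e_lab > trace[-1] + 1e-9:  # guard against capacity-rounding noise
            break
        changed = float(np.mean(new_labels != labels))
        labels = new_labels
        trace.append(e_lab)
        new_models = update_region_params(crop, labels, params.sigma, prev_models=models)
        e_mod = total_energy(crop, labels, new_models, params)
        if e_mod <= trace[-1] + 1e-9:
            models = new_models
            trace.append(min(e_mod, trace[-1]))
        if changed < params.tol:
            break

    guide = window.crop(strength) if strength is not None else inten
    label_ids = np.unique(labels)
    means = [guide[labels == l].mean() for l in label_ids]
    object_label = int(label_ids[int(np.argmax(means))])

    full = np.zeros(img.shape, dtype=np.uint8)
    full[window.row0 : window.row1, window.col0 : window.col1] = (
        labels == object_label
    ).astype(np.uint8)
    return SegmentationResult(
        mask=BinaryMask(full),
        labels=labels,
        window=window,
        energy_trace=trace,
        models=models,
        n_iters=n_iters,
        object_label=object_label,
    )
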
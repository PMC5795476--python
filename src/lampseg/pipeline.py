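"""End-to-end orchestration: features -> light decision -> candidate -> cut.

`run_pipeline` executes the five stages on one image and writes the
intermediate artifacts (feature maps, decision JSON, candidate JSON/PNG,
final mask PNG, energy trace).  `run_eval` scores a directory of predicted
masks against matching ground-truth masks.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .candidate_region import CandidateRegion, identify_candidate
from .evaluation import EvalReport, evaluate_masks, mean_report
from .image_model import BinaryMask, RectWindow, RGBImage, load_image, load_mask, save_mask
from .kernel_graphcut import KGCParams, SegmentationResult, segment
from .light_recognition import DEFAULT_THRESHOLD, LightDecision, recognize_light
from .optical_features import compute_feature_maps, save_feature_maps

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of the whole pipeline.

    ``threshold`` is the light-decision cutoff on the discrimination score S
    (0.6 by default).  When no artificial light is recognized and
    ``unguided_fallback`` is on, the whole image is segmented and the output
    is tagged "unguided".
    """

    threshold: float = DEFAULT_THRESHOLD
    kgc: KGCParams = field(default_factory=KGCParams)
    downscale_max_side: int | None = None
    unguided_fallback: bool = True
    output_dir: str | os.PathLike = "."
    log_level: str = "INFO"
    save_features: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kgc = KGCParams(**raw.pop("kgc", {}))
        return cls(kgc=kgc, **raw)


@dataclass
class PipelineOutput:
    decision: LightDecision
    candidate: CandidateRegion | None
    result: SegmentationResult | None
    guided: bool
    timings: dict


def _maybe_downscale(img: RGBImage, max_side: int | None) -> RGBImage:
    if max_side is None or max(img.shape) <= max_side:
        return img
    from PIL import Image

    scale = max_side / max(img.shape)
    new_w = max(2, round(img.width * scale))
    new_h = max(2, round(img.height * scale))
    arr = np.rint(img.pixels * 255.0).astype(np.uint8)
    im = Image.fromarray(arr, mode="RGB").resize((new_w, new_h), Image.BILINEAR)
    return RGBImage(np.asarray(im, dtype=np.float64) / 255.0)


def process_image(img: RGBImage, config: PipelineConfig | None = None) -> PipelineOutput:
    """Run the pipeline on an in-memory image; no artifacts are written."""
    config = config or PipelineConfig()
    timings: dict[str, float] = {}
    img = _maybe_downscale(img, config.downscale_max_side)

    t0 = time.perf_counter()
    maps = compute_feature_maps(img)
    timings["features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    decision = recognize_light(maps, config.threshold)
    timings["recognition"] = time.perf_counter() - t0
    logger.info(
        "light decision: S=%.4f terms=%s exists=%d (T=%.2f)",
        decision.score, [round(t, 3) for t in decision.corr_terms],
        decision.exists, config.threshold,
    )

    candidate = None
    guided = bool(decision.exists)
    if guided:
        t0 = time.perf_counter()
        candidate = identify_candidate(decision.w)
        timings["candidate"] = time.perf_counter() - t0
        window = candidate.window
        logger.info("candidate window: %s (otsu=%.4f)", window, candidate.otsu_threshold)
    elif config.unguided_fallback:
        h, w = img.shape
        window = RectWindow(0, 0, h, w)
        logger.info("no artificial light recognized; unguided whole-image segmentation")
    else:
        return PipelineOutput(decision, None, None, False, timings)

    t0 = time.perf_counter()
    strength = decision.w if guided else None
    result = segment(img, window, config.kgc, strength=strength)
    timings["segmentation"] = time.perf_counter() - t0
    logger.info(
        "segmentation: %d iterations, energy %.4f -> %.4f",
        result.n_iters, result.energy_trace[0], result.energy_trace[-1],
    )
    return PipelineOutput(decision, candidate, result, guided, timings)


def run_pipeline(
    image_path: str | os.PathLike, config: PipelineConfig | None = None
) -> PipelineOutput:
    """Run the pipeline on an image file and write all artifacts to
    ``config.output_dir`` (created if needed), named after the image stem."""
    config = config or PipelineConfig()
    img = load_image(image_path)
    out = process_image(img, config)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = Path(image_path).stem

    if config.save_features:
        maps = compute_feature_maps(_maybe_downscale(img, config.downscale_max_side))
        save_feature_maps(maps, outdir / stem)
    decision_dict = out.decision.to_json_dict()
    decision_dict["guided"] = out.guided
    with open(outdir / f"{stem}_decision.json", "w") as fh:
        json.dump(decision_dict, fh, indent=2)
    if out.candidate is not None:
        out.candidate.save_json(outdir / f"{stem}_candidate.json")
        save_mask(out.candidate.otsu_mask, outdir / f"{stem}_otsu.png")
    if out.result is not None:
        suffix = "mask" if out.guided else "mask_unguided"
        save_mask(out.result.mask, outdir / f"{stem}_{suffix}.png")
        out.result.save_trace_json(outdir / f"{stem}_energy.json")
    return out


def run_eval(
    pred_dir: str | os.PathLike,
    truth_dir: str | os.PathLike,
    csv_path: str | os.PathLike | None = None,
) -> tuple[dict[str, EvalReport], EvalReport]:
    """Evaluate every predicted mask against the ground-truth mask of the
    same filename; returns per-image reports and their unweighted mean."""
    preds = {p.name: p for p in sorted(Path(pred_dir).glob("*.png"))}
    truths = {p.name: p for p in sorted(Path(truth_dir).glob("*.png"))}
    missing = sorted(set(preds) ^ set(truths))
    if not preds or missing:
        raise ValueError(f"unmatched mask files between directories: {missing}")
    reports: dict[str, EvalReport] = {}
    for name in sorted(preds):
        reports[name] = evaluate_masks(load_mask(preds[name]), load_mask(truths[name]))
    agg = mean_report(list(reports.values()))
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image", "C", "Pr", "TPR", "FS", "Sim", "FPR", "PWC"])
            for name, r in reports.items():
                writer.writerow([name, r.overlap, r.precision, r.tpr,
                                 r.fscore, r.sim, r.fpr, r.pwc])
            writer.writerow(["mean", agg.overlap, agg.precision, agg.tpr,
                             agg.fscore, agg.sim, agg.fpr, agg.pwc])
    return reports, agg
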
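"""Mask evaluation: PASCAL overlap and the six confusion-matrix criteria.

Given a predicted mask Omega' and a ground-truth mask Omega the overlap is
C = |Omega' ∩ Omega| / |Omega' ∪ Omega| (intersection over union).  The
remaining criteria derive from the pixel confusion counts: precision
Pr = tp/(tp+fp), true positive rate TPR = tp/(tp+fn), F-score
FS = 2*Pr*TPR/(Pr+TPR), similarity Sim = tp/(tp+fp+fn), false positive rate
FPR = fp/(fp+tn), and percentage of wrong classifications
PWC = 100*(fn+fp)/(tp+tn+fp+fn).  Any 0/0 ratio is defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .image_model import BinaryMask


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvalReport:
    """The seven per-image criteria; all in [0, 1] except PWC in [0, 100]."""

    overlap: float
    precision: float
    tpr: float
    fscore: float
    sim: float
    fpr: float
    pwc: float

    def as_dict(self) -> dict:
        return asdict(self)


def _values(mask: BinaryMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.values
    return np.asarray(mask, dtype=np.uint8)


def pascal_overlap(pred: BinaryMask | np.ndarray, truth: BinaryMask | np.ndarray) -> float:
    """Intersection over union; 1 if both masks are empty, 0 if exactly one is."""
    p, t = _values(pred).astype(bool), _values(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    union = np.logical_or(p, t).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, t).sum() / union)


def confusion(pred: BinaryMask | np.ndarray, truth: BinaryMask | np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts with the truth mask as reference."""
    p, t = _values(pred).astype(bool), _values(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return ConfusionCounts(
        tp=int(np.logical_and(p, t).sum()),
        fp=int(np.logical_and(p, ~t).sum()),
        fn=int(np.logical_and(~p, t).sum()),
        tn=int(np.logical_and(~p, ~t).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def criteria(c: ConfusionCounts, overlap: float | None = None) -> EvalReport:
    """The six confusion-derived criteria (plus the overlap if supplied).

    When ``overlap`` is omitted it is filled with Sim, to which the PASCAL
    overlap is identical when computed from the same mask pair (Jaccard).
    """
    if c.total <= 0:
        raise ValueError("confusion counts must cover at least one pixel")
    pr = _ratio(c.tp, c.tp + c.fp)
    tpr = _ratio(c.tp, c.tp + c.fn)
    fs = _ratio(2.0 * pr * tpr, pr + tpr)
    sim = _ratio(c.tp, c.tp + c.fp + c.fn)
    fpr = _ratio(c.fp, c.fp + c.tn)
    pwc = 100.0 * (c.fn + c.fp) / c.total
    return EvalReport(
        overlap=sim if overlap is None else overlap,
        precision=pr,
        tpr=tpr,
        fscore=fs,
        sim=sim,
        fpr=fpr,
        pwc=pwc,
    )


def evaluate_masks(pred: BinaryMask | np.ndarray, truth: BinaryMask | np.ndarray) -> EvalReport:
    """Full report for one predicted/ground-truth mask pair."""
    return criteria(confusion(pred, truth), overlap=pascal_overlap(pred, truth))


def mean_report(reports: list[EvalReport]) -> EvalReport:
    """Unweighted per-image mean of a batch of reports."""
    if not reports:
        raise ValueError("no reports to average")
    arr = np.array([[r.overlap, r.precision, r.tpr, r.fscore, r.sim, r.fpr, r.pwc]
                    for r in reports]).mean(axis=0)
    return EvalReport(*map(float, arr))
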
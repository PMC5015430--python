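"""OTB-style tracker evaluation: precision and success curves, AUC, and the
one-pass / temporal-robustness / spatial-robustness protocols.

Precision at threshold tau is the fraction of frames whose center location
error is strictly below tau pixels (trackers are conventionally ranked at
tau = 20).  Success at overlap threshold tau is the fraction of frames whose
intersection-over-union with the ground truth strictly exceeds tau; the AUC
is the mean success rate over the 21-point grid 0, 0.05, ..., 1.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .imaging import BoundingBox

__all__ = [
    "MetricCurve",
    "center_error",
    "iou",
    "precision_curve",
    "success_curve",
    "success_rate",
    "run_protocol",
]


@dataclass(frozen=True)
class MetricCurve:
    thresholds: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if t.shape != r.shape:
            raise ValueError("thresholds and rates must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if r.min() < 0 or r.max() > 1:
            raise ValueError("rates must lie in [0, 1]")
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "rates", r)


def center_error(a: BoundingBox, b: BoundingBox) -> float:
    """Euclidean distance between box centers, in pixels."""
    (ax, ay), (bx, by) = a.center, b.center
    return float(np.hypot(ax - bx, ay - by))


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two continuous rectangles, in [0, 1]."""
    ix = max(0.0, min(a.x + a.w, b.x + b.w) - max(a.x, b.x))
    iy = max(0.0, min(a.y + a.h, b.y + b.h) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    if union <= 0:
        return 0.0
    # rounding in the edge arithmetic can push the ratio epsilon past 1
    return min(1.0, inter / union)


def _check_lengths(traj, gt) -> None:
    if len(traj) != len(gt) or len(traj) == 0:
        raise ValueError(
            f"trajectory ({len(traj)}) and ground truth ({len(gt)}) must have "
            "equal nonzero length")


def precision_curve(traj, gt, thresholds=None) -> tuple[MetricCurve, float]:
    """Center-error precision curve; also returns the precision at 20 px."""
    _check_lengths(traj, gt)
    if thresholds is None:
        thresholds = np.arange(0.0, 51.0)
    errors = np.array([center_error(t, g) for t, g in zip(traj, gt)])
    rates = np.array([(errors < tau).mean() for tau in thresholds])
    at20 = float((errors < 20.0).mean())
    return MetricCurve(thresholds, rates), at20


def success_curve(traj, gt, thresholds=None) -> tuple[MetricCurve, float]:
    """Overlap success curve; also returns its AUC (mean rate over the grid)."""
    _check_lengths(traj, gt)
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 21)
    overlaps = np.array([iou(t, g) for t, g in zip(traj, gt)])
    rates = np.array([(overlaps > tau).mean() for tau in thresholds])
    return MetricCurve(np.asarray(thresholds, float), rates), float(rates.mean())


def success_rate(traj, gt, threshold: float = 0.5) -> float:
    """Fraction of frames with IoU strictly above ``threshold``."""
    _check_lengths(traj, gt)
    return float(np.mean([iou(t, g) > threshold for t, g in zip(traj, gt)]))


#: SRE perturbations: 8 compass shifts of 10% of the box size + 4 pure scalings
_SRE_SHIFTS = [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]
_SRE_SCALES = [0.8, 0.9, 1.1, 1.2]


def _perturbed_boxes(box: BoundingBox) -> list[BoundingBox]:
    out = []
    for dx, dy in _SRE_SHIFTS:
        out.append(BoundingBox(box.x + 0.1 * box.w * dx, box.y + 0.1 * box.h * dy,
                               box.w, box.h))
    cx, cy = box.center
    for s in _SRE_SCALES:
        out.append(BoundingBox(cx - s * box.w / 2, cy - s * box.h / 2,
                               s * box.w, s * box.h))
    return out


def run_protocol(tracker_factory, frames, gt, protocol: str = "OPE",
                 n_segments: int = 20, seed: int = 0) -> list[tuple[float, float]]:
    """Score a tracker under OPE, TRE, or SRE.

    ``tracker_factory(frames, init_box, seed)`` must return one box per
    frame.  OPE runs once from frame 0; TRE restarts from ``n_segments``
    evenly spaced frames, each initialized with the ground truth there; SRE
    runs 12 times from frame 0 with the initial box shifted by ±10% of its
    size in 8 directions or scaled by 0.8/0.9/1.1/1.2.  Returns one
    ``(precision_at_20, auc)`` pair per run.
    """
    frames = list(frames)
    gt = list(gt)
    if len(gt) != len(frames):
        raise ValueError("ground truth must cover every frame")
    results: list[tuple[float, float]] = []
    if protocol == "OPE":
        starts_and_boxes = [(0, gt[0])]
    elif protocol == "TRE":
        starts = np.unique(np.linspace(0, len(frames) - 1, n_segments).astype(int))
        starts_and_boxes = [(int(s), gt[s]) for s in starts]
    elif protocol == "SRE":
        starts_and_boxes = [(0, b) for b in _perturbed_boxes(gt[0])]
    else:
        raise ValueError(f"unknown protocol {protocol!r} (use OPE, TRE, or SRE)")
    for run_idx, (start, init_box) in enumerate(starts_and_boxes):
        seg_frames, seg_gt = frames[start:], gt[start:]
        if len(seg_frames) < 2:
            warnings.warn(f"segment starting at frame {start} is shorter than "
                          "2 frames; skipped")
            continue
        traj = tracker_factory(seg_frames, init_box, seed + run_idx)
        _, p20 = precision_curve(traj, seg_gt)
        _, auc = success_curve(traj, seg_gt)
        results.append((p20, auc))
    return results
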
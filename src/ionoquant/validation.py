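"""Evaluation of segmentations against generator ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quantify import cell_mean_intensities, tophat_bg_subtract
from .segmentation import SegmentationResult
from .synthetic import GroundTruth

__all__ = ["RecoveryMetrics", "detection_metrics", "intensity_recovery"]


@dataclass
class RecoveryMetrics:
    n_true: int
    n_pred: int
    n_matched: int
    centroid_errors: list[float]
    matches: dict[int, int]  # predicted label -> truth label

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_pred if self.n_pred else 0.0

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def detection_metrics(seg: SegmentationResult, truth: GroundTruth,
                      iou_threshold: float = 0.5) -> RecoveryMetrics:
    """Greedy IoU matching of predicted cells to true cells.

    The shared base label (if any) is not a detection target.  A predicted
    cell counts as matched when its best IoU against an unclaimed true cell
    reaches ``iou_threshold``; centroid errors are Euclidean distances in
    voxels for matched cells.
    """
    true_ids = list(range(1, truth.n_cells + 1))
    pred_ids = [t.label for t in seg.trajectories]
    pairs = []
    for p in pred_ids:
        pm = seg.labels == p
        for t in true_ids:
            tm = truth.instance_labels == t
            inter = np.sum(pm & tm)
            if inter == 0:
                continue
            iou = inter / np.sum(pm | tm)
            if iou >= iou_threshold:
                pairs.append((iou, p, t))
    pairs.sort(reverse=True)
    matches: dict[int, int] = {}
    used_true: set[int] = set()
    for _, p, t in pairs:
        if p in matches or t in used_true:
            continue
        matches[p] = t
        used_true.add(t)

    centroids = seg.centroids()
    errors = [float(np.linalg.norm(np.array(centroids[p])
                                   - np.array(truth.centroids[t])))
              for p, t in matches.items()]
    return RecoveryMetrics(n_true=len(true_ids), n_pred=len(pred_ids),
                           n_matched=len(matches), centroid_errors=errors,
                           matches=matches)


def intensity_recovery(seg: SegmentationResult, truth: GroundTruth,
                       channel: np.ndarray, channel_index: int,
                       metrics: RecoveryMetrics,
                       subtract: bool = True) -> list[float]:
    """Relative per-cell mean-intensity errors for matched cells.

    Measures the (optionally top-hat-subtracted) channel within each
    matched predicted label and compares to the generator's true noiseless
    mean for the corresponding cell.
    """
    data = tophat_bg_subtract(channel) if subtract else channel
    measured = {m.cell_id: m.mean_intensity["ch"]
                for m in cell_mean_intensities(seg, {"ch": data})}
    errors = []
    for p, t in metrics.matches.items():
        expected = truth.true_means[t][channel_index]
        errors.append(abs(measured[p] - expected) / expected)
    return errors
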
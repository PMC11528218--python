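"""Per-cell and per-ROI fluorescence measurement.

Three measurement routes, mirroring how reporter and HCR signals are
quantified in practice:

* 3D route — measurement channels are background-subtracted with a small
  white top-hat and the mean intensity inside each segmented cell label
  is taken;
* 2D ROI route — maximum-intensity projection, rolling-ball background
  subtraction, then the mean within a drawn region of interest;
* raw paired route — the brightest slice (or projection of up to the
  three brightest slices) is measured with **no** background subtraction,
  and the two cells of a pair from the same image are compared directly.

Display-only gamma adjustment has no code path here by design: nothing in
this module takes a gamma parameter, so measurement is always on raw or
explicitly-subtracted data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.restoration import rolling_ball

from .segmentation import SegmentationResult, white_tophat_3d

__all__ = [
    "CellMeasurement",
    "PairMeasurement",
    "tophat_bg_subtract",
    "cell_mean_intensities",
    "max_projection",
    "rolling_ball_subtract",
    "roi_mean",
    "brightest_substack_projection",
    "pair_asymmetry",
]


@dataclass
class CellMeasurement:
    cell_id: int
    mean_intensity: dict[str, float]  # channel name -> mean grey value
    n_voxels: int
    source: str = "label3d"  # label3d | roi2d


@dataclass
class PairMeasurement:
    """High/low comparison of two cells measured in the same image."""

    high_id: int
    low_id: int
    high_intensity: float
    low_intensity: float
    ratio: float
    tie: bool = False


def tophat_bg_subtract(channel: np.ndarray,
                       footprint_yxz: tuple[int, int, int] = (15, 15, 1)) -> np.ndarray:
    """White top-hat background subtraction for measurement channels.

    Same operator as the segmentation top-hat but with the smaller
    measurement footprint, default (15, 15, 1) in (y, x, z).
    """
    return white_tophat_3d(channel, footprint_yxz)


def cell_mean_intensities(seg: SegmentationResult,
                          channels: dict[str, np.ndarray],
                          required_labels=None) -> list[CellMeasurement]:
    """Mean intensity of each channel within each segmented cell.

    ``channels`` maps channel name to a (z, y, x) array matching the label
    volume; the caller decides whether these are raw or top-hat-subtracted.
    ``required_labels`` (optional) raises if any listed label has no voxels.
    """
    labels = seg.labels
    present = [t.label for t in seg.trajectories]
    if required_labels is not None:
        missing = [lab for lab in required_labels
                   if not (labels == lab).any()]
        if missing:
            raise ValueError(f"labels absent from volume: {missing}")
    out = []
    for lab in present:
        sel = labels == lab
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"label {lab} has no voxels in the volume")
        means = {}
        for name, ch in channels.items():
            if ch.shape != labels.shape:
                raise ValueError(f"channel {name!r} shape {ch.shape} does not "
                                 f"match labels {labels.shape}")
            means[name] = float(ch[sel].mean())
        out.append(CellMeasurement(cell_id=lab, mean_intensity=means, n_voxels=n))
    return out


def max_projection(stack: np.ndarray, axis: int = 0) -> np.ndarray:
    """Maximum-intensity projection along z (axis 0 of a z, y, x array)."""
    stack = np.asarray(stack)
    if stack.ndim < 3:
        return stack
    return stack.max(axis=axis)


def rolling_ball_subtract(image: np.ndarray, radius: float = 50.0) -> np.ndarray:
    """Rolling-ball background subtraction on a 2D image.

    The background is estimated by a grey-scale opening with a ball-shaped
    (spherical-cap) structuring element of the given radius and subtracted;
    the result is clipped at zero.  This is the standard Sternberg rolling
    ball, which can differ from interactive tools in minor boundary
    details.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if np.any(image < 0):
        raise ValueError("expected non-negative intensities")
    background = rolling_ball(image, radius=radius)
    return np.clip(image - background, 0, None)


def roi_mean(image: np.ndarray, roi_mask: np.ndarray) -> float:
    """Mean intensity within a boolean region of interest."""
    image = np.asarray(image)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != image.shape:
        raise ValueError("ROI mask shape must match image")
    if not roi_mask.any():
        raise ValueError("empty ROI")
    return float(image[roi_mask].mean())


def brightest_substack_projection(stack: np.ndarray, k: int = 1,
                                  roi_mask: np.ndarray | None = None) -> np.ndarray:
    """Maximum projection of the k brightest slices (k in 1..3).

    Slices are ranked by total intensity, within the ROI if one is given.
    The output feeds the raw paired comparison and is deliberately not
    background subtracted.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) stack")
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    if k > stack.shape[0]:
        raise ValueError(f"k={k} exceeds slice count {stack.shape[0]}")
    if roi_mask is not None:
        sums = np.array([sl[roi_mask].sum() for sl in stack])
    else:
        sums = stack.reshape(stack.shape[0], -1).sum(axis=1)
    # stable sort so equal-sum ties resolve to the lowest slice indices
    top = np.argsort(-sums, kind="stable")[:k]
    return stack[np.sort(top)].max(axis=0)


def pair_asymmetry(id_a: int, intensity_a: float,
                   id_b: int, intensity_b: float) -> PairMeasurement:
    """Pairwise high/low comparison of two cells from the same image.

    The brighter cell is labeled high and the ratio high/low reported.
    Exact ties are flagged and broken deterministically by cell id (the
    smaller id becomes high).  The lower intensity must be positive for
    the ratio to be defined.
    """
    if intensity_a <= 0 or intensity_b <= 0:
        low = min(intensity_a, intensity_b)
        raise ValueError(f"nonpositive intensity {low}: ratio undefined")
    if intensity_a == intensity_b:
        hi, lo = sorted([(id_a, intensity_a), (id_b, intensity_b)])
        return PairMeasurement(high_id=hi[0], low_id=lo[0],
                               high_intensity=hi[1], low_intensity=lo[1],
                               ratio=1.0, tie=True)
    if intensity_a > intensity_b:
        hi, lo = (id_a, intensity_a), (id_b, intensity_b)
    else:
        hi, lo = (id_b, intensity_b), (id_a, intensity_a)
    return PairMeasurement(high_id=hi[0], low_id=lo[0],
                           high_intensity=hi[1], low_intensity=lo[1],
                           ratio=hi[1] / lo[1])
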
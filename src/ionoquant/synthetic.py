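"""Synthetic confocal stacks and ionocyte count experiments with ground truth.

The generators emulate the two data modalities the pipeline consumes:

* anisotropic multichannel z-stacks containing bright nuclear ellipsoids
  (Notch-reporter-positive ionocytes) that may fuse into a shared basal
  support-cell structure at one end of the stack, over a smooth background
  gradient with Poisson shot noise and Gaussian read noise;
* long-format per-larva x per-neuromast count tables of mature and
  progenitor ionocyte units under conditions with multiplicative rate
  effects, drawn from a zero-inflated Poisson.

Every generator is a pure function of its spec and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import MultiChannelStack

__all__ = [
    "CellSpec",
    "BaseSpec",
    "StackSpec",
    "GroundTruth",
    "ExperimentDesign",
    "generate_stack",
    "generate_pair_stack",
    "generate_count_experiment",
]


@dataclass
class CellSpec:
    """One ellipsoidal nucleus.

    ``peak_intensity`` has one grey value per channel; a value of 0 leaves
    the cell dark in that channel.
    """

    center_zyx: tuple[float, float, float]
    radii_zyx: tuple[float, float, float]
    peak_intensity: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(r < 1 for r in self.radii_zyx):
            raise ValueError("cell radii must be >= 1 voxel")
        if any(p < 0 for p in self.peak_intensity):
            raise ValueError("peak intensities must be non-negative")


@dataclass
class BaseSpec:
    """Shared basal structure into which listed cells fuse.

    A flat slab spanning ``z_extent`` slices at one end of the stack (the
    highest z indices by default, matching acquisition from top of the
    organ downward), with an elliptical lateral footprint.
    """

    z_extent: int
    center_yx: tuple[float, float]
    radii_yx: tuple[float, float]
    intensity: tuple[float, ...]
    at_high_z: bool = True

    def __post_init__(self) -> None:
        if self.z_extent < 1:
            raise ValueError("base z_extent must be >= 1 slice")


@dataclass
class StackSpec:
    """Full description of a synthetic stack; see module docstring."""

    shape_zyx: tuple[int, int, int]
    cells: list[CellSpec]
    base_structure: Optional[BaseSpec] = None
    #: per-channel plane-gradient coefficients (offset, dz, dy, dx) in grey
    #: values (per voxel for the slopes)
    background: Optional[Sequence[tuple[float, float, float, float]]] = None
    poisson_scale: float = 0.0  # grey values per photon; 0 disables shot noise
    gaussian_sd: float = 0.0  # additive read noise sd, grey values
    bit_depth: int = 16

    @property
    def n_channels(self) -> int:
        return len(self.cells[0].peak_intensity) if self.cells else 1

    def validate(self) -> None:
        if any(s <= 0 for s in self.shape_zyx):
            raise ValueError("stack shape must be positive on all axes")
        ceiling = 2**self.bit_depth - 1
        for c in self.cells:
            if len(c.peak_intensity) != self.n_channels:
                raise ValueError("inconsistent channel count across cells")
            if any(p > ceiling for p in c.peak_intensity):
                raise ValueError(f"peak intensity exceeds bit depth ceiling {ceiling}")
        if self.poisson_scale < 0 or self.gaussian_sd < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class GroundTruth:
    """Noiseless instance geometry of a generated stack.

    ``instance_labels`` uses 0 for background, 1..n for the cells in spec
    order, and n+1 for the shared base if present.  ``merge_z`` is the
    first slice, in traversal order, at which at least two cells share a
    2D connected component (None without a base structure).
    """

    instance_labels: np.ndarray
    centroids: dict[int, tuple[float, float, float]]
    true_means: dict[int, np.ndarray]
    merge_z: Optional[int]

    @property
    def n_cells(self) -> int:
        base = 1 if self.merge_z is not None else 0
        return len(self.centroids) - base


def _ellipsoid_profile(shape: tuple[int, int, int],
                       center: Sequence[float],
                       radii: Sequence[float],
                       edge_sigma: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Flat-top ellipsoid with Gaussian edge falloff.

    Returns ``(profile, interior)`` where ``profile`` is 1 inside the
    ellipsoid and decays as exp(-d^2 / 2 sigma^2) outside, with d the
    exact grid Euclidean distance (voxels) to the ellipsoid surface, and
    ``interior`` is the boolean true-label mask.
    """
    from scipy import ndimage

    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    r = np.sqrt(((zz - center[0]) / radii[0]) ** 2
                + ((yy - center[1]) / radii[1]) ** 2
                + ((xx - center[2]) / radii[2]) ** 2)
    interior = r <= 1.0
    d = ndimage.distance_transform_edt(~interior)
    profile = np.where(interior, 1.0, np.exp(-(d**2) / (2 * edge_sigma**2)))
    # truncate far tails so disjoint cells contribute exactly zero to each other
    profile[d > 4 * edge_sigma] = 0.0
    return profile, interior


def _base_mask(spec: BaseSpec, shape: tuple[int, int, int]) -> np.ndarray:
    z0 = shape[0] - spec.z_extent if spec.at_high_z else 0
    z1 = z0 + spec.z_extent
    yy, xx = np.ogrid[: shape[1], : shape[2]]
    lateral = (((yy - spec.center_yx[0]) / spec.radii_yx[0]) ** 2
               + ((xx - spec.center_yx[1]) / spec.radii_yx[1]) ** 2) <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[z0:z1] = lateral
    return mask


def _merge_slice(cell_masks: list[np.ndarray], base: np.ndarray,
                 traverse_from_high_z: bool) -> Optional[int]:
    """First slice (traversal order) where >=2 cells touch one 2D component."""
    from scipy import ndimage

    union = base.copy()
    for m in cell_masks:
        union |= m
    nz = union.shape[0]
    order = range(nz - 1, -1, -1) if traverse_from_high_z else range(nz)
    for z in order:
        comp, n = ndimage.label(union[z], structure=np.ones((3, 3), int))
        for cid in range(1, n + 1):
            sel = comp == cid
            hit = sum(1 for m in cell_masks if (m[z] & sel).any())
            if hit >= 2:
                return z
    return None


def generate_stack(spec: StackSpec, seed: int) -> tuple[MultiChannelStack, GroundTruth]:
    """Render a stack from a :class:`StackSpec` and return it with truth.

    The noiseless image is the per-channel sum of ellipsoid profiles, the
    base slab and the background plane; shot noise rescales the image to
    photons, draws Poisson counts and scales back, after which Gaussian
    read noise is added and the result clipped to the bit-depth range.

    Raises ``ValueError`` if two cells overlap without a base structure
    joining them (the truth labels would be ambiguous).
    """
    spec.validate()
    shape = spec.shape_zyx
    nchan = spec.n_channels
    rng = np.random.default_rng(seed)

    cell_masks, profiles = [], []
    for c in spec.cells:
        prof, interior = _ellipsoid_profile(shape, c.center_zyx, c.radii_zyx)
        profiles.append(prof)
        cell_masks.append(interior)

    base = (_base_mask(spec.base_structure, shape)
            if spec.base_structure else np.zeros(shape, dtype=bool))

    for i in range(len(cell_masks)):
        for j in range(i + 1, len(cell_masks)):
            if (cell_masks[i] & cell_masks[j]).any():
                raise ValueError(
                    f"cells {i} and {j} overlap directly; only fusion through "
                    "a base_structure is representable in the truth labels")
    if spec.base_structure is not None:
        for i, m in enumerate(cell_masks):
            if not (m & base).any():
                raise ValueError(f"cell {i} does not overlap the base_structure")

    clean = np.zeros((nchan,) + shape, dtype=np.float64)
    for ch in range(nchan):
        for c, prof in zip(spec.cells, profiles):
            clean[ch] += c.peak_intensity[ch] * prof
        if spec.base_structure is not None:
            clean[ch][base] = np.maximum(clean[ch][base],
                                         spec.base_structure.intensity[ch])
        if spec.background is not None:
            off, dz, dy, dx = spec.background[ch]
            zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
            clean[ch] += off + dz * zz + dy * yy + dx * xx

    noisy = clean.copy()
    if spec.poisson_scale > 0:
        noisy = rng.poisson(noisy / spec.poisson_scale) * spec.poisson_scale
    if spec.gaussian_sd > 0:
        noisy = noisy + rng.normal(0, spec.gaussian_sd, noisy.shape)
    noisy = np.clip(noisy, 0, 2**spec.bit_depth - 1).astype(np.float32)

    labels = np.zeros(shape, dtype=np.uint16)
    for i, m in enumerate(cell_masks, start=1):
        labels[m] = i
    if spec.base_structure is not None:
        labels[base & (labels == 0)] = len(cell_masks) + 1

    centroids, true_means = {}, {}
    for lab in range(1, labels.max() + 1):
        sel = labels == lab
        zz, yy, xx = np.nonzero(sel)
        centroids[lab] = (float(zz.mean()), float(yy.mean()), float(xx.mean()))
        true_means[lab] = clean[:, sel].mean(axis=1)

    merge_z = None
    if spec.base_structure is not None:
        merge_z = _merge_slice(cell_masks, base,
                               traverse_from_high_z=not spec.base_structure.at_high_z)

    stack = MultiChannelStack(
        data=noisy,
        channel_names=[f"ch{i}" for i in range(nchan)],
        segmentation_channel=0,
    )
    return stack, GroundTruth(labels, centroids, true_means, merge_z)


def default_two_cell_spec(ratio: float,
                          peak: float = 2000.0,
                          poisson_scale: float = 0.0,
                          gaussian_sd: float = 0.0) -> StackSpec:
    """Two identical nuclei whose measurement-channel peaks differ by ``ratio``.

    Channel 0 carries the (equal) segmentation reporter; channel 1 is the
    measured signal. Because the two cells share identical geometry, their
    true per-cell means in channel 1 differ by exactly ``ratio``.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return StackSpec(
        shape_zyx=(12, 64, 64),
        cells=[
            CellSpec((6, 20, 32), (3, 6, 6), (peak, peak)),
            CellSpec((6, 44, 32), (3, 6, 6), (peak, peak * ratio)),
        ],
        poisson_scale=poisson_scale,
        gaussian_sd=gaussian_sd,
    )


def generate_pair_stack(ratio: float, seed: int,
                        poisson_scale: float = 0.0,
                        gaussian_sd: float = 0.0) -> tuple[MultiChannelStack, GroundTruth]:
    """Stack with a high/low expression pair at a known true intensity ratio."""
    spec = default_two_cell_spec(ratio, poisson_scale=poisson_scale,
                                 gaussian_sd=gaussian_sd)
    return generate_stack(spec, seed)


def merge_scene_spec(n_cells: int,
                     n_channels: int = 1,
                     shape_zyx: tuple[int, int, int] = (20, 128, 128),
                     peak: float = 2000.0,
                     base_intensity: float = 1500.0,
                     poisson_scale: float = 0.0,
                     gaussian_sd: float = 0.0,
                     measurement_peaks: Optional[Sequence[float]] = None) -> StackSpec:
    """Scene of ``n_cells`` nuclei fused into one basal support structure.

    The nuclei sit in a row near the bottom of the stack and dip into an
    elongated basal slab occupying the last five slices, reproducing the
    geometry in which plain 3D connected components return a single
    object.  ``measurement_peaks`` sets per-cell peak intensities for an
    optional second channel.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    cells = []
    for i in range(n_cells):
        peaks = [peak]
        if n_channels > 1:
            extra = (measurement_peaks[i] if measurement_peaks is not None
                     else peak * (0.5 + 0.25 * i))
            peaks += [extra] * (n_channels - 1)
        cells.append(CellSpec((11, 35 + 20 * i, 40 + 14 * (i % 2)),
                              (4, 7, 7), tuple(peaks)))
    cy = 35 + 20 * (n_cells - 1) / 2
    base_int = (base_intensity,) + (200.0,) * (n_channels - 1)
    return StackSpec(
        shape_zyx=shape_zyx,
        cells=cells,
        base_structure=BaseSpec(z_extent=5, center_yx=(cy, 47),
                                radii_yx=(25 + 11 * n_cells, 20),
                                intensity=base_int),
        poisson_scale=poisson_scale,
        gaussian_sd=gaussian_sd,
    )


def scatter_scene_spec(n_cells: int, seed: int,
                       shape_zyx: tuple[int, int, int] = (20, 128, 128),
                       n_channels: int = 2,
                       poisson_scale: float = 2.0,
                       gaussian_sd: float = 50.0) -> StackSpec:
    """Scene of well-separated nuclei with per-cell random peak intensities.

    Cells are rejection-sampled to keep lateral centers >= 26 voxels apart
    so no two masks touch; reporter peaks are drawn in 1500-2500 grey
    values and measurement peaks in 800-3000, giving peak SNR well above 5
    under the default noise.
    """
    rng = np.random.default_rng(seed)
    cells: list[CellSpec] = []
    centers: list[tuple[float, float, float]] = []
    while len(cells) < n_cells:
        c = (rng.uniform(6, shape_zyx[0] - 7),
             rng.uniform(15, shape_zyx[1] - 15),
             rng.uniform(15, shape_zyx[2] - 15))
        if all((c[1] - o[1]) ** 2 + (c[2] - o[2]) ** 2 > 26**2 for o in centers):
            centers.append(c)
            peaks = [rng.uniform(1500, 2500)]
            peaks += [rng.uniform(800, 3000) for _ in range(n_channels - 1)]
            cells.append(CellSpec(c, (4, 7, 7), tuple(peaks)))
    return StackSpec(shape_zyx=shape_zyx, cells=cells,
                     poisson_scale=poisson_scale, gaussian_sd=gaussian_sd)


def generate_pair_measurements(n_pairs: int, ratio: float, seed: int,
                               base_mean: float = 1000.0,
                               base_cv: float = 0.4,
                               noise_cv: float = 0.25) -> np.ndarray:
    """Simulated per-pair intensity measurements at a known true ratio.

    Each pair shares a lognormal baseline intensity (coefficient of
    variation ``base_cv`` across pairs, emulating staining and depth
    variation between images); the first cell's true mean is ``ratio``
    times the second's, and both are measured with independent lognormal
    noise of coefficient of variation ``noise_cv``.  Returns an
    (n_pairs, 2) array of (cell_a, cell_b) intensities.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    rng = np.random.default_rng(seed)
    s_base = np.sqrt(np.log1p(base_cv**2))
    s_noise = np.sqrt(np.log1p(noise_cv**2))
    base = base_mean * rng.lognormal(-s_base**2 / 2, s_base, n_pairs)
    a = base * ratio * rng.lognormal(-s_noise**2 / 2, s_noise, n_pairs)
    b = base * rng.lognormal(-s_noise**2 / 2, s_noise, n_pairs)
    return np.column_stack([a, b])


@dataclass
class ExperimentDesign:
    """Design of a simulated ionocyte count experiment.

    ``conditions`` maps condition name to a multiplicative effect on the
    baseline occupancy rates; the panel of 10 quantified neuromasts per
    larva matches the anterior + posterior lateral-line set scored in the
    study.  ``zero_inflation`` is the probability that a neuromast carries
    no unit regardless of rate, reflecting that most neuromasts host 0 or
    1 ionocyte pair.
    """

    conditions: list[tuple[str, float]] = field(
        default_factory=lambda: [("embryo_medium", 1.0), ("di_water", 2.0)])
    n_larvae: int = 18
    neuromasts_per_larva: int = 10
    baseline_rate: float = 0.5
    progenitor_rate: float = 0.3
    zero_inflation: float = 0.3
    n_replicates: int = 1
    dispersion: Optional[float] = None  # NB size parameter; None = Poisson
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_rate < 0 or self.progenitor_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.zero_inflation <= 1:
            raise ValueError("zero_inflation must lie in [0, 1]")
        if self.n_larvae < 1:
            raise ValueError("need at least one larva per condition")
        if any(m < 0 for _, m in self.conditions):
            raise ValueError("rate multipliers must be non-negative")


def _draw_counts(rng: np.random.Generator, rate: float, size: int,
                 zero_inflation: float, dispersion: Optional[float]) -> np.ndarray:
    if dispersion is None:
        counts = rng.poisson(rate, size)
    else:
        # negative binomial parameterized by mean and size (dispersion)
        p = dispersion / (dispersion + rate) if rate > 0 else 1.0
        counts = rng.negative_binomial(dispersion, p, size)
    counts[rng.random(size) < zero_inflation] = 0
    return counts


def generate_count_experiment(design: ExperimentDesign) -> pd.DataFrame:
    """Draw a long-format count table under a zero-inflated Poisson model.

    Columns: condition, replicate, larva_id, neuromast_id, mature_units,
    progenitor_units.  Reproducible under ``design.seed``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    rows = []
    for rep in range(design.n_replicates):
        for cond, mult in design.conditions:
            for larva in range(design.n_larvae):
                nm = design.neuromasts_per_larva
                mature = _draw_counts(rng, design.baseline_rate * mult, nm,
                                      design.zero_inflation, design.dispersion)
                prog = _draw_counts(rng, design.progenitor_rate * mult, nm,
                                    design.zero_inflation, design.dispersion)
                for j in range(nm):
                    rows.append((cond, rep, f"{cond}_r{rep}_l{larva}", f"nm{j}",
                                 int(mature[j]), int(prog[j])))
    return pd.DataFrame(rows, columns=["condition", "replicate", "larva_id",
                                       "neuromast_id", "mature_units",
                                       "progenitor_units"])
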
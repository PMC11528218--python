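# Methods

## Segmentation model

The segmentation targets bright nuclear reporters on a dark background
with one nuisance structure: a basal support-cell mass that shares the
reporter and touches every ionocyte near the bottom of the stack. The
pipeline is deliberately classical — no learned components — and runs in
five stages on the reporter channel:

1. **White top-hat** (grey opening residual, box structuring element,
   default 50×50×3 in (y, x, z)). Removes background structures larger
   than the footprint while passing nuclei (~15 px across). Even
   footprint extents are rounded up to odd so the element is centered;
   a footprint exceeding the stack shape on any axis is an error.
2. **Gaussian smoothing**, σ = (1, 1, 0.5) in (y, x, z), reflective
   boundaries. The smaller z sigma matches the ~3:1 z:xy anisotropy of
   typical confocal stacks.
3. **Fixed threshold** at grey value 500 on a 16-bit scale, inclusive
   (≥ 500 is foreground). Inclusivity is a convention choice; it is
   exposed through the threshold parameter rather than a separate flag.
4. **EDT erosion**: the Euclidean distance transform of the mask is
   computed on the voxel grid (anisotropy ignored, matching how such
   masks are processed in practice) and voxels with distance < 2 are
   dropped. The transform is 3D by default with a per-slice 2D option
   (`edt_per_slice`), since either reading of "the" distance transform
   is defensible. The operation is anti-extensive; idempotence is not
   claimed and not relied on.
5. **Z-tracking split.** Slices are traversed in order (first→last by
   default; `traverse_from="last_slice"` flips it — the fused base must
   lie at the *end* of traversal). Per slice, 2D components
   (8-connected by default) are linked to open trajectories by ≥ 1 voxel
   overlap with the trajectory's previous-slice component:
   * 0 overlapping trajectories → a new trajectory opens;
   * 1 → the component with the greatest overlap continues the
     trajectory; further components claiming the same trajectory open
     new ones (the split rule, symmetric counterpart of the merge rule);
   * ≥ 2 → a merge event: all participants are terminated at the
     previous slice and the fused component, plus everything it touches
     in later slices, stays label 0.

   A trajectory that runs into an *already fused* (unlabeled) blob is
   also terminated with status `terminated_at_merge`, but no new
   MergeEvent is recorded: events are reserved for ≥ 2 live
   participants, keeping the event record interpretable. Trajectories
   below `min_object_voxels` (default 20; set 0 to disable) are dropped
   as noise specks — this size filter is an extension beyond the core
   procedure. Surviving labels are renumbered 1..K by first slice, then
   centroid.

On merge-free masks this partition provably coincides with 26-connected
3D components as long as each component's slice-wise cross sections stay
singly connected (verified on random ellipsoid scenes); general
hourglass-shaped components can legitimately differ, which is the point
of the method.

## Measurement model

Measurement channels are background-subtracted with a smaller top-hat,
(15, 15, 1) in (y, x, z), and the arithmetic mean inside each 3D label
is reported with its voxel count. Two 2D routes exist for interactive
workflows: maximum projection → rolling-ball subtraction (Sternberg
opening with a spherical-cap element, radius 50 px; a dialect that can
differ from interactive tools at boundaries, so only tolerance-based
guarantees are made) → ROI mean; and a raw route that projects the k ∈
{1, 2, 3} brightest slices (ranked by summed intensity, inside the ROI
if given; default k = 1) with **no** background subtraction, feeding the
pairwise high/low comparison. Ties in a pair are flagged and broken by
cell id. By design no gamma parameter exists anywhere in the
measurement API: display adjustments cannot contaminate quantification.

## Counting and statistics

A cell is a *progenitor* iff foxi3a⁺, trpv6⁻, immediately adjacent to
the neuromast and crescent-shaped; it is *mature* iff foxi3a⁺ or
foxi3b⁺, trpv6⁺, and inside or invading. Units are formed by greedy
nearest-first pairing of cells within `pair_distance` (default 10 µm,
one cell diameter at the figures' scale); pairs and singletons each
count as one unit. Greedy pairing equals the exhaustive maximum
matching except on adversarial chains of near-equal distances, which
annotated data do not produce; an exhaustive oracle is kept in the test
suite. Per-larva averages are taken over the quantified 10-neuromast
panel (anterior Ml1, O2, Ml2, IO4, O1; posterior L1–L3, LII.1, LII.2),
frequency is the percentage of neuromasts with ≥ 1 unit, and
normalization divides each larva's value by its replicate's control
mean (error if a replicate lacks control larvae or has control mean 0).

Two-group comparisons are gated on normality: a Kolmogorov–Smirnov test
against a normal with sample-estimated parameters, per group, at 0.05.
This estimated-parameter KS is the Lilliefors situation and
under-rejects; it is the default for fidelity to common practice, and
`method="lilliefors"` provides the corrected gate. If both groups pass,
an unpaired two-tailed t-test is used, otherwise a two-tailed
Mann–Whitney *U* (exact when both n ≤ 8 and no ties, otherwise normal
approximation with tie correction). Paired designs go directly to the
Wilcoxon matched-pairs signed-rank test; an all-zero difference vector
is reported as degenerate with p = 1. Multi-group comparisons run
one-way ANOVA or Kruskal–Wallis as omnibus, then Dunnett's many-to-one
test versus the control (default for control-anchored designs) or
Dunn's all-pairs rank test with tie correction and Holm (default) or
Bonferroni adjustment. s.e.m. is sd/√n. Calibration of the full
adaptive procedure (gate + selection) is verified by simulation: its
type-I error stays within [0.03, 0.07] at nominal 0.05 under both
normal and lognormal nulls.

## Synthetic data

`generate_stack` renders each nucleus as a flat-top ellipsoid (interior
exactly at peak intensity) with a Gaussian edge falloff of σ = 1 voxel
in *exact Euclidean distance* from the ellipsoid surface, truncated at
4 voxels so separated cells are numerically independent; an optional
basal slab (elliptical footprint over the last `z_extent` slices,
highest z by default, matching top→bottom acquisition) is combined by
voxelwise maximum, and per-channel plane gradients add background.
Noise is Poisson on photons (grey values divided by `poisson_scale`)
plus additive Gaussian read noise, clipped to the bit-depth ceiling
(default 16-bit — acquisition metadata are not part of the assay, so
bit depth and the 3:1 anisotropy convention are configuration, not
claims). Ground truth carries instance labels (cells in spec order,
then the base), centroids, noiseless per-channel means, and the first
traversal slice at which two cells share a 2D component (`merge_z`).
Cells may only overlap through a declared base; direct cell-cell
overlap is rejected because truth labels would be ambiguous.

Default conditions ("realistic noise"): `poisson_scale` 2 grey
values/photon and read noise σ 20–50 grey values against nuclear peaks
of 1500–2500, i.e. peak SNR ≈ 10–40, typical of spinning-disk HCR
imaging. The default reporter peak (2000) sits at 4× the fixed
threshold, which is the regime the EDT erosion presupposes: the
thresholded mask extends ~2 voxels beyond the nuclear surface and the
erosion returns it to the surface. Much brighter peaks inflate masks
beyond what the fixed 2-voxel erosion removes — a real limitation of
fixed-threshold segmentation, not of the generator.

`generate_count_experiment` draws mature and progenitor unit counts per
larva × neuromast from a zero-inflated Poisson (zero inflation 0.3,
baseline rates 0.5 mature / 0.3 progenitor units, 18 larvae and 10
neuromasts per larva, multiplicative condition effects), reflecting
that most neuromasts host 0 or 1 unit; a negative-binomial option
(`dispersion`) is available. `generate_pair_measurements` simulates the
45-pair asymmetry design at measurement level: a shared lognormal
baseline per pair (CV 0.4 across images) and independent lognormal
measurement noise (CV 0.25) around a true ratio.

What the generators do **not** model: PSF convolution, spectral
bleed-through, motion, depth-dependent attenuation, nucleus shape
irregularity, or spatial correlation between neighboring neuromasts.
Passing tests therefore demonstrate algorithmic correctness under the
stated geometry and noise, not robustness to optical artifacts.

## Problem sizes and numerics

Simulation sizes used by the test suite and acceptance script: 20
recovery stacks of 128×128 px × 20 slices with 2–6 cells; 100 random
merge-free masks (≤ 64×64×16) for the tracking/3D-components
equivalence; 50 random masks (≤ 32³) for the EDT contract against a
nearest-background search; 2000-replicate null simulations for each
calibration check and 200-replicate power checks — chosen to put
Monte-Carlo standard errors (~0.5 percentage points on a 5% rate) well
inside the asserted bands. Brightest-slice ranking uses a stable sort
(ties go to lower slice indices). Label volumes are uint16 (error
beyond 65535 cells). All generators and the pipeline are pure functions
of (config, seed); the CLI and `run_pipeline` stamp artifacts with a
config hash so reproducibility is checkable byte-for-byte.

## Known limitations

* Trajectory linking uses overlap only; cells perfectly stacked in z
  with no intervening background would be fused (not observed in this
  geometry, where nuclei are laterally separated).
* The fixed grey-value threshold ties segmentation quality to
  acquisition brightness, as discussed above.
* Voxels after a merge event are never measured; cells deeply embedded
  in the basal structure lose their bottom slices, slightly biasing
  centroids toward the tracked end (≤ ~0.8 voxel in the bundled
  scenes).
* Neuromast-within-larva correlation is handled by per-larva averaging,
  not mixed-effects modeling, mirroring the assay's convention.
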
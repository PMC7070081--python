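# Methods

This note documents the models, conventions and numerical choices behind
biofilm4d, in the order the pipeline runs them.

## Data model and conventions

A time lapse is an ordered list of frames; each frame holds one 3D 8-bit
stack per channel (reflection, bacteria, optional second organism, EPS).
Arrays are indexed `[z, y, x]` with **Z index 0 at the top of the stack**
(the slice nearest the objective), matching a top-to-bottom confocal scan;
stacks acquired bottom-up are flipped on ingest via the `z_orientation`
flag.  Coordinates are 0-based with half-open ranges throughout.

Physical calibration (`dx`, `dy` µm/px, `dz` µm/slice, frame interval in
minutes) always comes from an explicit sidecar manifest, never from TIFF
resolution tags: plain TIFF metadata is unreliable and silently wrong tags
would corrupt every volume downstream.  Defaults mirror a typical 40×
water-immersion CLSM acquisition: `dz = 0.42` µm, 20-min frames, and a
lateral pitch of 0.624 µm/px (a ~319.5-µm field at 512 px).  The lateral
pitch is the one quantity a user should always set from their own
acquisition, since field sizes alone do not determine it.

## Preprocessing

Fluorescence stacks are smoothed with an isotropic 3D Gaussian of
**variance 0.8 in squared pixels** (σ ≈ 0.894 px, the common denoising
setting for this kind of data).  The variance is interpreted in index
space; users with strongly anisotropic voxels can pass per-axis sigmas by
calling `scipy` directly, but the isotropic default is deliberate — the
filter's job is shot-noise suppression, not PSF modeling.  Reflect padding
keeps the DC gain exactly 1, so constant stacks are fixed points and no
spurious intensity gradient is introduced at borders.

Binarization is Otsu's method per stack by default.  High-contrast
staining makes the histogram strongly bimodal, so any histogram-valley
method lands in the same valley; Otsu is chosen because it is
deterministic and parameter-free.  The foreground is strictly above the
Otsu threshold (the scikit-image convention); a user-supplied fixed
threshold is inclusive (≥).  A constant-valued stack under the automatic
method is flagged degenerate and returned all-background rather than
raising, so a blank frame does not abort a run.  **For clean synthetic
scenes the recommended settings are `gaussian_variance: 0` and
`threshold: 128`** — there is no noise to remove, and skipping the filter
keeps segmentation geometry voxel-exact (blur at half-maximum bridges
sub-voxel gaps between nearly touching blobs, which would shift merge
detection by a frame).

## Topography

The heightmap scan walks each (x, y) column from the top of the stack
down and records the first voxel whose intensity reaches the contrast
threshold (default: the reflection stack's Otsu threshold).  A hit at Z
index k in an N-slice stack gives **elevation h = (N − 1 − k)·dz above
the deepest detectable plane**; reporting elevation rather than
distance-from-top makes positive skewness mean hill-dominated terrain.
Columns with no hit are masked undefined and excluded from every
statistic; no interpolation is performed over them.

Sa, Sq, Ssk are discrete sums over defined columns.  Ssk is undefined
(None) when Sq = 0; this is a flag, not a zero.  MAS tiling is
non-overlapping, anchored at the map origin, with partial edge tiles
dropped — a partition, so tile statistics are independent.  Window areas
are given in µm² and converted to the nearest integer pixel side.  A
colonized "site" is the axis-aligned bounding rectangle of the element's
Z-projected footprint.  Occupancy histograms are density-normalized
(integral 1) on bin edges shared between the colonized-site and MAS
tables so the two densities are directly comparable.

## Segmentation and morphometrics

Connected components are labeled at **26-connectivity by default**
(corner-touching cell chains are biologically contiguous); 6 and 18 are
available.  Element ids are assigned in lexicographic order of each
component's minimum (z, y, x) voxel, making labeling deterministic and
reproducible across runs.

Components touching a lateral (XY) image boundary are removed before
measurement: their volume and hull are corrupted by clipping.  Components
touching the top or bottom Z plane are kept — biofilms legitimately fill
the imaged depth.

Biovolume is voxel count × dx·dy·dz.  The convex hull is computed (via
Qhull) on **boundary-voxel centers** — voxels whose 6-neighborhood is not
fully foreground — in physical units.  The center convention means a
solid a×b×c-voxel cuboid yields hull volume (a−1)(b−1)(c−1) voxel
volumes, and the solidity ratio `qhull/volume` of a digitized convex body
approaches 1 from below as resolution grows (measured: 0.913 at r = 8 px,
0.962 at r = 16 px for a digitized ball).  Degenerate elements (coplanar
or < 4 boundary points) get a flagged, undefined hull rather than a fake
value.  The ratio is reported hull-over-volume, so branched morphologies
score high (> 4) and compact ones near 1–2.

Cell counts are `max(1, round_half_up(V / 0.35 µm³))`; 0.35 µm³ is the
reference single-cell biovolume of *S. mutans*.  Class bins: single cell
1–5, cluster 6–50, aggregate 51–300, microcolony > 300 (the lower bound
of the single-cell bin is inclusive at 1).  Beyond the cluster level the
volume–cell-count relation is not linear (EPS contributes volume), so
counts above ~300 are nominal and volume is the growth variable.

## Tracking

Linking is maximal voxel overlap between consecutive frames: with 20-min
frames and surface-attached growth, consecutive masks of the same
colonizer overlap heavily, so overlap linking is near-exact without
motion models.  Ties are broken by nearest centroid, then lower track id.
Unmatched new elements start new tracks (late attachers).  A track
unmatched for up to `max_gap` frames (default 0) may recapture a
reappearing element; detachment is declared when the trailing absence
lasts at least `persistence` frames (default 1) and the track was not
absorbed by a merge.  Re-attachment after a declared detachment starts a
new track.

SC/DC classification uses the strict rule **V(t*) > 5·V(0)** with t* the
first observed frame at or after 420 min (the nearest available frame
when sampling differs); a track that detaches or merges before t* is
"unfit".  V(0) is the first frame of that track — the pre-flow baseline
for initial colonizers, the attachment frame for late settlers.

## Growth fitting

Both model variants are available and reported explicitly:
`offset_power` V(t) = V0 + a·tᵇ (default) and `pure_power` V(t) = a·tᵇ
(appropriate when V(t) ≫ V(0)).  Fitting is bounded nonlinear least
squares on the untransformed model (a, b ≥ 0, b ≤ 10), initialized from a
log–log linear regression of the positive above-baseline volumes — "a"
spans many decades, and the log–log start makes convergence robust where
a naive start stalls.  Standard errors come from the fit covariance.
Series with total excursion below 5 % of V(0) are flagged static (the
power law is unidentifiable on them); fits with sd(b) > 1 or R² < 0.5 are
tallied "unfit" and excluded from population summaries (both thresholds
config-exposed).  Quantiles use the linear-interpolation rule throughout
so medians/quartiles are reproducible to the last digit.

Growth rates are central finite differences (one-sided at the ends),
exact for linear series; optional moving-average smoothing is off by
default.

## Merging

A merge exists at the first frame where one element overlaps ≥ 2
previous-frame tracks — any overlap counts, since even one shared voxel
means the labeler fused the components.  The merged mass is partitioned
among parents by contact planes: the perpendicular bisector plane of each
parent-pair's centroids, which for any number of parents is exactly a
nearest-centroid (Voronoi) assignment.  Parent centroids are **frozen at
the last pre-merge frame** so the partition does not drift as the merged
mass grows asymmetrically.  Voxels exactly on a plane go to the lower
track id — an arbitrary but deterministic tie-break that guarantees exact
voxel conservation (the partitions sum to the merged volume at every
frame, to machine precision).  Coincident parent centroids are an error,
not a silent fallback.  The surviving (child) track is also a parent:
its own pre-merge centroid takes part in the partition, so the central
element's share is tracked alongside the marginal ones.  Growth-rate
continuity across a merge is reported descriptively (mean rate
after/before per parent); no hypothesis test is attached.

## Synthetic scenes

The generator emulates: a rough substratum as a Gaussian random field
smoothed at a chosen correlation length (default 10 µm) and rescaled so
its Sa equals the target *exactly* (default 1.0 µm, within the 0.2–7 µm
range typical of apatitic substrata), rendered as a reflection stack
solid below the quantized surface; colonizers seeded on the surface with
chosen P0, grown by deterministic dilation-to-target-volume (voxels
claimed in anisotropic-distance order from the seed, restricted to the
space above the local substratum), so rendered volumes track the
scheduled V(t) = V0 + a·tᵇ within one voxel and growth is a nested,
connected dilation; scripted detachments (absence from a given time) and
merges (close seeding of two growers); and a noise model of Gaussian
blur, background offset, additive Gaussian and optional Poisson noise,
clipped to 8 bits.  Ground truth includes the continuous heightmap, all
scheduled and rendered volumes, detachment times, and pair contact frames
computed from the rendered masks (26-connectivity), independent of the
analysis path.

What the generator does **not** emulate: realistic optics (a true PSF,
depth-dependent attenuation, refractive-index mismatch), EPS-channel
signal, fluid-shear mechanics, colonizer motility, or cell-scale texture
inside blobs.  Passing tests on these scenes therefore demonstrates the
correctness of the measurement chain (topography, labeling, volumetry,
tracking, fitting, partitioning), not robustness to every optical
artifact of real acquisitions.

The mid-depth default base elevation keeps the scaled random field clear
of both clip planes, preserving the exact target Sa.

## Problem sizes

Tests and the acceptance script use fields of 64–256 px laterally,
20–40 slices, and up to 22 frames (0–420 min at 20-min cadence) — large
enough that every behavior (multi-scale tiling, merge geometry, 420-min
classification) is exercised at full fidelity, while a complete run of
suite plus acceptance script stays under a minute on one core.  The
benchmark scene (`example_scene`) is 176 × 144 px × 30 slices × 22
frames with 20 colonizers.  The generator accepts full acquisition-scale
scenes (512² × 100+ slices) unchanged.

## Known limitations

- Overlap linking assumes negligible inter-frame drift; there is no
  registration step, matching chambers imaged on a fixed stage.
- The topography scan takes the *first* contrast hit per column; debris
  above the substratum would be read as surface.  Use the denoising
  filter and a conservative contrast threshold on real reflection data.
- Volume-based cell counts above the cluster level are nominal.
- Merge partitioning is geometric (Voronoi); it conserves volume exactly
  but does not model mechanical deformation at the contact interface.
- The pipeline is single-channel for quantification; a second organism
  channel is carried through the data model but analyzed by re-running
  the pipeline on that channel.
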
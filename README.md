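# biofilm4d

Multiscale spatiotemporal population analysis of biofilm surface colonizers
from 4D confocal laser-scanning microscopy (CLSM) data.

## The problem

Early biofilm development starts with individual microbial colonizers — single
cells, chains, clusters and small aggregates — settling on a substratum and,
for a subset of them, growing into densely packed microcolonies that
eventually merge into submillimeter superstructures.  Following *every*
colonizer on a surface through that process requires linking four kinds of
analysis over a time-lapse of 3D image stacks:

1. **Substratum topography** — a reflection stack is scanned top-to-bottom per
   (x, y) column to recover the elevation field h(x, y), from which areal
   roughness parameters are computed over any evaluated area S:

   - average roughness `Sa = (1/S) Σ |h − h̄|`
   - RMS roughness `Sq = [(1/S) Σ (h − h̄)²]^½`
   - skewness `Ssk = (1/Sq³)(1/S) Σ (h − h̄)³`

   evaluated globally, per square tile at many window scales (multiscale area
   selection, MAS — a roughness census of every candidate binding site), and
   per colonized site (the rectangular footprint beneath each colonizer).
2. **Segmentation and morphometrics** — fluorescence stacks are denoised with
   a 3D Gaussian filter (variance 0.8 px²), binarized (Otsu or fixed
   threshold), and 3D-labeled into connected components.  Each component
   carries its biovolume (voxel count × voxel volume), an estimated cell count
   P = V / 0.35 µm³, a class (single cell 1–5, cluster 6–50, aggregate 51–300,
   microcolony > 300 cells), and the solidity ratio
   `R = qhull_volume / volume` (convex-hull volume over biovolume; ≈ 1 for
   compact communities, large for branched morphologies).
3. **Tracking and growth laws** — components are linked across frames by
   maximal voxel overlap into per-colonizer tracks; detachment is the terminal
   disappearance of a track.  Dynamic colonizers (DC) satisfy the strict rule
   V(420 min) > 5·V(0) and follow the growth law

   `V(t) = V(0) + a·tᵇ`   (t in minutes, V in µm³),

   which reduces to the pure power law `V(t) = a·tᵇ` when V(t) ≫ V(0); static
   colonizers (SC) keep V(t) ≈ V(0).  Fits are nonlinear least squares with
   log–log initialization; the population is summarized by medians and
   quartiles of (a, b), overall and per initial-size class.
4. **Merging** — when neighboring communities grow into contact, the merged
   mass is partitioned back to its parents by a centroid contact-plane rule
   (perpendicular bisector planes of parent-centroid pairs ⇔ nearest-centroid
   assignment, with centroids frozen pre-merge), so each parent's V(t) and
   growth rate can be followed through the merge with exact voxel
   conservation.

A fully ground-truthed **synthetic scene generator** (rough substrata,
scripted static/power-law/detaching/merging colonizers, PSF-like blur and
noise) makes every stage testable without microscope data.

## Worked example

Run the full pipeline on the bundled 20-colonizer benchmark scene
(6 power-law growers, 12 static colonizers of which 3 detach, one scripted
merge pair, on a rough substratum with Sa = 0.5 µm):

```python
import tempfile
from biofilm4d import generate_scene, run_pipeline
from biofilm4d.synthetic import example_scene

tl, truth = generate_scene(example_scene(seed=11))
res = run_pipeline({"timelapse": tl,
                    "params": {"gaussian_variance": 0, "threshold": 128.0}},
                   tempfile.mkdtemp(), seed=1)
print(res["summary"])
```

which prints (abridged):

```
global roughness: {'Sa': 0.489, 'Sq': 0.611, 'Ssk': -0.237, 'n_columns': 25344}
tracks: 20  detached: 3  merges: 1
usable fits: 8  median a: 1.75e-05  median b: 2.576
dynamics: {'SC': 9, 'DC': 7, 'unfit': 4}
```

Reading: the measured substratum roughness matches the generator's 0.5-µm
target; all 20 scripted colonizers are recovered as tracks; the 3 scripted
detachments and the single merge event are found; the 8 usable growth fits
(6 growers + the merge pair) have median exponent b ≈ 2.58, matching the
scripted range b = 2.40–2.65; SC counts the static survivors plus slow
growers, unfit the detached/absorbed tracks that end before the 420-min
reference.  Clean synthetic scenes are analyzed with the denoising filter off
and a fixed half-maximum threshold; for noisy data use the defaults
(`gaussian_variance: 0.8`, `threshold: otsu`).

The same run is available from the shell:

```
biofilm4d simulate --scene scene.yaml --out scene/
biofilm4d all --config run.yaml --out results/ --seed 1
```

writing `elements.csv`, `tracks.csv`, `events.csv`, `growth_fits.csv`,
`mas_roughness.csv`, `merge_partitions.csv`, `coverage.csv`,
`heightmap.tif`, `summary.json` and figure panels under `results/`.

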
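# golgi3d

3D reconstruction and morphometry of Golgi-impregnated spindle-shaped
neurons: brightfield z-stack segmentation of dendritic shafts and
spines, rule-based spine classification, SWC cylinder-model
morphometry, and a synthetic Golgi-phantom generator that makes every
stage testable against exact ground truth.

## The problem

Spindle-shaped neurons — elongated fusiform cell bodies with one
ascending and one descending primary dendrite leaving opposite somatic
poles — are candidate von Economo neurons, described in deep cortical
layer V. Characterizing them from Golgi-impregnated *postmortem* tissue
means working with brightfield z-stacks (dark silver-filled structure on
a bright, speckled background; 0.5 μm z-steps for whole neurons, 0.1 μm
for spine segments), reconstructing dendrites and spines in 3D,
classifying each spine's shape, and reducing the traced morphology to a
handful of per-cell numbers. No public image data exists for this
preparation, so the package ships a phantom generator that emulates the
acquisition — tubular dark dendrites with spiny protrusions, anisotropic
PSF blur, silver-precipitate speckle, uneven illumination, sensor noise —
with the true geometry, voxel mask and spine table retained for scoring.

It is aimed at quantitative neuroanatomists and image-analysis
developers who need a reproducible, fully specified version of this
processing chain.

## What it computes

**Spine reconstruction** (stages a–f on an 8-bit stack):
outlier removal (local-median robust-z replacement) → unsharp masking +
edge-aware recursive domain-transform smoothing → per-slice adaptive
(local mean − offset) thresholding → pruning of small detached
components → per-slice flood fill of enclosed background → cubic
z-upsampling of the binary field. Output is a `BinaryVolume` with full
stage provenance.

**Spine classification**: the shaft centreline is the longest path of
the 3D skeleton with radii from the Euclidean distance transform;
protrusions beyond the local shaft radius become spine candidates; the
width profile along the geodesic from the attachment gives neck diameter
(proximal minimum), head diameter (distal maximum), protrusion length,
and the count of distinct distal compartments. A first-match rule table
assigns thin / stubby / wide / mushroom-like / ramified / transitional /
atypical, with spinules (tiny, ≤0.4 μm × ≤0.2 μm protrusions off a
head) flagged separately, and linear spine density in spines/μm with a
sparse / moderate / high band.

**Morphometry** on SWC reconstructions (trees of connected tapering
cylinders): cell-body length L, maximum diameter D and prolate-ellipsoid
volume (4/3)·π·(L/2)·(D/2)²; primary-shaft diameters; total number of
branches (unbranched segments delimited by primary origins, branching
points and tips); total dendritic length Σ‖xᵢ−xⱼ‖ and total volume as
the frustum sum Σ π·h·(r₁² + r₁r₂ + r₂²)/3 per edge; and a geometric
spindle-phenotype qualifier (exactly two substantial primaries from
opposite poles, both within 30° of the declared vertical axis, soma
elongation L/D ≥ 1.6).

## Worked example

```python
import golgi3d as g
from golgi3d.reconstruction import BinaryVolume

# 60 ground-truth spines at 0.8/μm on 75 μm of dendrite, rendered at
# 0.1 μm isotropic voxels into a 128x128x151 brightfield stack
truth, stack = g.standard_spine_fixture()          # noiseless variant
vol, summary = g.reconstruct_spines(stack)          # stages (a)-(f)
analysis = BinaryVolume(vol.mask[::3], stack.spacing)  # original z-grid
records, axis = g.classify_volume(analysis)
density = g.spine_density(records, axis.length)
print(len(records), round(density["density_per_um"], 2), density["band"])
```

prints

```
60 0.78 moderate
```

— all 60 phantom spines are recovered and the density estimate (0.78/μm
over the 76.8 μm extracted centreline) lands within 3% of the generator
setting of 0.8/μm, in the "moderate" band. On the same fixture the
reconstructed mask reaches Jaccard 1.000 against the exact geometry
mask, detection precision 1.00, and mean per-class classification
accuracy 0.94; the SNR-10 variant (PSF blur, speckle, illumination ramp,
Gaussian noise) retains detection recall 0.85.

Morphometry of a generated spindle cell:

```python
cell = g.generate_spindle_swc(g.SpindleParams(soma_length=37, soma_diameter=19))
print(g.soma_metrics(cell))      # (37.0, 19.0, 6993.7)  μm, μm, μm³
print(g.classify_spindle(cell)[0])  # True
```

The analysis scripts `analysis/01_simulate_phantoms.py` …
`04_morphometry.py` run the same chain as a narrative study, writing
tables under `results/` (bulky TIFF stacks go to `scratch/`).

A `golgi3d` command-line tool wraps the same functions
(`simulate`, `reconstruct`, `classify`, `morpho`, `run-all`,
`validate-swc`); every stochastic command requires an explicit `--seed`
and writes a manifest with config, seeds and output hashes so that runs
are bit-reproducible.

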
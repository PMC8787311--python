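# Methods

This note documents the models, conventions and parameter choices behind
golgi3d: what each stage assumes, which numbers are free design choices,
and what the synthetic phantoms do and do not establish about real data.

## Coordinate and image conventions

Stacks are `[z][y][x]` with the origin at the first slice's top-left;
the physical coordinate of voxel (i, j, k) is (k·dx, j·dy, i·dz),
voxel-centre convention. Grids may be anisotropic (dz ≠ dx); the
spine-imaging default is 0.1 μm isotropic and the neuron-imaging z-step
is 0.5 μm. Voxel grids use `floor(extent/step)+1` samples per axis, so a
15 μm z-extent at dz = 0.1 μm gives 151 slices. 8-bit conversion maps
16-bit input by a full-range linear map and RGB by ITU-R 601 luminance
weights (0.299, 0.587, 0.114). The 2D composite of a brightfield stack
is the per-pixel **minimum** across depth by default: impregnated
structure is dark on a bright ground, so the darkest value at each pixel
keeps in-focus structure from any plane; literal summation is available
(`sum-clipped`) but saturates, and `mean` washes out thin branches.

## Phantom generator

The generator is the package's study-condition definition, not a test
utility.

**Morphology.** A spindle cell is a three-point soma (type-1 nodes: two
pole nodes at ±L/2 on the vertical axis and a centre node of radius
D/2; defaults L = 37 μm, D = 19 μm, matching the elongated somata this
phenotype shows) with one ascending and one descending primary dendrite
leaving the poles within 10° of vertical, tapering from 1.2 μm to
0.25 μm radius over a 260 μm total vertical extent. Collateral branching
follows a profile — `straight` (none), `sparse` (0.02/μm), `profuse`
(0.06/μm) — spanning the observed continuum from straight sparsely
ramified shafts to profuse radial collaterals. Soma length is recovered
by `soma_metrics` as the positional extent of the soma nodes along their
principal axis, max diameter as twice the largest soma radius, volume by
the prolate-ellipsoid model; a single-node soma degenerates correctly to
a sphere.

**Spines.** Spines are placed along dendritic arclength by a homogeneous
Poisson process, a Neyman–Scott cluster process (parents plus offspring
in a ±0.5 μm window; `grouping=0` degenerates to Poisson, and the parent
intensity is thinned so the mean density is conserved), or an exact
count with a guaranteed minimum gap (sampled in gap-reduced coordinates,
which stays uniform — naive rejection jams near 75% packing). Class-
conditional geometry ranges realize the taxonomy's qualitative
contrasts, since the classes are defined visually, not numerically:

| class | neck ∅ (μm) | head ∅ | neck length | shape |
|---|---|---|---|---|
| thin | 0.20–0.30 | 1.25–1.40 × neck | 0.9–1.4 | slender, head ≈ neck |
| stubby | — | base 0.45–0.60 | ~0 | height 0.8–1.0 × base |
| wide | — | base 0.80–1.10 | ~0 | height 0.55–0.65 × base |
| mushroom | 0.18–0.26 | 2.4–3.0 × neck | 0.45–0.70 | bulbous head |
| ramified | 0.20–0.26 | 0.40–0.52 | 0.45–0.65 | two heads, one stalk |

Stubby/wide bumps are rendered as flat-based constant-radius capsules
rooted just below the shaft surface — a tangent sphere would create a
spurious constriction that reads as a neck. Ramified heads sit at ±50°
from the stalk at 1.6 head-radii, far enough apart that the two distal
compartments are geometrically distinct (the property that defines the
class). Spinules (0.30 μm × 0.14 μm capsules off a head) decorate a
configurable fraction (default 15%) of mushroom/ramified spines. A
serial double-bulb variant (neck–bulb–neck–bulb) implements the
"atypical" geometry.

**Rendering.** Geometry (soma spheres, dendrite frusta as capsules with
linearly interpolated radius, spine primitives) is voxelized by an exact
centre-in-primitive test; the same mask is stored as ground truth, so
with zero optics the rendered stack thresholded at the fg/bg midpoint
equals the truth mask exactly. Optics and artifacts are applied in
order: punctate dark speckle (two-voxel grains, emulating nonspecific
silver precipitate), anisotropic Gaussian PSF (σ_z = 2 σ_xy by default,
mimicking brightfield axial elongation), multiplicative left–right
illumination ramp, additive Gaussian noise, 8-bit quantization. All
stages are deterministic given the seed.

**Standard fixture.** Criterion-level evaluations use one published
condition: seed 20220111, a helical dendritic segment (radius 4 μm,
~2.9 turns, 75 μm arclength, shaft radius 0.45 μm) carrying exactly 60
spines at 0.8/μm (minimum gap 0.95 μm, equal mix of the five crisp
classes), rendered at 0.1 μm isotropic voxels into 128×128×151. The
helix is how 75 μm of dendrite fits a spine-scale field of view while
remaining a single dominant elongated structure; its turn spacing
(≈4 μm) exceeds any spine's extent, and spine azimuths are constrained
to |z-component| ≤ 0.5 so no geometry clips the shallow z-range. The
noiseless variant has no optics at all; the SNR-10 variant uses
σ_xy = 0.08 μm, σ_z = 0.16 μm, speckle 0.2/1000 voxels, 10% illumination
ramp, and noise σ = 15 DN (contrast 150 DN ⇒ contrast-to-noise 10).

## Reconstruction stages

All parameters live in `PipelineConfig`; none of them is physically
forced, and the defaults are scaled to the 0.1 μm spine-imaging grid.

- **(a) outlier removal** (window 3, k = 4): replaces voxels deviating
  more than k robust SDs (1.4826·MAD) from their local median. The
  robust scale is floored at 0.15 (normalized): to a 3³ window a sub-μm
  neck *is* an impulse, so without the floor this stage erases exactly
  the structure the pipeline exists to recover. With the floor it
  removes only extreme hot/dead voxels; speckle grains are left to stage
  (d), which can tell "small and detached" from "small and attached".
  An optional 3D median prefilter (`median_subvolume=3`) is the
  denoising profile for noisy stacks; it is off by default because a 3³
  median also erases 1–2-voxel necks, and on noisy data the PSF has
  already widened them enough to survive.
- **(b) edge enhancement**: unsharp masking
  (`out = clip(in + 0.6·(in − G_0.2μm(in)))`) followed by an edge-aware
  pass — a recursive domain-transform filter (σ_s = 0.5 μm,
  σ_r = 0.1, 3 iterations of horizontal+vertical first-order recursive
  passes with the standard per-iteration σ schedule), which smooths
  near-constant regions while halting at intensity discontinuities.
  There is no installed implementation of this filter, so it is written
  here (~40 lines). The order unsharp→edge-aware is a config switch.
- **(c) adaptive binarization** (block 31 px, offset 5/255): per-slice
  local mean minus offset, strict inequality, edge-replicated borders;
  dark-foreground polarity by default, and
  `binarize(invert(x), bright) == binarize(x, dark)` exactly. Constant
  regions yield background. The block must be large relative to the
  structure (31 px ≈ 3 μm vs ≈1 μm dendrite width) or the structure's
  own interior raises the local mean enough to hollow it.
- **(d) pruning** (min 30 voxels, attach radius 0.5 μm): 26-connected
  components survive if large *or* within the attach radius of the
  largest component (measured in μm via the EDT), so detached spine
  heads survive while speckle is removed. Output ⊆ input.
- **(e) per-slice flood fill**: background not 4-connected to the slice
  border becomes foreground (`binary_fill_holes` per slice). Output ⊇
  input; idempotent.
- **(f) z-interpolation** (factor 3): the 0/1 field is interpolated
  along z with a cubic spline whose knots are the original slices —
  sample positions are reproduced exactly — and rethresholded at 0.5;
  dz divides by the factor. Below 4 slices it falls back to linear with
  a warning. Note that 0.5-thresholded interpolation and nearest-
  neighbour duplication give nearly identical *volumes* (both place
  transition boundaries mid-gap up to phase); the stage's real effect is
  smoother transition surfaces, which shows up as higher overlap with
  the analytic geometry on slanted structures (0.93 vs 0.88 Jaccard on
  the slanted-cylinder test).
- **(g)** is non-interactive export (mask TIFF + JSON report).

Connectivity is 26 in 3D for components and 4 in 2D for flood-fill
background, everywhere.

## Spine measurement and classification

The shaft centreline is the longest path through the 3D skeleton of the
largest component (double-sweep BFS — exact on trees, tight when
thinning leaves small cycles), smoothed with a 5-point moving average
because the raw voxel staircase inflates arclength by ~10% (enough to
push a density estimate out of band); radii come from the EDT. The
elongation gate is *path length / max thickness* ≥ 2 rather than a PCA
anisotropy ratio, because a curved or helical shaft is nearly isotropic
as a point cloud while being perfectly shaft-like.

Segmentation takes foreground farther than local radius + 0.15 μm from
the axis, keeps 26-components within 0.3 μm of the shaft envelope (the
gap tolerance recovers heads whose 2-voxel necks eroded during
binarization), drops candidates with radial extent < 0.2 μm (noise
floor) or with fewer than 3 voxels, and excludes attachments within
0.7 μm of the axis ends, where the rounded shaft cap otherwise reads as
a protrusion. A candidate touching the shaft over > 1.2 μm of arclength
is flagged `contact_ambiguous` (possible merged spines) rather than
split.

Measurement uses geodesic distance from the whole attachment base
(multi-source Dijkstra with physical edge weights), so length is height
above the shaft surface, not a corner-to-tip diagonal. The width at
geodesic distance d is the *equivalent circular diameter of the level
slab's cross-sectional area* (2·√(A/π) with A = voxel count × voxel
volume / slab thickness): area counting resolves widths well below one
voxel, where the inscribed-ball (EDT) width quantizes — at 0.1 μm voxels
it cannot separate a 0.20 μm neck from a 0.28 μm head, which is exactly
the thin-spine contrast. The neck is the proximal-half minimum of the
profile, the head the distal maximum (taken from the unsmoothed profile;
median smoothing erodes few-bin head peaks), and a neck exists when
head/neck ≥ 1.2. For squat neckless bumps geodesic level sets are shells
rather than planar cross-sections, so the neckless decision instead uses
direct geometry: radial height above the shaft surface and lateral
extent orthogonal to the radial direction. Distal compartments are the
26-components of the level set at 70% of the protrusion length:
components wider than 0.2 μm are heads (ramified when ≥ 2), thinner ones
spinules. Serial swellings are counted from dips (≥25%) in the distal
profile. Head sphericity is π^⅓(6V)^⅔/A with the surface area from
marching cubes.

Classification is a pure function of the feature vector and an editable
rule table, first-match priority: **ramified** (≥2 protrusions) →
**mushroom** (neck ∧ head/neck ≥ 1.5) → **thin** (neck ∧ length/neck-∅ ≥ 3
∧ head/neck < 1.5) → neckless **wide** (lateral/height ≥ 1.4) /
**stubby** (height/lateral ≤ 1.2) → **transitional** (a deciding ratio
within ±5% of its boundary) → **atypical** (residual; also any serial
multi-bulb). All ratios are dimensionless; the absolute spinule caps
(0.4/0.2 μm) multiply by a scale field so uniformly rescaled data keeps
its labels. The 1.2 / 1.5 / 3 ratios follow the quantitative spine
literature's head-to-neck contrasts; "wide" is not a standard class and
is operationalized as laterally dominant without a neck. Density bands:
sparse ≤ 0.3/μm < moderate ≤ 1.0/μm < high (declared bins, not
measured facts).

## Morphometry

Branch counting is fixed to "unbranched segments between topological
points": each primary origin opens one segment and a k-way branch point
closes one and opens k (a Y-shaped primary counts 3). Edges with a soma-
node parent carry no dendritic length or volume; the soma is reported
separately and excluded from the dendritic totals. Primary departure
directions are soma centroid → 5th node (or tip), making the angle
criteria deterministic. The vertical (pial) axis is supplied in config —
SWC carries no anatomical frame. Qualifier thresholds: primary diameter
≥ 0.6× the thickest, pole angle ≥ 150°, vertical deviation ≤ 30°,
elongation ≥ 1.6.

## What the phantoms do and do not show

Phantom recovery (Jaccard 1.0 noiseless, recall 0.85 at SNR 10, mean
class accuracy 0.94) demonstrates internal consistency: the pipeline
inverts its own forward model at realistic geometry, sampling and
contrast. Real Golgi material differs in ways the generator does not
emulate: incomplete impregnation, out-of-plane structures from *other*
cells, a vendor deconvolution step during acquisition that is not
modelled (the phantom uses a plain Gaussian PSF), refractive-index
mismatch and depth-dependent blur, and tissue shrinkage that biases all
absolute lengths. Class accuracy on real data is further limited by the
visual, partly subjective character of the taxonomy itself.

Known limitations: exact 90°-rotation label invariance holds for
well-separated class geometries but borderline thin-class spines can
flip (3D thinning is not lattice-symmetric, and thin sits between two
rule boundaries by construction); serial double-bulb spines with a weak
inner dip classify as mushroom; spinules merged into a head's level-set
component are missed, so the spinule flag under-counts; and the
measured shaft length carries a few percent digitization bias that the
5-point smoothing reduces but does not eliminate.

## Problem sizes

Default evaluations use the 128×128×151 fixture (~2.5M voxels), chosen
as the natural size of a spine-segment acquisition (12.8 × 12.8 ×
15 μm at 0.1 μm); the full chain runs in well under a minute per
variant on one CPU. Statistical checks use ≥500 generated spines on a
600 μm segment; morphometry oracles use 50 random trees of ≤300 nodes.
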
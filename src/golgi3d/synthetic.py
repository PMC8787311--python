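"""Synthetic Golgi-phantom generator with ground truth.

Everything downstream (reconstruction, spine classification, morphometry)
is exercised against phantoms produced here: spindle-neuron morphologies
built as SWC trees, dendritic segments decorated with ground-truth spines
drawn from class-conditional geometry ranges, and brightfield-like
renders — dark tubular structure on a bright ground, anisotropic Gaussian
PSF, punctate dark speckle (the "unspecific silver precipitate" of a real
Golgi background), a multiplicative illumination ramp, and additive
Gaussian noise, quantized to 8 bits.

Every operation is deterministic for a fixed seed.  The ground truth
(:class:`PhantomTruth`) carries the morphology, the spine table with
attachment coordinates and class labels, and — once rendered — the exact
voxel mask, so recovery can be scored without any manual annotation.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .image_io import ImageStack, VoxelSpacing
from .morphometry import DENDRITE, SOMA, NeuronMorphology, SWCNode
from .reconstruction import BinaryVolume

__all__ = [
    "SpindleParams",
    "SpineSpec",
    "PhantomTruth",
    "SPINE_CLASSES",
    "generate_spindle_swc",
    "generate_pyramidal_like",
    "helix_segment",
    "straight_segment",
    "decorate_with_spines",
    "voxelize_truth",
    "render_stack",
    "standard_spine_fixture",
]

SPINE_CLASSES = ("thin", "stubby", "wide", "mushroom", "ramified", "transitional", "atypical")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpindleParams:
    """Parameters of a spindle-neuron phantom.

    The spindle phenotype is an elongated soma (major axis > max minor
    diameter) with two primary dendrites leaving opposite poles close to
    the vertical axis.  ``branch_profile`` spans the observed continuum
    from a straight course with rare branches to profuse radial
    collaterals.
    """

    soma_length: float = 37.0        # μm, major axis
    soma_diameter: float = 19.0      # μm, max minor diameter
    n_primary: int = 2
    primary_angle_spread: float = 10.0   # deg from vertical
    branch_profile: Literal["straight", "sparse", "profuse"] = "sparse"
    collateral_angle_range: tuple[float, float] = (40.0, 80.0)  # deg
    total_extent: float = 260.0      # μm, pole-to-pole including soma
    primary_radius: float = 1.2      # μm at the shaft base
    tip_radius: float = 0.25         # μm
    node_spacing: float = 2.0        # μm between SWC samples
    seed: int = 0

    def __post_init__(self) -> None:
        if self.soma_length <= self.soma_diameter:
            raise ValueError("spindle phenotype requires soma_length > soma_diameter")
        if self.n_primary < 1:
            raise ValueError("n_primary must be >= 1")
        if self.total_extent <= self.soma_length:
            raise ValueError("total_extent must exceed soma_length")


@dataclass
class SpineSpec:
    """One ground-truth spine: class label, geometry, and placement."""

    class_label: str
    neck_length: float       # μm; ~0 for stubby/wide
    neck_diameter: float     # μm
    head_diameter: float     # μm
    n_heads: int = 1
    has_spinule: bool = False
    spinule_length: float = 0.0
    position_arclen: float = 0.0   # μm along the decorated dendrite
    azimuth: float = 0.0           # deg around the local tangent
    attachment: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    length: float = 0.0            # μm, attachment (shaft surface) to tip
    primitives: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.class_label not in SPINE_CLASSES:
            raise ValueError(f"unknown spine class {self.class_label!r}")
        if self.class_label == "ramified" and self.n_heads < 2:
            raise ValueError("ramified spines need n_heads >= 2")
        if self.has_spinule and self.spinule_length >= self.head_diameter:
            raise ValueError("spinule_length must be smaller than head_diameter")


@dataclass
class PhantomTruth:
    """Generator ground truth: morphology, spine table, and (after
    rendering) the exact voxel mask."""

    morphology: NeuronMorphology
    spines: list[SpineSpec]
    density_per_um: float
    decorated_length: float
    mask: BinaryVolume | None = None


# ---------------------------------------------------------------------------
# morphology generators
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _tilted(axis: np.ndarray, tilt_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector at ``tilt_deg`` from ``axis`` toward azimuth ``azimuth_deg``."""
    axis = _unit(axis)
    # orthonormal frame around axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 0.0, 1.0])
    e1 = _unit(np.cross(axis, helper))
    e2 = np.cross(axis, e1)
    t, a = math.radians(tilt_deg), math.radians(azimuth_deg)
    return math.cos(t) * axis + math.sin(t) * (math.cos(a) * e1 + math.sin(a) * e2)


_BRANCH_RATES = {"straight": 0.0, "sparse": 0.020, "profuse": 0.060}  # per μm


def generate_spindle_swc(params: SpindleParams) -> NeuronMorphology:
    """Build a spindle-neuron SWC tree.

    Three-point soma (type 1): centre node with radius = soma_diameter/2
    and two pole nodes at +/- soma_length/2 on the vertical (+y) axis.
    One ascending and one descending primary dendrite emerge at the poles
    within ``primary_angle_spread`` of vertical, taper linearly, and carry
    collateral branches according to ``branch_profile``.  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    L, D = params.soma_length, params.soma_diameter
    nodes: list[SWCNode] = [
        SWCNode(1, SOMA, 0.0, 0.0, 0.0, D / 2.0, -1),
        SWCNode(2, SOMA, 0.0, +L / 2.0, 0.0, D / 6.0, 1),
        SWCNode(3, SOMA, 0.0, -L / 2.0, 0.0, D / 6.0, 1),
    ]
    next_id = 4
    shaft_len = (params.total_extent - L) / 2.0
    branch_rate = _BRANCH_RATES[params.branch_profile]

    def grow(start: np.ndarray, direction: np.ndarray, length: float,
             r0: float, r1: float, parent: int, allow_collaterals: bool) -> None:
        nonlocal next_id
        n_seg = max(2, int(round(length / params.node_spacing)))
        step = length / n_seg
        pos = start.copy()
        d = direction.copy()
        for i in range(1, n_seg + 1):
            # gentle meander, renormalized to keep overall course
            if i > 1:
                d = _unit(d + rng.normal(0.0, 0.03, size=3))
            pos = pos + step * d
            r = r0 + (r1 - r0) * (i / n_seg)
            nodes.append(SWCNode(next_id, DENDRITE, *pos, r, parent))
            parent = next_id
            next_id += 1
            if (
                allow_collaterals
                and branch_rate > 0
                and 0.15 * length < i * step < 0.9 * length
                and rng.random() < branch_rate * step
            ):
                lo, hi = params.collateral_angle_range
                cdir = _tilted(d, rng.uniform(lo, hi), rng.uniform(0, 360))
                clen = rng.uniform(8.0, 22.0)
                grow(pos, cdir, clen, min(0.45, r), 0.15, parent, False)

    for sign, pole_id in ((+1.0, 2), (-1.0, 3)):
        tilt = rng.uniform(0.0, params.primary_angle_spread)
        d = _tilted(np.array([0.0, sign, 0.0]), tilt, rng.uniform(0, 360))
        start = np.array([0.0, sign * L / 2.0, 0.0])
        grow(start, d, shaft_len, params.primary_radius, params.tip_radius, pole_id, True)

    m = NeuronMorphology(nodes)
    if params.n_primary != 2:
        raise ValueError("spindle phenotype generator only emits 2 primaries")
    return m


def generate_pyramidal_like(seed: int = 0, soma_diameter: float = 20.0,
                            n_basal: int = 5) -> NeuronMorphology:
    """Pyramidal-like control morphology: roundish soma, one thick apical
    dendrite plus ``n_basal`` basal dendrites fanning downward/lateral."""
    rng = np.random.default_rng(seed)
    r = soma_diameter / 2.0
    nodes = [SWCNode(1, SOMA, 0.0, 0.0, 0.0, r, -1),
             SWCNode(2, SOMA, 0.0, +r, 0.0, r, 1),
             SWCNode(3, SOMA, 0.0, -r, 0.0, r, 1)]
    next_id = 4

    def grow(direction, length, r0, parent):
        nonlocal next_id
        pos = np.array([0.0, 0.0, 0.0]) + direction * r
        n_seg = max(2, int(length / 3.0))
        for i in range(1, n_seg + 1):
            p = pos + direction * (length * i / n_seg)
            rad = r0 + (0.2 - r0) * (i / n_seg)
            nodes.append(SWCNode(next_id, DENDRITE, *p, rad, parent))
            parent = next_id
            next_id += 1

    grow(np.array([0.0, 1.0, 0.0]), 120.0, 1.5, 2)  # apical
    for i in range(n_basal):
        az = 360.0 * i / n_basal + rng.uniform(-10, 10)
        d = _tilted(np.array([0.0, -1.0, 0.0]), rng.uniform(35, 70), az)
        grow(d, 60.0, 1.0, 3)
    return NeuronMorphology(nodes)


def straight_segment(length: float = 10.0, radius: float = 0.5,
                     start: Sequence[float] = (0.0, 0.0, 0.0),
                     direction: Sequence[float] = (1.0, 0.0, 0.0),
                     node_spacing: float = 1.0) -> NeuronMorphology:
    """A bare straight dendritic segment (no soma), for cylinder phantoms."""
    start = np.asarray(start, dtype=float)
    d = _unit(np.asarray(direction, dtype=float))
    n = max(1, int(round(length / node_spacing)))
    nodes = [SWCNode(1, DENDRITE, *start, radius, -1)]
    for i in range(1, n + 1):
        p = start + d * (length * i / n)
        nodes.append(SWCNode(i + 1, DENDRITE, *p, radius, i))
    return NeuronMorphology(nodes)


def helix_segment(length: float = 75.0, helix_radius: float = 4.0,
                  shaft_radius: float = 0.45,
                  center: Sequence[float] = (6.35, 6.35),
                  z_range: Sequence[float] = (1.5, 13.5),
                  node_spacing: float = 0.5) -> NeuronMorphology:
    """A helical dendritic segment: long arclength in a compact volume.

    Used for the standard spine fixture, where tens of micrometres of
    decorated dendrite must fit a spine-scale field of view; successive
    turns are separated by several micrometres so the shaft remains the
    single dominant elongated component.
    """
    cx, cy = center
    z0, z1 = z_range
    dz_total = z1 - z0
    circ = math.sqrt(max(length ** 2 - dz_total ** 2, 0.0))
    n_turns = circ / (2.0 * math.pi * helix_radius)
    n = max(2, int(round(length / node_spacing)))
    nodes = []
    for i in range(n + 1):
        t = i / n
        ang = 2.0 * math.pi * n_turns * t
        x = cx + helix_radius * math.cos(ang)
        y = cy + helix_radius * math.sin(ang)
        z = z0 + dz_total * t
        nodes.append(SWCNode(i + 1, DENDRITE, x, y, z, shaft_radius, i if i else -1))
    return NeuronMorphology(nodes)


# ---------------------------------------------------------------------------
# spine decoration
# ---------------------------------------------------------------------------

#: Class-conditional geometry ranges (μm).  The taxonomy gives qualitative
#: contrasts, not numbers; these defaults realize them crisply: stubby and
#: wide are neckless (stubby roughly isometric, wide laterally dominant),
#: thin has a long thin neck with a barely wider head, mushroom a bulbous
#: head at least twice its neck, ramified two heads on one stalk.
CLASS_GEOMETRY: dict[str, dict] = {
    "thin": {"neck_d": (0.20, 0.30), "head_ratio": (1.25, 1.40), "neck_len": (0.9, 1.4)},
    "stubby": {"base_d": (0.45, 0.60), "aspect": (0.80, 1.00)},
    "wide": {"base_d": (0.80, 1.10), "aspect": (0.55, 0.65)},
    "mushroom": {"neck_d": (0.18, 0.26), "head_ratio": (2.4, 3.0), "neck_len": (0.45, 0.70)},
    "ramified": {"neck_d": (0.20, 0.26), "head_d": (0.40, 0.52), "neck_len": (0.45, 0.65)},
    "transitional": {"neck_d": (0.20, 0.26), "head_ratio": (1.45, 1.55), "neck_len": (0.5, 0.7)},
    "atypical": {"neck_d": (0.18, 0.24), "head_d": (0.35, 0.45), "neck_len": (0.35, 0.5)},
}

SPINULE_LENGTH = 0.30   # μm
SPINULE_DIAMETER = 0.14  # μm


def _arclength_table(m: NeuronMorphology) -> tuple[list, float]:
    """Ordered dendritic edges as (cum_len, p0, p1, r0, r1); total length."""
    edges = []
    cum = 0.0
    for n in m.nodes:
        if n.parent == -1 or n.structure != DENDRITE:
            continue
        p = m.node(n.parent)
        if p.structure != DENDRITE:
            continue
        h = float(np.linalg.norm(n.pos - p.pos))
        if h == 0:
            continue
        edges.append((cum, h, p.pos, n.pos, p.radius, n.radius))
        cum += h
    return edges, cum


def _point_at_arclen(edges, s: float):
    """(point, tangent, radius) at arclength s along the edge table."""
    for cum, h, p0, p1, r0, r1 in edges:
        if s <= cum + h or (cum, h, p0, p1, r0, r1) is edges[-1]:
            t = np.clip((s - cum) / h, 0.0, 1.0)
            point = p0 + t * (p1 - p0)
            tangent = _unit(p1 - p0)
            radius = r0 + t * (r1 - r0)
            return point, tangent, radius
    raise ValueError(f"arclength {s} beyond dendrite")


def _spine_primitives(spec: SpineSpec, surface: np.ndarray, u: np.ndarray,
                      rng: np.random.Generator) -> tuple[list, float]:
    """Build capsule/sphere primitives for one spine; returns (prims, length)."""
    prims: list = []
    cls = spec.class_label
    if cls in ("stubby", "wide"):
        # neckless bump: constant-radius capsule rooted below the shaft
        # surface, so no spurious constriction forms at the junction
        b = spec.head_diameter  # base diameter doubles as the only width
        L = spec.length
        r = b / 2.0
        prims.append(("capsule", surface - u * 0.1, surface + u * max(L - r, 0.02), r, r))
        return prims, L
    # necked classes: capsule neck + head sphere(s)
    neck_top = surface + u * spec.neck_length
    prims.append(("capsule", surface, neck_top, spec.neck_diameter / 2.0,
                  spec.neck_diameter / 2.0))
    hr = spec.head_diameter / 2.0
    if cls == "ramified":
        # two heads branching from the shared stalk; separated enough that
        # the distal compartments are geometrically distinct
        w = _unit(np.cross(u, rng.normal(size=3)))
        ang = math.radians(50.0)
        for sgn in (+1.0, -1.0):
            hd = _unit(math.cos(ang) * u + sgn * math.sin(ang) * w)
            c = neck_top + hd * (1.6 * hr)
            prims.append(("capsule", neck_top, c, spec.neck_diameter / 2.0, hr * 0.7))
            prims.append(("sphere", c, hr))
        length = spec.neck_length + math.cos(ang) * 1.6 * hr + hr
    elif cls == "atypical":
        # serial double bulb: neck, bulb, second neck, second bulb
        c1 = neck_top + u * hr
        prims.append(("sphere", c1, hr))
        neck2_top = c1 + u * (hr + 0.25)
        prims.append(("capsule", c1, neck2_top, spec.neck_diameter / 2.0,
                      spec.neck_diameter / 2.0))
        c2 = neck2_top + u * hr
        prims.append(("sphere", c2, hr))
        length = float(np.linalg.norm(c2 + u * hr - surface))
    else:
        c = neck_top + u * hr
        prims.append(("sphere", c, hr))
        length = spec.neck_length + 2.0 * hr
    if spec.has_spinule:
        head_centre = prims[-1][1]
        sd = _unit(_tilted(u, rng.uniform(30, 70), rng.uniform(0, 360)))
        tip = head_centre + sd * (hr + spec.spinule_length)
        prims.append(("capsule", head_centre + sd * hr * 0.8, tip,
                      SPINULE_DIAMETER / 2.0, SPINULE_DIAMETER / 2.0))
    return prims, length


def _draw_spec(cls: str, rng: np.random.Generator, spinule_fraction: float) -> SpineSpec:
    g = CLASS_GEOMETRY[cls]
    if cls in ("stubby", "wide"):
        base = rng.uniform(*g["base_d"])
        aspect = rng.uniform(*g["aspect"])
        return SpineSpec(cls, neck_length=0.0, neck_diameter=base,
                         head_diameter=base, length=base * aspect)
    neck_d = rng.uniform(*g["neck_d"])
    if "head_ratio" in g:
        head_d = neck_d * rng.uniform(*g["head_ratio"])
    else:
        head_d = rng.uniform(*g["head_d"])
    neck_len = rng.uniform(*g["neck_len"])
    n_heads = 2 if cls == "ramified" else 1
    has_spinule = cls in ("mushroom", "ramified") and rng.random() < spinule_fraction
    return SpineSpec(cls, neck_length=neck_len, neck_diameter=neck_d,
                     head_diameter=head_d, n_heads=n_heads,
                     has_spinule=has_spinule,
                     spinule_length=SPINULE_LENGTH if has_spinule else 0.0)


def _sample_positions(rng: np.random.Generator, total: float, density: float,
                      grouping: float, n_spines: int | None,
                      min_separation: float) -> np.ndarray:
    if n_spines is not None:
        # exact uniform placement with a guaranteed minimum gap: sample in
        # the gap-reduced interval, sort, then re-expand by the gaps
        slack = total - (n_spines - 1) * min_separation
        if slack <= 0:
            raise ValueError("could not place requested spine count with separation")
        u = np.sort(rng.uniform(0.0, slack, size=n_spines))
        return u + min_separation * np.arange(n_spines)
    if grouping <= 0:
        n = rng.poisson(density * total)
        pos = np.sort(rng.uniform(0.0, total, size=n))
    else:
        # Neyman–Scott: parents thinned so the total intensity stays `density`
        mean_cluster = 1.0 + 2.0 * grouping
        n_par = rng.poisson(density * total / mean_cluster)
        parents = rng.uniform(0.0, total, size=n_par)
        pos = []
        for p in parents:
            k = 1 + rng.poisson(2.0 * grouping)
            pos.extend(np.clip(p + rng.uniform(-0.5, 0.5, size=k), 0.0, total))
        pos = np.sort(np.asarray(pos, dtype=float))
    if min_separation > 0 and len(pos) > 1:
        keep = [pos[0]]
        for s in pos[1:]:
            if s - keep[-1] >= min_separation:
                keep.append(s)
        pos = np.asarray(keep)
    return pos


def decorate_with_spines(
    morphology: NeuronMorphology,
    density_per_um: float,
    class_mix: dict[str, float],
    grouping: float = 0.0,
    seed: int = 0,
    n_spines: int | None = None,
    min_separation: float = 0.0,
    spinule_fraction: float = 0.15,
    max_axial_component: float = 1.0,
    positions: Sequence[float] | None = None,
    class_sequence: Sequence[str] | None = None,
    spec_sequence: Sequence[SpineSpec] | None = None,
) -> PhantomTruth:
    """Place ground-truth spines along the dendritic arclength.

    Placement is a homogeneous Poisson process (``grouping=0``) or a
    Neyman–Scott clustered process (parents plus offspring within a
    +/-0.5 μm window) realizing "isolated or grouped" spines; ``n_spines``
    forces an exact count instead of a Poisson draw.  Each spine's class
    comes from ``class_mix`` and its geometry from the class-conditional
    ranges in :data:`CLASS_GEOMETRY`.  ``max_axial_component`` bounds
    |z-component| of the spine direction (rejection-sampled), keeping
    fixture spines inside shallow fields of view.
    """
    if density_per_um < 0:
        raise ValueError("density must be >= 0")
    labels = list(class_mix)
    probs = np.array([class_mix[c] for c in labels], dtype=float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix must be nonnegative and sum to 1")
    for c in labels:
        if c not in SPINE_CLASSES:
            raise ValueError(f"unknown class in mix: {c!r}")

    rng = np.random.default_rng(seed)
    edges, total = _arclength_table(morphology)
    if not edges:
        raise ValueError("morphology has no dendritic edges to decorate")
    if density_per_um == 0 and n_spines is None and positions is None:
        return PhantomTruth(morphology, [], 0.0, total)

    if positions is None:
        positions = _sample_positions(rng, total, density_per_um, grouping,
                                      n_spines, min_separation)
    else:
        positions = np.asarray(positions, dtype=float)
    spines: list[SpineSpec] = []
    for k, s in enumerate(positions):
        if spec_sequence is not None:
            spec = copy.deepcopy(spec_sequence[k % len(spec_sequence)])
        else:
            if class_sequence is not None:
                cls = class_sequence[k % len(class_sequence)]
            else:
                cls = labels[int(rng.choice(len(labels), p=probs))]
            spec = _draw_spec(cls, rng, spinule_fraction)
        point, tangent, shaft_r = _point_at_arclen(edges, float(s))
        for _ in range(64):
            az = rng.uniform(0.0, 360.0)
            u = _tilted(tangent, 90.0, az)
            if abs(u[2]) <= max_axial_component:
                break
        else:
            # constraint unsatisfiable by rejection: project the axial
            # component out and renormalize
            u = np.array([u[0], u[1], 0.0])
            if np.linalg.norm(u) < 1e-9:
                u = np.array([1.0, 0.0, 0.0])
            u = _unit(u)
        surface = point + u * shaft_r
        spec.position_arclen = float(s)
        spec.azimuth = az
        spec.attachment = tuple(surface)
        spec.direction = tuple(u)
        prims, length = _spine_primitives(spec, surface, u, rng)
        spec.primitives = prims
        if spec.length == 0.0:
            spec.length = length
        spines.append(spec)
    return PhantomTruth(morphology, spines,
                        density_per_um=len(spines) / total if total else 0.0,
                        decorated_length=total)


# ---------------------------------------------------------------------------
# voxelization and rendering
# ---------------------------------------------------------------------------

def _soma_primitives(m: NeuronMorphology) -> list:
    """Approximate an elongated soma by spheres along its principal axis."""
    soma = m.soma_nodes()
    if not soma:
        return []
    if len(soma) == 1:
        n = soma[0]
        return [("sphere", n.pos, n.radius)]
    pts = np.array([n.pos for n in soma])
    radii = np.array([n.radius for n in soma])
    centre = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centre, full_matrices=False)
    axis = vt[0]
    proj = (pts - centre) @ axis
    L = proj.max() - proj.min()
    R = radii.max()
    prims = []
    for t in np.linspace(-1.0, 1.0, 11):
        r = R * math.sqrt(max(1.0 - t * t, 0.0))
        if r > 0.05:
            prims.append(("sphere", centre + axis * (t * L / 2.0), r))
    return prims


def _geometry_primitives(truth: PhantomTruth) -> list:
    prims = _soma_primitives(truth.morphology)
    m = truth.morphology
    for n in m.nodes:
        if n.parent == -1 or n.structure != DENDRITE:
            continue
        p = m.node(n.parent)
        if p.structure != DENDRITE:
            continue
        prims.append(("capsule", p.pos, n.pos, p.radius, n.radius))
    for s in truth.spines:
        prims.extend(s.primitives)
    return prims


def _paint_primitive(mask: np.ndarray, prim, spacing: VoxelSpacing,
                     origin: np.ndarray) -> None:
    dzyx = np.array([spacing.dz, spacing.dy, spacing.dx])
    if prim[0] == "sphere":
        _, c, r = prim
        lo_w = np.array([c[2] - r, c[1] - r, c[0] - r])
        hi_w = np.array([c[2] + r, c[1] + r, c[0] + r])
    else:
        _, a, b, r0, r1 = prim
        r = max(r0, r1)
        lo_w = np.minimum(a[::-1], b[::-1]) - r
        hi_w = np.maximum(a[::-1], b[::-1]) + r
    lo = np.maximum(np.floor((lo_w - origin[::-1]) / dzyx).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((hi_w - origin[::-1]) / dzyx).astype(int) + 2,
                    np.array(mask.shape))
    if (hi <= lo).any():
        return
    zz, yy, xx = np.meshgrid(
        origin[2] + np.arange(lo[0], hi[0]) * spacing.dz,
        origin[1] + np.arange(lo[1], hi[1]) * spacing.dy,
        origin[0] + np.arange(lo[2], hi[2]) * spacing.dx,
        indexing="ij",
    )
    pts = np.stack([xx, yy, zz], axis=-1)
    if prim[0] == "sphere":
        _, c, r = prim
        inside = np.sum((pts - np.asarray(c)) ** 2, axis=-1) <= r * r
    else:
        _, a, b, r0, r1 = prim
        a = np.asarray(a, dtype=float)
        ab = np.asarray(b, dtype=float) - a
        denom = float(ab @ ab)
        t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
        nearest = a + t[..., None] * ab if denom > 0 else a
        d2 = np.sum((pts - nearest) ** 2, axis=-1)
        rr = r0 + (r1 - r0) * (t if denom > 0 else 0.0)
        inside = d2 <= rr * rr
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= inside


def voxelize_truth(
    truth: PhantomTruth, spacing: VoxelSpacing,
    shape: tuple[int, int, int] | None = None,
    origin: Sequence[float] | None = None,
    pad: float = 0.0,
) -> BinaryVolume:
    """Rasterize the phantom geometry into an exact boolean voxel grid.

    A voxel is foreground iff its centre lies inside any geometric
    primitive (sphere, or capsule with linearly interpolated radius).
    With ``shape=None`` the grid spans from ``origin`` (default: the
    geometry's padded bounding-box corner) to the bounding-box top with
    ``floor(extent/step)+1`` voxels per axis — voxel-centre convention.
    Passing ``origin=(0, 0, 0)`` keeps grid indices aligned with world
    coordinates for geometry placed in the positive octant.
    """
    prims = _geometry_primitives(truth)
    if shape is None:
        if not prims:
            raise ValueError("empty geometry needs an explicit shape")
        los, his = [], []
        for p in prims:
            if p[0] == "sphere":
                c, r = np.asarray(p[1], float), p[2]
                los.append(c - r)
                his.append(c + r)
            else:
                a, b, r = np.asarray(p[1], float), np.asarray(p[2], float), max(p[3], p[4])
                los.append(np.minimum(a, b) - r)
                his.append(np.maximum(a, b) + r)
        lo = np.min(los, axis=0) - pad
        hi = np.max(his, axis=0) + pad
        origin = lo if origin is None else np.asarray(origin, dtype=float)
        steps = np.array([spacing.dx, spacing.dy, spacing.dz])
        shape_xyz = np.floor((hi - origin) / steps + 1e-9).astype(int) + 1
        shape = (int(shape_xyz[2]), int(shape_xyz[1]), int(shape_xyz[0]))
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    for p in prims:
        _paint_primitive(mask, p, spacing, origin)
    return BinaryVolume(mask, spacing, provenance=[{"stage": "voxelize_truth",
                                                    "origin": tuple(origin)}])


def render_stack(
    truth: PhantomTruth,
    spacing: VoxelSpacing,
    psf_sigma_xy: float = 0.0,
    psf_sigma_z: float = 0.0,
    bg_level: float = 200.0,
    fg_level: float = 50.0,
    speckle_density: float = 0.0,   # dark puncta per 1000 voxels
    illumination_gradient: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int, int] | None = None,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> ImageStack:
    """Render a brightfield-like 8-bit stack from phantom ground truth.

    Dark structure (``fg_level``) on a bright ground (``bg_level``),
    blurred with an anisotropic Gaussian PSF, with punctate dark speckle,
    a multiplicative left-right illumination ramp, additive Gaussian
    noise, and 8-bit quantization.  Also attaches the exact geometry mask
    to ``truth.mask``.  Deterministic for a fixed seed.
    """
    if fg_level >= bg_level:
        raise ValueError("brightfield rendering requires fg_level < bg_level")
    min_feature = min(
        [s.neck_diameter for s in truth.spines if s.neck_diameter > 0] or [np.inf]
    )
    if max(spacing.dx, spacing.dy, spacing.dz) > min_feature:
        warnings.warn(
            "voxel spacing coarser than the smallest spine neck diameter; "
            "thin necks may not be resolved", stacklevel=2,
        )
    vol = voxelize_truth(truth, spacing, shape=shape, origin=origin)
    truth.mask = vol
    rng = np.random.default_rng(seed)
    img = np.where(vol.mask, float(fg_level), float(bg_level))

    if speckle_density > 0:
        n = rng.poisson(speckle_density * img.size / 1000.0)
        if n:
            idx = rng.integers(0, img.size, size=n)
            zz, yy, xx = np.unravel_index(idx, img.shape)
            speck = np.zeros(img.shape, dtype=bool)
            speck[zz, yy, xx] = True
            speck = np.logical_or(speck, np.roll(speck, 1, axis=2))  # 2-voxel grains
            img = np.where(speck, fg_level + 0.25 * (bg_level - fg_level), img)
    if psf_sigma_xy > 0 or psf_sigma_z > 0:
        from scipy import ndimage
        img = ndimage.gaussian_filter(
            img, sigma=(psf_sigma_z / spacing.dz,
                        psf_sigma_xy / spacing.dy,
                        psf_sigma_xy / spacing.dx), mode="nearest")
    if illumination_gradient != 0:
        ramp = 1.0 + illumination_gradient * (
            np.linspace(-0.5, 0.5, img.shape[2])[None, None, :])
        img = img * ramp
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ImageStack(img, spacing, meta={"synthetic": True, "seed": seed})


# ---------------------------------------------------------------------------
# the standard spine fixture
# ---------------------------------------------------------------------------

#: Published fixture seed; the fixture is the reference condition every
#: recovery experiment runs against.
STANDARD_FIXTURE_SEED = 20220111
STANDARD_FIXTURE_SHAPE = (151, 128, 128)
STANDARD_FIXTURE_SPACING = VoxelSpacing(0.1, 0.1, 0.1)
STANDARD_FIXTURE_MIX = {
    "thin": 0.2, "stubby": 0.2, "wide": 0.2, "mushroom": 0.2, "ramified": 0.2,
}


def standard_spine_fixture(
    seed: int = STANDARD_FIXTURE_SEED,
    noise: Literal["noiseless", "snr10"] = "noiseless",
) -> tuple[PhantomTruth, ImageStack]:
    """The reference spine phantom: 60 spines at 0.8/μm on a helical
    75 μm dendritic segment, rendered at 0.1 μm isotropic voxels into a
    128x128x151 field of view.

    ``noiseless`` renders exact binary levels; ``snr10`` adds the PSF,
    speckle, an illumination ramp and Gaussian noise with a
    contrast-to-noise ratio of 10.
    """
    segment = helix_segment()
    truth = decorate_with_spines(
        segment, density_per_um=0.8, class_mix=STANDARD_FIXTURE_MIX,
        seed=seed, n_spines=60, min_separation=0.95, spinule_fraction=0.15,
        max_axial_component=0.5,
    )
    if noise == "noiseless":
        stack = render_stack(truth, STANDARD_FIXTURE_SPACING,
                             shape=STANDARD_FIXTURE_SHAPE, seed=seed)
    else:
        stack = render_stack(
            truth, STANDARD_FIXTURE_SPACING, shape=STANDARD_FIXTURE_SHAPE,
            psf_sigma_xy=0.08, psf_sigma_z=0.16, speckle_density=0.2,
            illumination_gradient=0.1, noise_sd=15.0, seed=seed,
        )
    return truth, stack


def invariance_phantom(seed: int = 0):
    """Straight-shaft phantom with eight well-separated spines (stubby,
    wide, mushroom, ramified — classes whose decision ratios sit far from
    every rule boundary) for orientation/scale invariance checks.

    Returns (truth, volume) with the volume voxelized at 0.1 μm isotropic
    into an 81x160x280 grid.
    """
    segment = straight_segment(length=24.0, radius=0.45, start=(2.0, 8.0, 4.0),
                               node_spacing=1.0)
    positions = [3.0, 5.5, 8.0, 10.5, 13.0, 15.5, 18.0, 20.5]
    classes = ["stubby", "wide", "mushroom", "ramified"] * 2
    truth = decorate_with_spines(
        segment, 0.0, {"stubby": 1.0}, seed=seed, positions=positions,
        class_sequence=classes, max_axial_component=0.5, spinule_fraction=0.0,
    )
    spacing = VoxelSpacing(0.1, 0.1, 0.1)
    volume = voxelize_truth(truth, spacing, shape=(81, 160, 280),
                            origin=(0.0, 0.0, 0.0))
    return truth, volume
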
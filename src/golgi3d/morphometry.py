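"""SWC morphology I/O and cylinder-model morphometry.

A reconstruction is a rooted tree of 3D sample points with radii (SWC
semantics): each edge between connected samples is a frustum (truncated
cone), so the dendritic tree is a series of connected tapering cylinders.
The quantities computed here are the classic single-cell ones: cell-body
length / maximum diameter / volume, primary-shaft diameters, total number
of branches (unbranched segments delimited by origins, branching points
and tips), total dendritic length, and total dendritic volume (frustum
sum).  A geometric qualifier tests the spindle phenotype: two primary
dendrites leaving opposite somatic poles, both near-vertical, on an
elongated soma.

Soma convention
---------------
The soma is carried by structure-code-1 nodes.  The generator writes a
three-point soma: two pole nodes at the tips of the major axis and a
centre node whose radius is half the maximum minor-axis diameter.  Soma
length is the positional extent of the soma nodes along their principal
axis (or twice the maximum radius for a single-node sphere, whichever is
larger); maximum diameter is twice the largest soma-node radius; volume
uses the prolate-ellipsoid model (4/3)*pi*(L/2)*(D/2)^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "SWCNode",
    "NeuronMorphology",
    "MorphometryReport",
    "SpindleCriteria",
    "read_swc",
    "write_swc",
    "soma_metrics",
    "dendrite_metrics",
    "classify_spindle",
    "frustum_volume",
]

SOMA = 1
AXON = 2
DENDRITE = 3
APICAL = 4


def frustum_volume(r1: float, r2: float, h: float) -> float:
    """Volume of a truncated cone: pi*h*(r1^2 + r1*r2 + r2^2)/3."""
    return math.pi * h * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0


@dataclass(frozen=True)
class SWCNode:
    id: int
    structure: int
    x: float
    y: float
    z: float
    radius: float
    parent: int

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


class SWCError(ValueError):
    """Malformed SWC content (duplicate id, dangling parent, cycle, bad radius)."""


@dataclass
class NeuronMorphology:
    """Validated rooted tree of SWC nodes."""

    nodes: list[SWCNode]
    _children: dict[int, list[int]] = field(default_factory=dict, repr=False)
    _by_id: dict[int, SWCNode] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        by_id: dict[int, SWCNode] = {}
        for n in self.nodes:
            if n.id in by_id:
                raise SWCError(f"duplicate node id {n.id}")
            if n.radius <= 0:
                raise SWCError(f"node {n.id}: nonpositive radius {n.radius}")
            by_id[n.id] = n
        roots = [n for n in self.nodes if n.parent == -1]
        if len(roots) != 1:
            raise SWCError(f"expected exactly one root, found {len(roots)}")
        children: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent != -1:
                if n.parent not in by_id:
                    raise SWCError(f"node {n.id}: dangling parent {n.parent}")
                children[n.parent].append(n.id)
        # cycle / connectivity check: walk from the root
        seen: set[int] = set()
        stack = [roots[0].id]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise SWCError(f"cycle detected at node {nid}")
            seen.add(nid)
            stack.extend(children[nid])
        if len(seen) != len(self.nodes):
            raise SWCError("graph is not a single connected tree")
        self._by_id = by_id
        self._children = children

    # -- accessors -------------------------------------------------------
    @property
    def root(self) -> SWCNode:
        return next(n for n in self.nodes if n.parent == -1)

    def node(self, nid: int) -> SWCNode:
        return self._by_id[nid]

    def children(self, nid: int) -> list[SWCNode]:
        return [self._by_id[c] for c in self._children[nid]]

    def soma_nodes(self) -> list[SWCNode]:
        return [n for n in self.nodes if n.structure == SOMA]

    def dendrite_nodes(self) -> list[SWCNode]:
        return [n for n in self.nodes if n.structure in (DENDRITE, APICAL)]

    def primary_dendrite_roots(self) -> list[SWCNode]:
        """Dendritic nodes whose parent is a soma node (or the tree root)."""
        out = []
        for n in self.nodes:
            if n.structure in (DENDRITE, APICAL) and n.parent != -1:
                if self._by_id[n.parent].structure == SOMA:
                    out.append(n)
        return out

    def subtree_ids(self, nid: int) -> list[int]:
        out, stack = [], [nid]
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(self._children[cur])
        return out

    # -- geometry helpers ------------------------------------------------
    def edge_length(self, child: SWCNode) -> float:
        p = self._by_id[child.parent]
        return float(np.linalg.norm(child.pos - p.pos))

    def transformed(self, R: np.ndarray | None = None, t: np.ndarray | None = None,
                    scale: float = 1.0) -> "NeuronMorphology":
        """Return a rigidly transformed / uniformly scaled copy."""
        R = np.eye(3) if R is None else np.asarray(R, dtype=float)
        t = np.zeros(3) if t is None else np.asarray(t, dtype=float)
        out = []
        for n in self.nodes:
            p = scale * (R @ n.pos) + t
            out.append(SWCNode(n.id, n.structure, *p, n.radius * scale, n.parent))
        return NeuronMorphology(out)


def read_swc(path: str | Path) -> NeuronMorphology:
    """Parse whitespace-delimited 7-column SWC with '#' comments."""
    nodes = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        nid, struct = int(parts[0]), int(parts[1])
        x, y, z, r = (float(p) for p in parts[2:6])
        nodes.append(SWCNode(nid, struct, x, y, z, r, int(parts[6])))
    return NeuronMorphology(nodes)


def write_swc(m: NeuronMorphology, path: str | Path, header: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    for n in m.nodes:
        lines.append(
            f"{n.id} {n.structure} {n.x:.6f} {n.y:.6f} {n.z:.6f} {n.radius:.6f} {n.parent}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def soma_metrics(m: NeuronMorphology) -> tuple[float, float, float]:
    """(length, max diameter, prolate-ellipsoid volume) of the soma, in μm."""
    soma = m.soma_nodes()
    if not soma:
        raise ValueError("morphology has no soma nodes (structure code 1)")
    pts = np.array([n.pos for n in soma])
    radii = np.array([n.radius for n in soma])
    max_diam = float(2.0 * radii.max())
    if len(soma) == 1:
        length = max_diam
    else:
        centred = pts - pts.mean(axis=0)
        # principal axis of the soma point set
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        proj = centred @ vt[0]
        length = float(proj.max() - proj.min())
        length = max(length, max_diam)
    volume = (4.0 / 3.0) * math.pi * (length / 2.0) * (max_diam / 2.0) ** 2
    return length, max_diam, volume


@dataclass
class MorphometryReport:
    soma_length: float
    soma_max_diameter: float
    soma_volume: float
    primary_shaft_diameters: list[float]
    n_branches: int
    total_dendritic_length: float
    total_dendritic_volume: float
    per_dendrite: list[dict]

    def as_dict(self) -> dict:
        return {
            "soma_length_um": self.soma_length,
            "soma_max_diameter_um": self.soma_max_diameter,
            "soma_volume_um3": self.soma_volume,
            "primary_shaft_diameters_um": self.primary_shaft_diameters,
            "n_branches": self.n_branches,
            "total_dendritic_length_um": self.total_dendritic_length,
            "total_dendritic_volume_um3": self.total_dendritic_volume,
            "per_dendrite": self.per_dendrite,
        }


def _dendritic_subtree_metrics(m: NeuronMorphology, primary: SWCNode) -> dict:
    """Branch count, length and frustum volume of one primary dendrite's subtree."""
    n_branches = 0
    length = 0.0
    volume = 0.0
    # segments: start at the primary origin; a segment ends at a branch
    # point (>=2 children) or a tip; each child then starts a new segment
    stack = [primary.id]
    while stack:
        nid = stack.pop()
        n_branches += 1
        cur = nid
        while True:
            node = m.node(cur)
            parent = m.node(node.parent)
            if parent.structure != SOMA:  # edges into the soma carry no dendritic length
                h = float(np.linalg.norm(node.pos - parent.pos))
                length += h
                volume += frustum_volume(parent.radius, node.radius, h)
            kids = m.children(cur)
            if len(kids) == 1:
                cur = kids[0].id
            else:
                stack.extend(k.id for k in kids)
                break
    return {
        "primary_id": primary.id,
        "n_branches": n_branches,
        "length_um": length,
        "volume_um3": volume,
        "shaft_diameter_um": 2.0 * primary.radius,
    }


def dendrite_metrics(m: NeuronMorphology) -> tuple[int, float, float, list[float]]:
    """(n_branches, total length μm, total frustum volume μm³, shaft diameters).

    A branch is an unbranched segment delimited by primary origins,
    branching points and terminal tips; totals are sums over all primary
    subtrees (soma excluded).
    """
    primaries = m.primary_dendrite_roots()
    if not primaries and not m.dendrite_nodes():
        raise ValueError("morphology has no dendritic nodes")
    per = [_dendritic_subtree_metrics(m, p) for p in primaries]
    n_branches = sum(d["n_branches"] for d in per)
    total_length = sum(d["length_um"] for d in per)
    total_volume = sum(d["volume_um3"] for d in per)
    diameters = [d["shaft_diameter_um"] for d in per]
    return n_branches, total_length, total_volume, diameters


def morphometry_report(m: NeuronMorphology) -> MorphometryReport:
    """Full per-cell report combining soma and dendrite metrics."""
    L, D, V = soma_metrics(m)
    primaries = m.primary_dendrite_roots()
    per = [_dendritic_subtree_metrics(m, p) for p in primaries]
    return MorphometryReport(
        soma_length=L,
        soma_max_diameter=D,
        soma_volume=V,
        primary_shaft_diameters=[d["shaft_diameter_um"] for d in per],
        n_branches=sum(d["n_branches"] for d in per),
        total_dendritic_length=sum(d["length_um"] for d in per),
        total_dendritic_volume=sum(d["volume_um3"] for d in per),
        per_dendrite=per,
    )


# ---------------------------------------------------------------------------
# spindle qualifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpindleCriteria:
    """Thresholds for the spindle-phenotype qualifier.

    vertical_axis: unit vector toward the pial surface (SWC carries no
    anatomical frame, so it must be declared).
    """

    vertical_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    min_primary_diameter_frac: float = 0.6
    min_pole_angle_deg: float = 150.0
    max_vertical_dev_deg: float = 30.0
    min_soma_elongation: float = 1.6
    departure_node_index: int = 5


def _departure_direction(m: NeuronMorphology, primary: SWCNode, k: int) -> np.ndarray:
    """Unit vector soma centroid -> k-th node along the primary (or tip)."""
    soma = m.soma_nodes()
    origin = np.mean([n.pos for n in soma], axis=0) if soma else m.root.pos
    cur = primary
    for _ in range(k - 1):
        kids = m.children(cur.id)
        if len(kids) != 1:
            break
        cur = kids[0]
    d = cur.pos - origin
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ValueError(f"degenerate departure direction for primary {primary.id}")
    return d / nrm


def classify_spindle(
    m: NeuronMorphology, criteria: SpindleCriteria | None = None
) -> tuple[bool, dict]:
    """Evaluate the geometric spindle-neuron qualifier.

    Criteria: exactly two substantial primary dendrites (basal diameter at
    least ``min_primary_diameter_frac`` of the thickest), departing from
    opposite somatic poles (angle between departure directions >=
    ``min_pole_angle_deg``), each within ``max_vertical_dev_deg`` of the
    declared vertical axis, on an elongated soma (L/D >=
    ``min_soma_elongation``).  Returns (flag, per-criterion report).
    """
    c = criteria or SpindleCriteria()
    primaries = m.primary_dendrite_roots()
    if not primaries:
        raise ValueError("morphology has no primary dendrites")
    diam = np.array([2.0 * p.radius for p in primaries])
    substantial = [p for p, d in zip(primaries, diam) if d >= c.min_primary_diameter_frac * diam.max()]
    report: dict = {"n_primary": len(primaries), "n_substantial_primary": len(substantial)}
    report["two_primaries"] = len(substantial) == 2

    axis = np.asarray(c.vertical_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if report["two_primaries"]:
        d1 = _departure_direction(m, substantial[0], c.departure_node_index)
        d2 = _departure_direction(m, substantial[1], c.departure_node_index)
        pole_angle = math.degrees(math.acos(float(np.clip(d1 @ d2, -1.0, 1.0))))
        devs = [
            math.degrees(math.acos(float(np.clip(abs(d @ axis), 0.0, 1.0))))
            for d in (d1, d2)
        ]
        report["pole_angle_deg"] = pole_angle
        report["vertical_deviation_deg"] = devs
        report["opposite_poles"] = pole_angle >= c.min_pole_angle_deg
        report["vertical_orientation"] = all(v <= c.max_vertical_dev_deg for v in devs)
    else:
        report["opposite_poles"] = False
        report["vertical_orientation"] = False

    L, D, _ = soma_metrics(m)
    report["soma_elongation"] = L / D
    report["elongated_soma"] = (L / D) >= c.min_soma_elongation

    ok = bool(
        report["two_primaries"]
        and report["opposite_poles"]
        and report["vertical_orientation"]
        and report["elongated_soma"]
    )
    report["is_spindle"] = ok
    return ok, report
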
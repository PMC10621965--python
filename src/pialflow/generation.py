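"""Construction of full semi-realistic microvascular networks.

Starting from a pial surface-artery (SA) graph, the generator (i) samples
additional descending-artery (DA) root locations into the SA reconstruction
until a target areal root density is met, (ii) distributes ascending-vein
(AV) roots around the DA roots on a rhombic pattern with a DA:AV ratio of
1:3, (iii) grows bifurcating penetrating trees (DA and AV) into the cortex
with Murray-law diameter tapering, (iv) lays down a stacked hexagonal
capillary lattice with uniform diameter, length and tortuosity, and (v)
assembles everything into one connected network with a single inflow vertex
(circle of Willis, 100 mmHg) and outflow boundary conditions (10 mmHg) at
every AV root.

Penetrating trees are synthesised algorithmically (random bifurcating
trees with depth targets and Murray tapering); their statistics are config
parameters chosen so that assembled networks fall into published ranges of
length/volume density per vessel type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import VascularNetwork, Vertex, validate_network

__all__ = ["GenerationConfig", "refine_pial_network", "place_av_roots",
           "generate_penetrating_tree", "generate_capillary_lattice",
           "assemble_network", "build_network"]


@dataclass
class GenerationConfig:
    """Parameters of the network generator (lengths in um).

    ``tree_scale`` rescales the reference penetrating-tree segment length
    (rat-derived trees are scaled by 2/3 for mouse cortex).
    """

    target_da_root_density: float = 12.0   # roots per mm^2
    av_per_da: int = 3
    capillary_diameter: float = 4.0
    capillary_length: float = 62.0
    capillary_tortuosity: float = 1.37
    lattice_depth: float = 260.0
    lattice_layers: int = 4
    lattice_top: float = 60.0              # z of the shallowest capillary layer
    tree_scale: float = 2.0 / 3.0
    tree_segment_length: float = 120.0      # reference (pre-scale) segment length
    tree_min_diameter: float = 6.0
    da_root_diameter_range: tuple[float, float] = (15.0, 20.0)
    av_root_diameter_range: tuple[float, float] = (24.0, 36.0)
    tree_bifurcation_prob: float = 0.85
    tree_lateral_extent: float = 140.0     # max lateral drift of a tree from its root
    da_root_min_spacing: float = 100.0
    av_offset: float = 150.0
    sa_attach_diameter: float = 14.0
    connector_diameter: float = 4.0        # leaf-to-capillary connector calibre
    sa_tortuosity: float = 1.1
    max_connector_length: float = 200.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.av_per_da < 1:
            raise ValueError("av_per_da must be >= 1")
        if self.capillary_tortuosity < 1.0:
            raise ValueError("capillary_tortuosity must be >= 1")
        for name in ("target_da_root_density", "capillary_diameter", "capillary_length",
                     "lattice_depth", "lattice_layers", "tree_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------- refinement

def _point_segment(p, a, b):
    """(distance, t, foot) from point p to segment ab, planar coordinates."""
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    foot = a + t * ab
    return float(np.linalg.norm(p - foot)), t, foot


def _pial_hull(net: VascularNetwork):
    from shapely.geometry import MultiPoint

    pts = [(v.position[0], v.position[1]) for v in net.vertices.values()]
    return MultiPoint(pts).convex_hull


def refine_pial_network(pial: VascularNetwork, cfg: GenerationConfig,
                        rng: np.random.Generator) -> VascularNetwork:
    """Sample DA roots into the SA graph up to the target areal density.

    The target count is ``round(density * convex-hull area)`` over the pial
    vertices.  Each new root is connected to the nearest SA edge by a new
    SA vessel; the host edge is split at the orthogonal projection point
    (tie between equidistant SAs broken by lower edge id).  Original SA
    edges are only ever split, never removed.
    """
    from shapely.geometry import Point

    net = pial.copy()
    hull = _pial_hull(net)
    area_mm2 = hull.area / 1e6
    target = int(round(cfg.target_da_root_density * area_mm2))
    existing = net.vertices_of_role("da_root")
    if target < len(existing):
        raise ValueError(
            f"target DA-root count {target} below current count {len(existing)}")
    placed = [v.position[:2].copy() for v in existing]

    minx, miny, maxx, maxy = hull.bounds
    xmid = hull.centroid.x  # balance sampling across the two halves
    half_count = {False: 0, True: 0}
    for q in placed:
        half_count[bool(q[0] > xmid)] += 1
    tries, max_tries = 0, 20000
    while len(placed) < target:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"cannot place {target} DA roots with minimum inter-root spacing "
                f"{cfg.da_root_min_spacing} um in a {area_mm2:.3g} mm^2 hull")
        p = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
        if not hull.contains(Point(p)):
            continue
        if placed and min(np.linalg.norm(p - q) for q in placed) < cfg.da_root_min_spacing:
            continue
        half = bool(p[0] > xmid)
        if half_count[half] > half_count[not half]:
            continue
        # nearest SA edge (ties -> lower id)
        best = None
        for eid in sorted(net.vessels):
            e = net.vessels[eid]
            if e.vtype != "SA":
                continue
            a = net.vertices[e.v1].position[:2]
            b = net.vertices[e.v2].position[:2]
            dist, t, _ = _point_segment(p, a, b)
            if best is None or dist < best[0] - 1e-12:
                best = (dist, eid, t)
        if best is None:
            raise ValueError("pial network contains no SA edges to attach DA roots to")
        dist, eid, t = best
        host = net.vessels[eid]
        if t < 0.05 or t > 0.95:
            attach_vid = host.v1 if t < 0.05 else host.v2
        else:
            attach_vid = net.split_vessel(eid, t).id
        root = net.add_vertex((p[0], p[1], 0.0), role="da_root")
        chord = max(net.distance(attach_vid, root.id), 1.0)
        net.add_vessel(attach_vid, root.id, min(host.diameter, cfg.sa_attach_diameter),
                       chord * cfg.sa_tortuosity, "SA", host.side)
        placed.append(p)
        half_count[half] += 1
    return net


def place_av_roots(net: VascularNetwork, cfg: GenerationConfig,
                   rng: np.random.Generator) -> VascularNetwork:
    """Add ``av_per_da`` AV-root vertices around each DA root.

    Offsets lie on a rhombic pattern (equal radius ``av_offset``, equally
    spaced angles with a per-root random phase), deterministic given the
    seed.  AV roots receive their outflow boundary conditions during
    assembly.
    """
    out = net.copy()
    angles = np.arange(cfg.av_per_da) * (2.0 * math.pi / cfg.av_per_da)
    for root in sorted(out.vertices_of_role("da_root"), key=lambda v: v.id):
        phase = rng.uniform(0.0, 2.0 * math.pi)
        for ang in angles:
            dx = cfg.av_offset * math.cos(phase + ang)
            dy = cfg.av_offset * math.sin(phase + ang)
            out.add_vertex((root.position[0] + dx, root.position[1] + dy, 0.0),
                           role="av_root")
    return out


# -------------------------------------------------------------------- trees

def generate_penetrating_tree(root: Vertex, kind: str, cfg: GenerationConfig,
                              rng: np.random.Generator) -> VascularNetwork:
    """Grow one bifurcating penetrating tree below a surface root.

    Returns a standalone fragment whose vertex 0 sits at the root position
    (z = 0).  Diameters taper from a sampled root diameter towards the
    leaves following Murray's rule d_parent^3 = sum d_child^3; leaves carry
    role ``tree_leaf``.  AV trees share the generator (flow direction is
    set purely by the boundary conditions), with a larger root calibre.
    """
    if kind not in ("DA", "AV"):
        raise ValueError(f"tree kind must be DA or AV, got {kind!r}")
    depth = cfg.lattice_depth
    if depth <= 0:
        raise ValueError("lattice_depth must be positive")
    lo, hi = (cfg.da_root_diameter_range if kind == "DA" else cfg.av_root_diameter_range)
    # reference (rat-derived) tree dimensions are rescaled for mouse cortex:
    # the scale applies to segment lengths and calibres alike
    d_root = rng.uniform(lo, hi) * cfg.tree_scale
    seg = cfg.tree_segment_length * cfg.tree_scale

    frag = VascularNetwork()
    r = frag.add_vertex(root.position, role=root.role)
    stack = [(r.id, float(d_root), 0)]  # (vertex id, diameter, level)
    while stack:
        vid, d, level = stack.pop()
        pos = frag.vertices[vid].position
        deep = pos[2] >= 0.92 * depth
        if (d < cfg.tree_min_diameter or deep) and level > 0:
            frag.vertices[vid].role = "tree_leaf"
            continue
        branch = level >= 1 and rng.uniform() < cfg.tree_bifurcation_prob
        if branch:
            w = rng.uniform(0.4, 0.6)
            children = [d * w ** (1.0 / 3.0), d * (1.0 - w) ** (1.0 / 3.0)]
        else:
            children = [d]
        for dc in children:
            length = seg * rng.uniform(0.8, 1.2)
            theta = rng.uniform(0.0, math.radians(40.0))
            phi = rng.uniform(0.0, 2.0 * math.pi)
            dz = length * math.cos(theta)
            new_z = min(pos[2] + dz, depth)
            ext = cfg.tree_lateral_extent
            nx_ = np.clip(pos[0] + length * math.sin(theta) * math.cos(phi),
                          root.position[0] - ext, root.position[0] + ext)
            ny_ = np.clip(pos[1] + length * math.sin(theta) * math.sin(phi),
                          root.position[1] - ext, root.position[1] + ext)
            new = frag.add_vertex((nx_, ny_, new_z))
            chord = max(frag.distance(vid, new.id), 1.0)
            frag.add_vessel(vid, new.id, dc, chord * 1.05, kind)
            stack.append((new.id, dc, level + 1))
    return frag


# ------------------------------------------------------------------ lattice

def generate_capillary_lattice(bbox: tuple[float, float, float, float],
                               cfg: GenerationConfig,
                               rng: np.random.Generator) -> VascularNetwork:
    """Stacked hexagonal (honeycomb) capillary lattice over ``bbox``.

    ``bbox`` is (xmin, xmax, ymin, ymax) in um.  In-plane bond chord equals
    ``capillary_length / capillary_tortuosity`` so every edge carries the
    configured hydraulic length and tortuosity exactly; layers are spaced
    one chord apart in z and joined by vertical connectors with the same
    diameter and length.
    """
    import networkx as nx

    xmin, xmax, ymin, ymax = bbox
    a = cfg.capillary_length / cfg.capillary_tortuosity  # chord
    width, height = xmax - xmin, ymax - ymin
    if width < math.sqrt(3.0) * a or height < 1.5 * a:
        raise ValueError("bbox smaller than one hexagon of the capillary lattice")
    n_cols = int(math.ceil(width / (math.sqrt(3.0) * a))) + 1
    n_rows = int(math.ceil(height / (1.5 * a))) + 1
    g = nx.hexagonal_lattice_graph(n_rows, n_cols)
    pos = nx.get_node_attributes(g, "pos")

    frag = VascularNetwork()
    keep = {}
    for node, (px, py) in pos.items():
        x, y = xmin + px * a, ymin + py * a
        if x <= xmax + 0.5 * a and y <= ymax + 0.5 * a:
            keep[node] = (x, y)
    vid_of = {}
    for k in range(cfg.lattice_layers):
        z = cfg.lattice_top + k * a
        for node, (x, y) in keep.items():
            vid_of[(node, k)] = frag.add_vertex((x, y, z)).id
    for k in range(cfg.lattice_layers):
        for u, v in g.edges():
            if u in keep and v in keep:
                frag.add_vessel(vid_of[(u, k)], vid_of[(v, k)],
                                cfg.capillary_diameter, cfg.capillary_length, "C")
        if k + 1 < cfg.lattice_layers:
            for node in keep:
                frag.add_vessel(vid_of[(node, k)], vid_of[(node, k + 1)],
                                cfg.capillary_diameter, cfg.capillary_length, "C")
    return frag


# ----------------------------------------------------------------- assembly

def _merge_fragment(net: VascularNetwork, frag: VascularNetwork,
                    attach: dict[int, int] | None = None) -> dict[int, int]:
    """Copy a fragment into ``net``; returns fragment-id -> net-id map."""
    attach = attach or {}
    vmap: dict[int, int] = {}
    for v in sorted(frag.vertices.values(), key=lambda v: v.id):
        if v.id in attach:
            vmap[v.id] = attach[v.id]
        else:
            vmap[v.id] = net.add_vertex(v.position, role=v.role).id
    for e in sorted(frag.vessels.values(), key=lambda e: e.id):
        net.add_vessel(vmap[e.v1], vmap[e.v2], e.diameter, e.length, e.vtype, e.side,
                       has_diameter_measurement=e.has_diameter_measurement,
                       d_prior=e.d_prior, is_connector=e.is_connector)
    return vmap


def assemble_network(pial: VascularNetwork,
                     trees: dict[int, VascularNetwork],
                     lattice: VascularNetwork,
                     cfg: GenerationConfig) -> VascularNetwork:
    """Join pial graph, penetrating trees and capillary lattice.

    ``trees`` maps a pial root-vertex id to its tree fragment (fragment
    vertex 0 is the root).  Every tree leaf is connected to its nearest
    lattice vertex by a connector edge inheriting the tree's type.  Sets
    the pressure boundary conditions: 100 mmHg at the single inflow vertex
    and 10 mmHg at every AV root.
    """
    from scipy.spatial import cKDTree

    net = pial.copy()
    lmap = _merge_fragment(net, lattice)
    lat_ids = np.array([lmap[i] for i in sorted(lattice.vertices)])
    lat_pos = np.array([net.vertices[i].position for i in lat_ids])
    kd = cKDTree(lat_pos)

    for root_id, frag in sorted(trees.items()):
        vmap = _merge_fragment(net, frag, attach={0: root_id})
        vtype = next(iter(frag.vessels.values())).vtype if frag.vessels else "DA"
        for fv in frag.vertices.values():
            if fv.role != "tree_leaf":
                continue
            leaf_id = vmap[fv.id]
            leaf_pos = net.vertices[leaf_id].position
            dist, j = kd.query(leaf_pos)
            if dist > cfg.max_connector_length:
                raise ValueError(
                    f"tree leaf {leaf_id} is {dist:.0f} um from the nearest capillary "
                    f"(max connector length {cfg.max_connector_length} um)")
            chord = max(float(dist), 1.0)
            net.add_vessel(leaf_id, int(lat_ids[j]), cfg.connector_diameter,
                           chord * 1.1, vtype, is_connector=True)

    net.boundary_conditions = {net.inflow_vertex.id: 100.0}
    for v in net.vertices_of_role("av_root"):
        net.boundary_conditions[v.id] = 10.0
    return net


def build_network(pial: VascularNetwork, cfg: GenerationConfig,
                  rng: np.random.Generator) -> VascularNetwork:
    """Full pipeline: refine -> AV roots -> trees -> lattice -> assemble."""
    refined = refine_pial_network(pial, cfg, rng)
    refined = place_av_roots(refined, cfg, rng)
    trees = {}
    for v in sorted(refined.vertices_of_role("da_root"), key=lambda v: v.id):
        trees[v.id] = generate_penetrating_tree(v, "DA", cfg, rng)
    for v in sorted(refined.vertices_of_role("av_root"), key=lambda v: v.id):
        trees[v.id] = generate_penetrating_tree(v, "AV", cfg, rng)
    roots = (refined.vertices_of_role("da_root") + refined.vertices_of_role("av_root"))
    xs = [v.position[0] for v in roots]
    ys = [v.position[1] for v in roots]
    pad = cfg.tree_lateral_extent + 40.0
    bbox = (min(xs) - pad, max(xs) + pad, min(ys) - pad, max(ys) + pad)
    lattice = generate_capillary_lattice(bbox, cfg, rng)
    net = assemble_network(refined, trees, lattice, cfg)
    rep = validate_network(net)
    if rep.violations:
        raise RuntimeError("assembled network failed validation: "
                           + "; ".join(v.message for v in rep.violations[:5]))
    return net
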
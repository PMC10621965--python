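"""Territory classification and perfusion-change metrics.

Vessels are assigned to the MCA or ACA territory by tracing the baseline
supply of every DA root upstream through the pial network (always following
the incident edge with the largest inflow) until one of the feeder branches
is reached.  The feeding area of each DA tree is approximated by the planar
Voronoi tessellation around all DA roots; capillaries inherit the label of
the cell containing them and the watershed line is the boundary between
differently labelled cells.

Perfusion changes between two solved states are reported as relative
changes of a class aggregate: mean flow (dq_rel), integral/sum flow
(dQ_rel) and mean pressure (dp_rel), each (agg_new - agg_base)/agg_base.
Flow values enter as magnitudes (flows reverse under occlusion; perfusion
is reported as a positive quantity), pressures enter signed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import VascularNetwork
from .solver import FlowSolution

__all__ = ["VesselClassification", "assign_sides", "classify_sa_paths",
           "relative_change", "distance_bins", "cbf_summary", "CbfSummary",
           "direction_changes", "integral_flow", "mean_flow",
           "capillary_border_mask"]

PIAL = ("SA", "SA_to_CoW", "LMC")


@dataclass
class VesselClassification:
    """Per-edge side labels, SA path classes and distance-to-LMC bins."""

    edge_side: dict[int, str]                 # MCA / ACA / none (LMCs)
    da_root_side: dict[int, str]              # da_root vertex id -> side
    voronoi_area: dict[int, float]            # da_root vertex id -> cell area um^2
    footprint_area_um2: float
    sa_path_class: dict[int, str] = field(default_factory=dict)
    dist_to_lmc: dict[int, float] = field(default_factory=dict)
    dist_bin: dict[int, int] = field(default_factory=dict)

    def edges_of(self, net: VascularNetwork, side: str, *vtypes: str,
                 include_connectors: bool = False) -> list[int]:
        out = []
        for e in net.vessels.values():
            if vtypes and e.vtype not in vtypes:
                continue
            if e.is_connector and not include_connectors:
                continue
            if self.edge_side.get(e.id) == side:
                out.append(e.id)
        return out


# ------------------------------------------------------------- side tracing

def _upstream_trace(net: VascularNetwork, sol: FlowSolution, start: int,
                    cache: dict[int, str]) -> str:
    """Follow the largest pial inflow upstream until a feeder branch."""
    adj = net.adjacency()
    q_floor = 1e-9 * max((abs(sol.flow_of(e.id)) for e in net.vessels.values()
                          if e.vtype in PIAL), default=0.0)
    path = []
    v = start
    visited = set()
    while True:
        if v in cache:
            side = cache[v]
            break
        if v in visited:
            raise RuntimeError(f"upstream trace from vertex {start} entered a cycle")
        visited.add(v)
        path.append(v)
        best, best_q = None, 0.0
        for e in adj[v]:
            if e.vtype not in PIAL:
                continue
            q = sol.flow_of(e.id)
            a, b = min(e.v1, e.v2), max(e.v1, e.v2)
            into_v = (q > 0 and b == v) or (q < 0 and a == v)
            if into_v and abs(q) > max(best_q, q_floor):
                best, best_q = e, abs(q)
        if best is None:
            # dead-end branches carry only round-off flow and are pressure-flat;
            # walk back towards the flowing network (the unvisited neighbour at
            # non-lower pressure with the largest flow on its own incident edges)
            p_v = sol.pressure_of(v)
            p_tol = 1e-6 * max(abs(p_v), 1.0)
            best_score = None
            for e in adj[v]:
                if e.vtype not in PIAL:
                    continue
                w = e.v1 if e.v2 == v else e.v2
                if w in visited or sol.pressure_of(w) < p_v - p_tol:
                    continue
                w_flow = max((abs(sol.flow_of(e2.id)) for e2 in adj[w]
                              if e2.vtype in PIAL), default=0.0)
                score = (w_flow, sol.pressure_of(w))
                if best_score is None or score > best_score:
                    best, best_score = e, score
        if best is None:
            raise RuntimeError(
                f"upstream trace from vertex {start} reached vertex {v} with no "
                "pial inflow (isolated component?)")
        if best.vtype == "SA_to_CoW":
            side = best.side if best.side in ("MCA", "ACA") else "MCA"
            break
        v = best.v1 if best.v2 == v else best.v2
    for u in path:
        cache[u] = side
    return side


def _voronoi_cells(net: VascularNetwork, roots):
    """Planar Voronoi polygons of the DA roots, clipped to their hull."""
    from shapely.geometry import MultiPoint, Point
    from shapely.ops import voronoi_diagram

    pts = [Point(net.vertices[r].position[0], net.vertices[r].position[1])
           for r in roots]
    hull = MultiPoint(pts).convex_hull
    cells = voronoi_diagram(MultiPoint(pts), envelope=hull.buffer(1000.0))
    polys = {}
    for poly in cells.geoms:
        clipped = poly.intersection(hull)
        for r, pt in zip(roots, pts):
            if poly.contains(pt):
                polys[r] = clipped
                break
    return polys, hull


def assign_sides(net: VascularNetwork, base_solution: FlowSolution
                 ) -> VesselClassification:
    """Label every vessel MCA or ACA from the baseline supply pattern.

    DA roots are traced upstream along the pial network; DA/AV tree edges
    inherit the label of their tree's root; capillaries take the label of
    the DA root whose planar Voronoi cell contains their midpoint; SAs are
    labelled by the same upstream trace from their high-pressure endpoint.
    LMCs have side "none".
    """
    from scipy.spatial import cKDTree

    cache: dict[int, str] = {}
    da_roots = sorted(v.id for v in net.vertices_of_role("da_root"))
    if not da_roots:
        raise ValueError("network has no DA roots")
    root_side = {r: _upstream_trace(net, base_solution, r, cache) for r in da_roots}

    polys, hull = _voronoi_cells(net, da_roots)
    areas = {r: (polys[r].area if r in polys else 0.0) for r in da_roots}

    root_pos = np.array([net.vertices[r].position[:2] for r in da_roots])
    kd = cKDTree(root_pos)

    # tree components over DA edges / AV edges (connectors included)
    comp_label: dict[int, str] = {}
    for vtype, root_role in (("DA", "da_root"), ("AV", "av_root")):
        seen_edges: set[int] = set()
        adj = net.adjacency()
        for rv in net.vertices_of_role(root_role):
            # flood over edges of this vtype starting at the root vertex
            if vtype == "DA":
                label = root_side[rv.id] if rv.id in root_side else "MCA"
            else:
                _, j = kd.query(rv.position[:2])
                label = root_side[da_roots[int(j)]]
            stack = [rv.id]
            comp_vs = set()
            while stack:
                u = stack.pop()
                if u in comp_vs:
                    continue
                comp_vs.add(u)
                for e in adj[u]:
                    if e.vtype != vtype or e.id in seen_edges:
                        continue
                    seen_edges.add(e.id)
                    comp_label[e.id] = label
                    stack.append(e.v2 if e.v1 == u else e.v1)

    edge_side: dict[int, str] = {}
    for e in net.vessels.values():
        if e.vtype == "LMC":
            edge_side[e.id] = "none"
        elif e.vtype == "SA_to_CoW":
            edge_side[e.id] = e.side
        elif e.vtype == "SA":
            p1 = base_solution.pressure_of(e.v1)
            p2 = base_solution.pressure_of(e.v2)
            up = e.v1 if p1 >= p2 else e.v2
            edge_side[e.id] = _upstream_trace(net, base_solution, up, cache)
        elif e.id in comp_label:
            edge_side[e.id] = comp_label[e.id]
        else:  # capillaries: Voronoi cell of the nearest DA root
            mid = 0.5 * (net.vertices[e.v1].position[:2] + net.vertices[e.v2].position[:2])
            _, j = kd.query(mid)
            edge_side[e.id] = root_side[da_roots[int(j)]]

    return VesselClassification(edge_side=edge_side, da_root_side=root_side,
                                voronoi_area=areas, footprint_area_um2=hull.area)


# --------------------------------------------------------------- SA path class

def classify_sa_paths(net: VascularNetwork, classification: VesselClassification
                      ) -> dict[int, str]:
    """Mark SAs on a geometric shortest path from the CoW to any LMC.

    All ties are kept: an SA edge is "on_path_to_LMC" if it lies on any
    minimum-length path (over SA / SA-to-CoW edges) from the inflow vertex
    to an endpoint of any LMC.  Fills and returns
    ``classification.sa_path_class``.
    """
    import networkx as nx

    g = nx.Graph()
    for e in net.vessels_of_type("SA", "SA_to_CoW"):
        w = e.length
        if g.has_edge(e.v1, e.v2):
            if w < g[e.v1][e.v2]["weight"]:
                g[e.v1][e.v2]["weight"] = w
        else:
            g.add_edge(e.v1, e.v2, weight=w)
    cow = net.inflow_vertex.id
    on_path: set[tuple[int, int]] = set()
    lmc_endpoints = sorted({vid for e in net.vessels_of_type("LMC")
                            for vid in (e.v1, e.v2)})
    for t in lmc_endpoints:
        if t not in g:
            continue  # dangling tip with no pial edges of its own
        try:
            paths = nx.all_shortest_paths(g, cow, t, weight="weight")
            for path in paths:
                for u, v in zip(path, path[1:]):
                    on_path.add((min(u, v), max(u, v)))
        except nx.NetworkXNoPath:
            raise ValueError(f"LMC endpoint {t} not reachable from the CoW") from None

    out = {}
    for e in net.vessels_of_type("SA", "SA_to_CoW"):
        key = (min(e.v1, e.v2), max(e.v1, e.v2))
        out[e.id] = "on_path_to_LMC" if key in on_path else "other"
    classification.sa_path_class = out
    return out


# ------------------------------------------------------------- change metrics

def relative_change(values_base, values_new, aggregator: str = "mean",
                    magnitudes: bool = True) -> float:
    """(agg(new) - agg(base)) / agg(base); NaN when the baseline aggregate is 0.

    With ``magnitudes`` (the default for flows) absolute values enter the
    aggregate; pressures should be passed with ``magnitudes=False``.
    """
    base = np.asarray(values_base, dtype=float)
    new = np.asarray(values_new, dtype=float)
    if base.size == 0 or base.size != new.size:
        raise ValueError("need matching non-empty value arrays")
    if magnitudes:
        base, new = np.abs(base), np.abs(new)
    agg = {"mean": np.mean, "sum": np.sum}[aggregator]
    b = float(agg(base))
    if b == 0.0:
        return float("nan")
    return (float(agg(new)) - b) / b


def mean_flow(sol: FlowSolution, edge_ids) -> float:
    return float(np.mean([abs(sol.flow_of(e)) for e in edge_ids]))


def integral_flow(sol: FlowSolution, edge_ids) -> float:
    """Integral (sum of magnitudes) flow over a vessel class, um^3/s."""
    return float(np.sum([abs(sol.flow_of(e)) for e in edge_ids]))


# ------------------------------------------------------------- distance bins

def _min_dist_to_segments(points: np.ndarray, segs: list[tuple[np.ndarray, np.ndarray]]
                          ) -> np.ndarray:
    best = np.full(len(points), np.inf)
    for a, b in segs:
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d = np.linalg.norm(points - a, axis=1)
        else:
            t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
            foot = a[None, :] + t[:, None] * ab[None, :]
            d = np.linalg.norm(points - foot, axis=1)
        best = np.minimum(best, d)
    return best


def distance_bins(net: VascularNetwork, classification: VesselClassification,
                  spacing: float = 250.0) -> dict[int, int]:
    """Planar distance from each edge midpoint to the nearest LMC, binned.

    Bin index is ``floor(distance / spacing)``; with no LMCs all distances
    are infinite and every edge falls into the single overflow bin (-1).
    Fills ``classification.dist_to_lmc`` / ``dist_bin``.
    """
    segs = [(net.vertices[e.v1].position[:2].astype(float),
             net.vertices[e.v2].position[:2].astype(float))
            for e in net.vessels_of_type("LMC")]
    eids = sorted(net.vessels)
    mids = np.array([0.5 * (net.vertices[net.vessels[i].v1].position[:2]
                            + net.vertices[net.vessels[i].v2].position[:2])
                    for i in eids])
    if segs:
        dist = _min_dist_to_segments(mids, segs)
        bins = np.floor(dist / spacing).astype(int)
    else:
        dist = np.full(len(eids), np.inf)
        bins = np.full(len(eids), -1)
    classification.dist_to_lmc = {i: float(d) for i, d in zip(eids, dist)}
    classification.dist_bin = {i: int(b) for i, b in zip(eids, bins)}
    return classification.dist_bin


def capillary_border_mask(net: VascularNetwork, max_dist: float = 200.0
                          ) -> dict[int, bool]:
    """True for capillaries farther than ``max_dist`` (planar) from any DA edge.

    Border capillaries are excluded from velocity/flux summary statistics.
    """
    segs = [(net.vertices[e.v1].position[:2].astype(float),
             net.vertices[e.v2].position[:2].astype(float))
            for e in net.vessels_of_type("DA")]
    caps = sorted(e.id for e in net.vessels_of_type("C"))
    mids = np.array([0.5 * (net.vertices[net.vessels[i].v1].position[:2]
                            + net.vertices[net.vessels[i].v2].position[:2])
                    for i in caps])
    dist = _min_dist_to_segments(mids, segs) if len(caps) else np.array([])
    return {i: bool(d > max_dist) for i, d in zip(caps, dist)}


# ----------------------------------------------------------------------- CBF

@dataclass
class CbfSummary:
    """Total network inflow normalised per area, volume and mass.

    Units: flow per surface area in ml/min/mm^2, per tissue volume in
    ml/min/cm^3, per mass in ml/min/100g (tissue density 1046 kg/m^3).
    """

    total_inflow_um3_s: float
    footprint_area_mm2: float
    depth_mm: float
    flow_per_area_ml_min_mm2: float
    flow_per_volume_ml_min_cm3: float
    cbf_ml_min_100g: float


TISSUE_DENSITY_G_CM3 = 1.046


def cbf_summary(net: VascularNetwork, sol: FlowSolution,
                classification: VesselClassification | None = None) -> CbfSummary:
    """Cerebral blood flow metrics from the total inflow at the CoW vertex.

    The surface area is the footprint of the DA-root Voronoi tessellation;
    tissue volume is area times the vascularised depth (max vertex z).
    """
    cow = net.inflow_vertex.id
    q_in = sum(abs(sol.flow_of(e.id)) for e in net.vessels.values()
               if cow in (e.v1, e.v2))
    if classification is not None:
        area_um2 = classification.footprint_area_um2
    else:
        roots = sorted(v.id for v in net.vertices_of_role("da_root"))
        _, hull = _voronoi_cells(net, roots)
        area_um2 = hull.area
    if area_um2 <= 0:
        raise ValueError("zero footprint area")
    depth_um = max(v.position[2] for v in net.vertices.values())
    area_mm2 = area_um2 / 1e6
    q_ml_min = q_in * 60.0 / 1e12
    vol_cm3 = area_mm2 * (depth_um / 1000.0) * 1e-3  # mm^3 -> cm^3
    per_vol = q_ml_min / vol_cm3
    return CbfSummary(
        total_inflow_um3_s=q_in,
        footprint_area_mm2=area_mm2,
        depth_mm=depth_um / 1000.0,
        flow_per_area_ml_min_mm2=q_ml_min / area_mm2,
        flow_per_volume_ml_min_cm3=per_vol,
        cbf_ml_min_100g=per_vol / TISSUE_DENSITY_G_CM3 * 100.0,
    )


# ---------------------------------------------------------- direction changes

def direction_changes(sol_a: FlowSolution, sol_b: FlowSolution,
                      dead_fraction: float = 1e-9) -> set[int]:
    """Edges whose flow sign flipped between two states of the same network.

    Edges with |q| below ``dead_fraction`` of the larger state's maximum
    flow in either state are considered dead and excluded.  States that
    differ by an occlusion split are compared on their common edge ids.
    """
    common = sorted(set(map(int, sol_a.edge_ids)) & set(map(int, sol_b.edge_ids)))
    if not common:
        raise ValueError("solutions share no edges")
    qa = np.array([sol_a.flow_of(e) for e in common])
    qb = np.array([sol_b.flow_of(e) for e in common])
    scale = max(float(np.max(np.abs(qa))), float(np.max(np.abs(qb))))
    tol = dead_fraction * scale
    flipped = (qa * qb < 0) & (np.abs(qa) > tol) & (np.abs(qb) > tol)
    return {e for e, f in zip(common, flipped) if f}
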
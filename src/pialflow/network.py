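"""Core domain types for vascular graphs.

A cortical microvascular network is represented as a geometric graph whose
vertices carry 3D positions (``z`` = cortical depth, 0 at the pial surface,
increasing downward) and whose edges are blood vessels with a diameter, a
hydraulic length and a type annotation.  Vessel types follow the standard
hierarchy of the cortical vasculature: surface (pial) arteries (``SA``),
artificial feeder stubs towards the circle of Willis (``SA_to_CoW``),
leptomeningeal collaterals (``LMC``), descending arteries / penetrating
arteriolar trees (``DA``), capillaries (``C``) and ascending veins (``AV``).

Units are fixed network-wide: micrometre (length, diameter), mmHg
(pressure), mm/s (velocity), um^3/s (flow rate), mPa.s (viscosity).  The
mmHg<->Pa conversion (1 mmHg = 133.322 Pa) is applied only inside the flow
solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

VERTEX_ROLES = ("internal", "cow_inflow", "da_root", "av_root", "tree_leaf")
VESSEL_TYPES = ("SA", "SA_to_CoW", "LMC", "DA", "C", "AV")
SIDES = ("MCA", "ACA", "none")

#: 1 mmHg in Pa, used only by the solver for unit folding.
MMHG_TO_PA = 133.322


@dataclass
class Vertex:
    id: int
    position: np.ndarray  # (3,) um
    role: str = "internal"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"vertex {self.id}: position must be a 3-vector")


@dataclass
class Vessel:
    """One blood vessel (graph edge).

    ``length`` is the hydraulic length and may exceed the Euclidean endpoint
    distance (tortuosity >= 1); only the hydraulic length enters the
    Poiseuille resistance.  ``d_prior`` is the diameter before inverse
    tuning and anchors the per-category box constraints.  ``frozen`` marks
    vessels excluded from tuning, dilation and elastic coupling (e.g. the
    constricted occlusion segment).  ``is_connector`` flags artificial
    plumbing (tree-leaf-to-capillary connectors) so statistics can exclude
    it.
    """

    id: int
    v1: int
    v2: int
    diameter: float  # um
    length: float  # um
    vtype: str = "C"
    side: str = "none"
    has_diameter_measurement: bool = False
    d_prior: float | None = None
    is_connector: bool = False
    frozen: bool = False
    polyline: np.ndarray | None = None

    @property
    def endpoints(self) -> tuple[int, int]:
        return (self.v1, self.v2)


class VascularNetwork:
    """Geometric vessel graph with pressure boundary conditions.

    Parameters
    ----------
    haematocrit : float
        Discharge haematocrit, assumed constant network-wide (default 0.3).
    plasma_viscosity : float
        Plasma viscosity in mPa.s (default 1.2).
    """

    def __init__(self, haematocrit: float = 0.3, plasma_viscosity: float = 1.2):
        self.vertices: dict[int, Vertex] = {}
        self.vessels: dict[int, Vessel] = {}
        self.boundary_conditions: dict[int, float] = {}  # vertex id -> mmHg
        self.haematocrit = float(haematocrit)
        self.plasma_viscosity = float(plasma_viscosity)
        self._next_vertex_id = 0
        self._next_vessel_id = 0

    # ------------------------------------------------------------------ build
    def add_vertex(self, position, role: str = "internal", id: int | None = None) -> Vertex:
        if id is None:
            id = self._next_vertex_id
        if id in self.vertices:
            raise ValueError(f"duplicate vertex id {id}")
        v = Vertex(id=id, position=np.asarray(position, dtype=float), role=role)
        self.vertices[id] = v
        self._next_vertex_id = max(self._next_vertex_id, id + 1)
        return v

    def add_vessel(
        self,
        v1: int,
        v2: int,
        diameter: float,
        length: float | None = None,
        vtype: str = "C",
        side: str = "none",
        id: int | None = None,
        **kw,
    ) -> Vessel:
        if id is None:
            id = self._next_vessel_id
        if id in self.vessels:
            raise ValueError(f"duplicate vessel id {id}")
        if length is None:
            length = self.distance(v1, v2)
        e = Vessel(id=id, v1=v1, v2=v2, diameter=float(diameter), length=float(length),
                   vtype=vtype, side=side, **kw)
        if e.d_prior is None:
            e.d_prior = e.diameter
        self.vessels[id] = e
        self._next_vessel_id = max(self._next_vessel_id, id + 1)
        return e

    def distance(self, v1: int, v2: int) -> float:
        return float(np.linalg.norm(self.vertices[v1].position - self.vertices[v2].position))

    def copy(self) -> "VascularNetwork":
        out = VascularNetwork(self.haematocrit, self.plasma_viscosity)
        for v in self.vertices.values():
            out.vertices[v.id] = Vertex(v.id, v.position.copy(), v.role)
        for e in self.vessels.values():
            out.vessels[e.id] = replace(
                e, polyline=None if e.polyline is None else e.polyline.copy())
        out.boundary_conditions = dict(self.boundary_conditions)
        out._next_vertex_id = self._next_vertex_id
        out._next_vessel_id = self._next_vessel_id
        return out

    # ------------------------------------------------------------- accessors
    def vertices_of_role(self, role: str) -> list[Vertex]:
        return [v for v in self.vertices.values() if v.role == role]

    def vessels_of_type(self, *vtypes: str) -> list[Vessel]:
        return [e for e in self.vessels.values() if e.vtype in vtypes]

    @property
    def inflow_vertex(self) -> Vertex:
        cows = self.vertices_of_role("cow_inflow")
        if len(cows) != 1:
            raise ValueError(f"expected exactly 1 cow_inflow vertex, found {len(cows)}")
        return cows[0]

    def adjacency(self) -> dict[int, list[Vessel]]:
        adj: dict[int, list[Vessel]] = {vid: [] for vid in self.vertices}
        for e in self.vessels.values():
            adj[e.v1].append(e)
            adj[e.v2].append(e)
        return adj

    def to_networkx(self):
        """MultiGraph view with vessel/vertex attributes (for path queries)."""
        import networkx as nx

        g = nx.MultiGraph()
        for v in self.vertices.values():
            g.add_node(v.id, x=v.position[0], y=v.position[1], z=v.position[2], role=v.role)
        for e in self.vessels.values():
            g.add_edge(e.v1, e.v2, key=e.id, id=e.id, diameter=e.diameter,
                       length=e.length, vtype=e.vtype, side=e.side)
        return g

    # ------------------------------------------------------------- mutation
    def split_vessel(self, vessel_id: int, fraction: float, role: str = "internal") -> Vertex:
        """Split a vessel at ``fraction`` of its length into two vessels.

        The new vertex is placed on the straight chord between the
        endpoints; both halves inherit all vessel attributes, with lengths
        (and prior diameters) pro-rated.  Returns the new vertex.
        """
        if not 0.0 < fraction < 1.0:
            raise ValueError("split fraction must be in (0, 1)")
        e = self.vessels[vessel_id]
        p1 = self.vertices[e.v1].position
        p2 = self.vertices[e.v2].position
        v_new = self.add_vertex(p1 + fraction * (p2 - p1), role=role)
        l1 = e.length * fraction
        l2 = e.length * (1.0 - fraction)
        del self.vessels[vessel_id]
        self.add_vessel(e.v1, v_new.id, e.diameter, l1, e.vtype, e.side, id=vessel_id,
                        has_diameter_measurement=e.has_diameter_measurement,
                        d_prior=e.d_prior, is_connector=e.is_connector, frozen=e.frozen)
        self.add_vessel(v_new.id, e.v2, e.diameter, l2, e.vtype, e.side,
                        has_diameter_measurement=e.has_diameter_measurement,
                        d_prior=e.d_prior, is_connector=e.is_connector, frozen=e.frozen)
        return v_new

    def remove_vessel(self, vessel_id: int, drop_isolated: bool = True) -> None:
        e = self.vessels.pop(vessel_id)
        if drop_isolated:
            adj = self.adjacency()
            for vid in (e.v1, e.v2):
                if not adj.get(vid):
                    self.vertices.pop(vid, None)
                    self.boundary_conditions.pop(vid, None)


# ---------------------------------------------------------------- validation

@dataclass
class Violation:
    code: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    def __bool__(self) -> bool:  # truthy iff valid
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def __iter__(self) -> Iterator[Violation]:
        return iter(self.violations)

    def codes(self) -> list[str]:
        return [v.code for v in self.violations]


def validate_network(net: VascularNetwork) -> ValidationReport:
    """Structural validation; violations are reported, never raised."""
    rep = ValidationReport()
    add = lambda code, msg: rep.violations.append(Violation(code, msg))

    for v in net.vertices.values():
        if not np.all(np.isfinite(v.position)):
            add("nonfinite position", f"vertex {v.id} has non-finite position")
        if v.role not in VERTEX_ROLES:
            add("unknown role", f"vertex {v.id} role {v.role!r}")

    n_cow = len(net.vertices_of_role("cow_inflow"))
    if n_cow != 1:
        add("inflow count", f"expected exactly 1 cow_inflow vertex, found {n_cow}")

    for e in net.vessels.values():
        if e.v1 not in net.vertices or e.v2 not in net.vertices:
            add("dangling endpoint", f"vessel {e.id} references a missing vertex")
            continue
        if not e.diameter > 0:
            add("nonpositive diameter", f"vessel {e.id} diameter {e.diameter}")
        if not e.length > 0:
            add("nonpositive length", f"vessel {e.id} length {e.length}")
        chord = net.distance(e.v1, e.v2)
        if e.length < chord * (1.0 - 1e-9) and chord > 0:
            add("length below chord",
                f"vessel {e.id} length {e.length:.3g} < endpoint distance {chord:.3g}")
        if e.vtype not in VESSEL_TYPES:
            add("unknown vtype", f"vessel {e.id} vtype {e.vtype!r}")
        if e.side not in SIDES:
            add("unknown side", f"vessel {e.id} side {e.side!r}")

    for vid in net.boundary_conditions:
        if vid not in net.vertices:
            add("bc on missing vertex", f"boundary condition on absent vertex {vid}")
    for v in net.vertices_of_role("av_root"):
        if v.id not in net.boundary_conditions:
            add("av_root without outflow",
                f"av_root vertex {v.id} carries no outflow boundary condition")

    # connectivity: every boundary vertex must be reachable from the inflow
    if n_cow == 1 and net.vessels:
        adj = net.adjacency()
        seen: set[int] = set()
        stack = [net.inflow_vertex.id]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            for e in adj.get(u, []):
                w = e.v2 if e.v1 == u else e.v1
                if w not in seen:
                    stack.append(w)
        for vid in net.boundary_conditions:
            if vid in net.vertices and vid not in seen:
                add("disconnected boundary",
                    f"boundary vertex {vid} unreachable from the inflow vertex")
    return rep


def category_counts(net: VascularNetwork) -> dict[str, tuple[int, float, float]]:
    """Per vessel type: (edge count, total length um, total volume um^3).

    Volume of one vessel is pi d^2 / 4 * L (cylindrical segment).
    """
    out: dict[str, tuple[int, float, float]] = {}
    for t in VESSEL_TYPES:
        n, ltot, vtot = 0, 0.0, 0.0
        for e in net.vessels.values():
            if e.vtype == t:
                n += 1
                ltot += e.length
                vtot += math.pi * e.diameter**2 / 4.0 * e.length
        out[t] = (n, ltot, vtot)
    return out
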
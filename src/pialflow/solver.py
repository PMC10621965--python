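"""Steady Poiseuille blood flow on a vascular network.

Each vessel is a cylindrical resistor with conductance

    G = pi d^4 / (128 mu_eff L),        mu_eff = mu_p * mu_rel(d, H_D)

and vertex pressures solve the sparse linear Laplacian system expressing
mass conservation at every free vertex under Dirichlet pressure boundary
conditions.  Flows are signed: q > 0 means flow from the lower-id endpoint
towards the higher-id endpoint.  RBC velocity is taken equal to the bulk
mean velocity (phase separation neglected, constant haematocrit).

Unit conventions: d, L in um; pressures in mmHg; q in um^3/s; u in mm/s;
WSS in Pa; viscosities in mPa.s.  The mmHg -> Pa conversion is folded into
the conductance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import MMHG_TO_PA, VascularNetwork
from .viscosity import relative_viscosity, relative_viscosity_derivative

__all__ = ["FlowSolution", "edge_conductance", "solve_flow", "wall_shear_stress",
           "NetworkSystem"]


def edge_conductance(diameter, length, hematocrit: float, plasma_viscosity: float,
                     dialect: str = "in_vitro"):
    """Conductance G in um^3/(s.mmHg); vectorised over edges.

    G = pi d^4 / (128 mu_eff L) with mu_eff in Pa.s and the mmHg->Pa
    conversion folded in, so that q[um^3/s] = G * dp[mmHg].
    """
    d = np.asarray(diameter, dtype=float)
    L = np.asarray(length, dtype=float)
    mu_rel = relative_viscosity(d, hematocrit, dialect)
    mu_eff_pa_s = plasma_viscosity * mu_rel * 1e-3  # mPa.s -> Pa.s
    g = np.pi * d**4 * MMHG_TO_PA / (128.0 * mu_eff_pa_s * L)
    return g if g.ndim else float(g)


def edge_conductance_derivative(diameter, length, hematocrit: float,
                                plasma_viscosity: float, dialect: str = "in_vitro"):
    """dG/dd at fixed length, including the diameter dependence of mu_rel."""
    d = np.asarray(diameter, dtype=float)
    L = np.asarray(length, dtype=float)
    mu = relative_viscosity(d, hematocrit, dialect)
    dmu = relative_viscosity_derivative(d, hematocrit, dialect)
    c0 = np.pi * MMHG_TO_PA / (128.0 * plasma_viscosity * 1e-3 * L)
    out = c0 * (4.0 * d**3 * mu - d**4 * dmu) / mu**2
    return out if out.ndim else float(out)


def wall_shear_stress(q, d, mu_eff):
    """WSS = 32 |q| mu_eff / (pi d^3), parabolic profile; result in Pa.

    q in um^3/s, d in um, mu_eff in mPa.s.
    """
    q = np.abs(np.asarray(q, dtype=float))
    d = np.asarray(d, dtype=float)
    mu = np.asarray(mu_eff, dtype=float) * 1e-3  # mPa.s -> Pa.s
    w = 32.0 * q * mu / (np.pi * d**3)
    return w if w.ndim else float(w)


@dataclass
class FlowSolution:
    """Flow state of one network: per-vertex pressures, per-edge flows.

    Arrays are aligned with ``vertex_ids`` / ``edge_ids``.  Signed flow is
    positive from the lower-id endpoint to the higher-id endpoint.
    """

    vertex_ids: np.ndarray
    pressure: np.ndarray          # mmHg
    edge_ids: np.ndarray
    flow: np.ndarray              # um^3/s, signed
    velocity: np.ndarray          # mm/s, signed
    wss: np.ndarray               # Pa
    effective_viscosity: np.ndarray  # mPa.s

    def __post_init__(self):
        self._vidx = {int(v): i for i, v in enumerate(self.vertex_ids)}
        self._eidx = {int(e): i for i, e in enumerate(self.edge_ids)}

    def pressure_of(self, vertex_id: int) -> float:
        return float(self.pressure[self._vidx[vertex_id]])

    def flow_of(self, edge_id: int) -> float:
        return float(self.flow[self._eidx[edge_id]])

    def velocity_of(self, edge_id: int) -> float:
        return float(self.velocity[self._eidx[edge_id]])

    def edge_index(self, edge_ids) -> np.ndarray:
        return np.array([self._eidx[int(e)] for e in np.atleast_1d(edge_ids)])

    def to_frames(self, net: VascularNetwork):
        """(vertex DataFrame, edge DataFrame) views of the solution."""
        import pandas as pd

        vdf = pd.DataFrame({"id": self.vertex_ids, "pressure_mmHg": self.pressure})
        edf = pd.DataFrame({
            "id": self.edge_ids,
            "flow_um3_s": self.flow,
            "velocity_mm_s": self.velocity,
            "wss_Pa": self.wss,
            "mu_eff_mPa_s": self.effective_viscosity,
        })
        return vdf, edf


class NetworkSystem:
    """Index/array view of a network for repeated linear solves.

    Extracted once, then re-solved for different diameter vectors (the
    inverse model and the elastic fixed point both iterate on diameters
    without changing the topology).
    """

    def __init__(self, net: VascularNetwork, dialect: str = "in_vitro"):
        self.net = net
        self.dialect = dialect
        self.hematocrit = net.haematocrit
        self.plasma_viscosity = net.plasma_viscosity

        self.vertex_ids = np.array(sorted(net.vertices), dtype=int)
        vidx = {int(v): i for i, v in enumerate(self.vertex_ids)}
        self.edge_ids = np.array(sorted(net.vessels), dtype=int)
        edges = [net.vessels[int(e)] for e in self.edge_ids]
        # orient a -> b with id(a) < id(b): sign convention for q
        a = np.array([min(e.v1, e.v2) for e in edges], dtype=int)
        b = np.array([max(e.v1, e.v2) for e in edges], dtype=int)
        self.ia = np.array([vidx[x] for x in a])
        self.ib = np.array([vidx[x] for x in b])
        self.diameters = np.array([e.diameter for e in edges], dtype=float)
        self.lengths = np.array([e.length for e in edges], dtype=float)
        self.vtypes = np.array([e.vtype for e in edges])

        nv = len(self.vertex_ids)
        self.bc_mask = np.zeros(nv, dtype=bool)
        self.bc_values = np.zeros(nv)
        for vid, p in net.boundary_conditions.items():
            self.bc_mask[vidx[vid]] = True
            self.bc_values[vidx[vid]] = p
        self.free = np.flatnonzero(~self.bc_mask)
        self.free_pos = -np.ones(nv, dtype=int)
        self.free_pos[self.free] = np.arange(len(self.free))
        if not self.bc_mask.any():
            raise ValueError("network has no pressure boundary conditions")
        self._check_bc_connectivity()

    def _check_bc_connectivity(self):
        """Every vertex must reach a Dirichlet vertex, else the system is singular."""
        nv = len(self.vertex_ids)
        adj: list[list[int]] = [[] for _ in range(nv)]
        for i, j in zip(self.ia, self.ib):
            adj[i].append(j)
            adj[j].append(i)
        seen = self.bc_mask.copy()
        stack = list(np.flatnonzero(self.bc_mask))
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        if not seen.all():
            orphan = self.vertex_ids[~seen]
            raise RuntimeError(
                "singular pressure system: component containing vertices "
                f"{orphan[:5].tolist()} is not connected to any boundary condition")

    # ------------------------------------------------------------------ core
    def conductances(self, d: np.ndarray | None = None) -> np.ndarray:
        d = self.diameters if d is None else d
        return edge_conductance(d, self.lengths, self.hematocrit,
                                self.plasma_viscosity, self.dialect)

    def assemble(self, g: np.ndarray):
        """Reduced SPD system (A, rhs) for the free-vertex pressures."""
        nfree = len(self.free)
        fa, fb = self.free_pos[self.ia], self.free_pos[self.ib]
        rows, cols, vals = [], [], []
        rhs = np.zeros(nfree)
        both = (fa >= 0) & (fb >= 0)
        rows.append(fa[both]); cols.append(fb[both]); vals.append(-g[both])
        rows.append(fb[both]); cols.append(fa[both]); vals.append(-g[both])
        for fi, other_bc, other_val in (
                (fa, self.bc_mask[self.ib], self.bc_values[self.ib]),
                (fb, self.bc_mask[self.ia], self.bc_values[self.ia])):
            m = fi >= 0
            rows.append(fi[m]); cols.append(fi[m]); vals.append(g[m])
            mb = m & other_bc
            np.add.at(rhs, fi[mb], g[mb] * other_val[mb])
        rows = np.concatenate(rows); cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        a = sp.coo_matrix((vals, (rows, cols)), shape=(nfree, nfree)).tocsc()
        return a, rhs

    def solve_pressures(self, d: np.ndarray | None = None) -> np.ndarray:
        """Full pressure vector (mmHg) aligned with ``vertex_ids``."""
        g = self.conductances(d)
        a, rhs = self.assemble(g)
        try:
            lu = spla.splu(a)
        except RuntimeError as exc:  # singular factor
            raise RuntimeError(
                "singular pressure system: a network component is not connected "
                "to any boundary condition") from exc
        p_free = lu.solve(rhs)
        if not np.all(np.isfinite(p_free)):
            raise RuntimeError(
                "singular pressure system: a network component is not connected "
                "to any boundary condition")
        p = self.bc_values.copy()
        p[self.free] = p_free
        return p

    def solution_from_pressures(self, p: np.ndarray, d: np.ndarray | None = None) -> FlowSolution:
        d = self.diameters if d is None else d
        g = self.conductances(d)
        q = g * (p[self.ia] - p[self.ib])
        area = np.pi * d**2 / 4.0
        u = q / area / 1000.0  # um/s -> mm/s
        mu_eff = self.plasma_viscosity * relative_viscosity(d, self.hematocrit, self.dialect)
        w = wall_shear_stress(q, d, mu_eff)
        return FlowSolution(self.vertex_ids.copy(), p, self.edge_ids.copy(),
                            q, u, w, np.asarray(mu_eff, dtype=float))

    def solve(self, d: np.ndarray | None = None) -> FlowSolution:
        p = self.solve_pressures(d)
        return self.solution_from_pressures(p, d)


def solve_flow(net: VascularNetwork, dialect: str = "in_vitro") -> FlowSolution:
    """Solve the steady pressure/flow field of ``net``.

    Raises if the network lacks boundary conditions or contains a component
    with boundary conditions that is disconnected from the rest.
    """
    return NetworkSystem(net, dialect=dialect).solve()


def mass_residuals(net: VascularNetwork, sol: FlowSolution) -> np.ndarray:
    """Signed net outflow at every interior (non-BC) vertex, um^3/s.

    Used by tests to verify conservation; at interior vertices the residual
    should vanish relative to the local flow scale.
    """
    sys_ = NetworkSystem(net)
    res = np.zeros(len(sol.vertex_ids))
    np.add.at(res, sys_.ia, sol.flow)       # q > 0 leaves the lower-id endpoint
    np.subtract.at(res, sys_.ib, sol.flow)  # and arrives at the higher-id endpoint
    return res[sys_.free]
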
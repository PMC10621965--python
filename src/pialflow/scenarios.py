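"""Perturbation states: MCA occlusion, collateral/arterial dilation, elasticity.

All transforms are pure — they return a modified copy and never mutate the
input network — so a scenario is reproducible from (network, state, seed).

The four canonical states are:

* ``Base``               — the tuned network, untouched.
* ``MCAo``               — a 50 um segment of the MCA feeder, upstream of
  the pial network, constricted to 10% of its baseline diameter.
* ``MCAo_LMC_dil``       — MCAo plus dilation of every LMC (uniform factor
  1.7 when no per-vessel measurement is available).
* ``MCAo_LMC_SA_DA_dil`` — additionally all SAs and DAs dilated by 10%
  (a simplified stand-in for autoregulation / therapeutic vasodilation).

Passive diameter changes due to pressure alterations can be superimposed on
any state through a linear pressure-area (tube-law) coupling solved by
fixed-point iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import VascularNetwork
from .solver import FlowSolution, NetworkSystem, solve_flow

__all__ = ["ScenarioState", "ElasticityParams", "apply_mcao", "apply_dilation",
           "elastic_coupled_solve", "elastic_reference", "remove_lmcs", "add_lmcs",
           "build_state", "STATE_NAMES"]

STATE_NAMES = ("Base", "MCAo", "MCAo_LMC_dil", "MCAo_LMC_SA_DA_dil")


@dataclass
class ScenarioState:
    """A named diameter-modification recipe."""

    name: str = "MCAo"
    occlusion_edge: int | None = None
    occlusion_length: float = 50.0       # um
    occlusion_residual: float = 0.10     # fraction of baseline diameter
    lmc_dilation: float | dict[int, float] = 1.7
    arterial_dilation_fraction: float = 0.10
    elasticity_enabled: bool = False

    def __post_init__(self):
        if self.name not in STATE_NAMES:
            raise ValueError(f"unknown state {self.name!r}; expected one of {STATE_NAMES}")
        if not 0.0 < self.occlusion_residual <= 1.0:
            raise ValueError("occlusion residual fraction must be in (0, 1]")


# ------------------------------------------------------------------ occlusion

def apply_mcao(net: VascularNetwork, state: ScenarioState) -> VascularNetwork:
    """Constrict a 50 um sub-segment of the MCA feeder to 10% diameter.

    The occluded segment is split out of the host edge (preserving the
    stated segment geometry), frozen (excluded from tuning, dilation and
    elastic coupling), and its diameter set to ``residual * baseline``.
    Raises if the edge is not on the MCA side.
    """
    if state.occlusion_edge is None:
        raise ValueError("ScenarioState.occlusion_edge is not set")
    out = net.copy()
    e = out.vessels.get(state.occlusion_edge)
    if e is None:
        raise KeyError(f"occlusion edge {state.occlusion_edge} not in network")
    if e.side != "MCA":
        raise ValueError(
            f"occlusion edge {state.occlusion_edge} is on side {e.side!r}, not MCA")
    seg_len = state.occlusion_length
    if e.length > seg_len:
        # split out a centred sub-segment of the requested length
        f0 = 0.5 - 0.5 * seg_len / e.length
        mid1 = out.split_vessel(e.id, f0)
        # after the first split the distal part keeps a new id
        distal = [ed for ed in out.adjacency()[mid1.id] if ed.id != e.id][0]
        out.split_vessel(distal.id, seg_len / distal.length)
        seg = [ed for ed in out.adjacency()[mid1.id] if ed.id != e.id][0]
    else:
        seg = e
    seg.diameter = state.occlusion_residual * seg.diameter
    seg.frozen = True
    return out


def occluded_segments(net: VascularNetwork) -> list[int]:
    return [e.id for e in net.vessels.values() if e.frozen]


# ------------------------------------------------------------------- dilation

def apply_dilation(net: VascularNetwork, selection, factor) -> VascularNetwork:
    """Multiply selected diameters by a factor.

    ``selection`` is a set of vessel types or an explicit iterable of edge
    ids; ``factor`` a scalar or an edge-id -> factor map.  Frozen (occluded)
    segments are never dilated.  An empty selection is a warned no-op.
    """
    out = net.copy()
    if selection and all(isinstance(s, str) for s in selection):
        ids = [e.id for e in out.vessels.values() if e.vtype in set(selection)]
    else:
        ids = list(selection)
    ids = [i for i in ids if not out.vessels[i].frozen]
    if not ids:
        warnings.warn("dilation selection is empty; network unchanged")
        return out
    for i in ids:
        f = factor.get(i, 1.0) if isinstance(factor, dict) else float(factor)
        if f <= 0:
            raise ValueError(f"dilation factor for edge {i} must be positive")
        out.vessels[i].diameter *= f
    return out


def build_state(net: VascularNetwork, state: ScenarioState) -> VascularNetwork:
    """Apply the full diameter recipe of a named state to a Base network."""
    if state.name == "Base":
        return net.copy()
    out = apply_mcao(net, state)
    if state.name == "MCAo":
        return out
    lmc_ids = [e.id for e in out.vessels_of_type("LMC")]
    out = apply_dilation(out, lmc_ids, state.lmc_dilation) if lmc_ids else out
    if state.name == "MCAo_LMC_dil":
        return out
    return apply_dilation(out, {"SA", "DA"}, 1.0 + state.arterial_dilation_fraction)


# ----------------------------------------------------------------- elasticity

@dataclass
class ElasticityParams:
    """Linear pressure-diameter coupling around a reference (Base) state.

    ``compliance`` is the fractional diameter change per mmHg of midpoint
    pressure deviation from baseline, per vessel type.  The default value
    keeps passive constrictions after an MCA occlusion below ~10%.
    """

    compliance: dict[str, float] = field(default_factory=lambda: {
        "SA": 1e-3, "SA_to_CoW": 1e-3, "LMC": 1e-3, "DA": 1e-3, "C": 1e-3, "AV": 1e-3})
    reference_pressure: dict[int, float] = field(default_factory=dict)  # edge -> mmHg
    reference_diameter: dict[int, float] = field(default_factory=dict)  # edge -> um
    max_iterations: int = 50
    tolerance: float = 1e-8  # max relative diameter change


def elastic_reference(net: VascularNetwork, sol: FlowSolution,
                      compliance: dict[str, float] | float | None = None
                      ) -> ElasticityParams:
    """Build ElasticityParams from a solved Base state."""
    params = ElasticityParams()
    if isinstance(compliance, (int, float)):
        params.compliance = {t: float(compliance) for t in params.compliance}
    elif compliance is not None:
        params.compliance.update(compliance)
    for e in net.vessels.values():
        p_mid = 0.5 * (sol.pressure_of(e.v1) + sol.pressure_of(e.v2))
        params.reference_pressure[e.id] = p_mid
        params.reference_diameter[e.id] = e.diameter
    return params


def elastic_coupled_solve(net: VascularNetwork, params: ElasticityParams,
                          dialect: str = "in_vitro"):
    """Fixed-point iteration of the pressure-diameter coupling.

    Each elastic edge's diameter follows
    ``d = d_state * (1 + c * (p_mid - p_mid_base))`` where ``d_state`` is the
    edge's diameter in the current scenario state (so prescribed dilations
    are preserved) and the pressure deviation is measured from the Base
    reference.  Returns ``(network with passive diameters, FlowSolution)``.
    """
    out = net.copy()
    sys_ = NetworkSystem(out, dialect=dialect)
    d_state = sys_.diameters.copy()
    comp = np.array([0.0 if out.vessels[int(i)].frozen
                     else params.compliance.get(out.vessels[int(i)].vtype, 0.0)
                     for i in sys_.edge_ids])
    p_base = np.array([params.reference_pressure.get(int(i), np.nan)
                       for i in sys_.edge_ids])
    known = np.isfinite(p_base)

    d = d_state.copy()
    residuals = []
    for _ in range(params.max_iterations):
        p = sys_.solve_pressures(d)
        p_mid = 0.5 * (p[sys_.ia] + p[sys_.ib])
        d_new = d.copy()
        d_new[known] = d_state[known] * (1.0 + comp[known] * (p_mid[known] - p_base[known]))
        d_new = np.maximum(d_new, 0.05 * d_state)
        change = float(np.max(np.abs(d_new - d) / np.maximum(d, 1e-12)))
        residuals.append(change)
        d = d_new
        if change < params.tolerance:
            break
    else:
        raise RuntimeError(
            f"elastic coupling did not converge in {params.max_iterations} iterations; "
            f"residual history tail {residuals[-5:]}")
    for i, eid in enumerate(sys_.edge_ids):
        out.vessels[int(eid)].diameter = float(d[i])
    return out, sys_.solve(d)


# ------------------------------------------------------- LMC removal/addition

def remove_lmcs(net: VascularNetwork, keep_fraction: float,
                rng: np.random.Generator) -> VascularNetwork:
    """Keep a random ``round(keep_fraction * n)`` subset of the LMCs."""
    out = net.copy()
    lmc_ids = sorted(e.id for e in out.vessels_of_type("LMC"))
    if keep_fraction >= 1.0 or not lmc_ids:
        return out
    n_keep = int(round(keep_fraction * len(lmc_ids)))
    keep = set(rng.choice(lmc_ids, size=n_keep, replace=False).tolist()) if n_keep else set()
    for eid in lmc_ids:
        if eid not in keep:
            out.remove_vessel(eid)
    return out


def add_lmcs(net: VascularNetwork, target_count: int, rng: np.random.Generator,
             spacing_min: float = 310.0, length_max: float = 1000.0,
             diameter_median: float = 12.0, diameter_sigma: float = 0.15,
             tortuosity: float = 1.2, sides=None) -> VascularNetwork:
    """Sequentially sample new collaterals across the watershed line.

    Candidates connect a random MCA-side pial vertex to the closest
    ACA-side pial vertex; a candidate is accepted iff its distance to every
    existing LMC exceeds ``spacing_min`` and its chord is at most
    ``length_max``.  Diameters are drawn log-normally.  ``sides`` maps
    vertex id -> side for the pial vertices (derived from incident SA edges
    when omitted).  Returns what could be placed, warning if the target is
    infeasible under the spacing rule.
    """
    out = net.copy()
    if target_count <= 0:
        return out
    if sides is None:
        sides = {}
        for e in out.vessels_of_type("SA"):
            for vid in (e.v1, e.v2):
                sides.setdefault(vid, e.side)
    mca = [v for v in sorted(sides) if sides[v] == "MCA" and v in out.vertices]
    aca = [v for v in sorted(sides) if sides[v] == "ACA" and v in out.vertices]
    if not mca or not aca:
        raise ValueError("need pial vertices on both sides to add LMCs")
    aca_pos = np.array([out.vertices[v].position[:2] for v in aca])

    def lmc_midpoints():
        return [0.5 * (out.vertices[e.v1].position[:2] + out.vertices[e.v2].position[:2])
                for e in out.vessels_of_type("LMC")]

    placed = 0
    candidates = list(mca)
    rng.shuffle(candidates)
    for v in candidates:
        if placed >= target_count:
            break
        p = out.vertices[v].position[:2]
        j = int(np.argmin(np.linalg.norm(aca_pos - p, axis=1)))
        w = aca[j]
        chord = out.distance(v, w)
        if chord > length_max:
            continue
        mid = 0.5 * (p + aca_pos[j])
        if any(np.linalg.norm(mid - m) <= spacing_min for m in lmc_midpoints()):
            continue
        d = diameter_median * float(np.exp(rng.normal(0.0, diameter_sigma)))
        out.add_vessel(v, w, d, chord * tortuosity, "LMC", "none")
        placed += 1
    if placed < target_count:
        warnings.warn(f"placed only {placed}/{target_count} LMCs under the "
                      f"{spacing_min} um spacing rule")
    return out
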
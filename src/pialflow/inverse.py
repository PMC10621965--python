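"""Inverse model: tune vessel diameters to sparse RBC-velocity constraints.

Sparse in vivo velocity data enter as per-edge constraints of two kinds:
a precise target value (measured vessels) or an admissible range (literature
priors for DA and AV roots).  The misfit is a sum of one-sided parabolas,
zero at the target or inside the range.  Because the solved velocity of one
edge depends on every diameter through the pressure field, the gradient of
the misfit with respect to all diameters is obtained with the adjoint
method: one extra linear solve of the (transposed, here symmetric) pressure
system per gradient evaluation, instead of one forward solve per parameter.

Diameters are box-constrained relative to their prior values with
per-category half-widths (default 5% for measured SAs, 20% for unmeasured
pial vessels, 50% for everything else).  The solution is ambiguous — many
diameter fields reach zero cost — so only the cost, not the diameters, is a
reproducible quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import VascularNetwork
from .solver import (FlowSolution, NetworkSystem, edge_conductance,
                     edge_conductance_derivative)

__all__ = ["VelocityConstraint", "TuningOptions", "constraint_cost", "total_cost",
           "cost_gradient_adjoint", "tune_diameters",
           "da_root_range_constraints", "av_root_range_constraints"]

PIAL_TYPES = ("SA", "SA_to_CoW", "LMC")

#: literature velocity ranges (mm/s) for the most upstream DA / AV segments
DA_ROOT_RANGE = (2.0, 10.0)
AV_ROOT_RANGE = (0.4, 2.0)
#: fallback target for LMCs without their own measurement (median of
#: measured LMC velocities is preferred when any exist)
LMC_DEFAULT_TARGET = 0.53


@dataclass
class VelocityConstraint:
    """Target value or admissible range for |u| (mm/s) on one edge."""

    edge_id: int
    kind: str  # "target" | "range"
    u_meas: float | None = None
    u_min: float | None = None
    u_max: float | None = None
    weight: float = 1.0

    def __post_init__(self):
        if self.kind == "target":
            if self.u_meas is None or self.u_meas <= 0:
                raise ValueError(f"target constraint on edge {self.edge_id} needs u_meas > 0")
        elif self.kind == "range":
            if self.u_min is None or self.u_max is None or not 0 < self.u_min < self.u_max:
                raise ValueError(f"range constraint on edge {self.edge_id} needs 0 < u_min < u_max")
        else:
            raise ValueError(f"unknown constraint kind {self.kind!r}")

    @property
    def scale(self) -> float:
        """Velocity scale used for optional cost normalization."""
        return self.u_meas if self.kind == "target" else 0.5 * (self.u_min + self.u_max)


@dataclass
class TuningOptions:
    """Optimizer settings and per-category diameter bound fractions."""

    beta_sa_measured: float = 0.05
    beta_sa_unmeasured: float = 0.20
    beta_other: float = 0.50
    max_iterations: int = 500
    cost_tolerance: float = 1e-10
    normalize: bool = True
    method: str = "lbfgsb"  # or "pgd"
    pgd_step_init: float = 1.0
    pgd_step_grow: float = 1.6
    pgd_step_shrink: float = 0.4
    rng_seed: int = 0

    def __post_init__(self):
        for b in (self.beta_sa_measured, self.beta_sa_unmeasured, self.beta_other):
            if not 0.0 < b < 1.0:
                raise ValueError("bound fractions must be in (0, 1)")


# ----------------------------------------------------------------- the cost

def constraint_cost(u: float, c: VelocityConstraint, normalize: bool = True
                    ) -> tuple[float, float]:
    """(cost, dcost/du) of one constraint at signed velocity ``u`` (mm/s).

    The magnitude |u| is compared to the target/range; the derivative is
    continuous and vanishes on the zero-cost set.
    """
    w = c.weight / (c.scale**2 if normalize else 1.0)
    au = abs(u)
    lo = c.u_meas if c.kind == "target" else c.u_min
    hi = c.u_meas if c.kind == "target" else c.u_max
    if au < lo:
        r = au - lo
    elif au > hi:
        r = au - hi
    else:
        return 0.0, 0.0
    sign = 1.0 if u > 0 else (-1.0 if u < 0 else 0.0)
    return w * r * r, 2.0 * w * r * sign


class _ConstraintSet:
    """Vectorised view of a constraint list against a NetworkSystem."""

    def __init__(self, sys_: NetworkSystem, constraints, normalize: bool):
        eidx = {int(e): i for i, e in enumerate(sys_.edge_ids)}
        try:
            self.ce = np.array([eidx[c.edge_id] for c in constraints], dtype=int)
        except KeyError as exc:
            raise KeyError(f"constraint on missing edge {exc.args[0]}") from None
        self.lo = np.array([c.u_meas if c.kind == "target" else c.u_min
                            for c in constraints])
        self.hi = np.array([c.u_meas if c.kind == "target" else c.u_max
                            for c in constraints])
        self.w = np.array([c.weight / (c.scale**2 if normalize else 1.0)
                           for c in constraints])

    def cost_and_dJdu(self, u_edges: np.ndarray):
        u = u_edges[self.ce]
        au = np.abs(u)
        r = np.where(au < self.lo, au - self.lo, np.where(au > self.hi, au - self.hi, 0.0))
        cost = float(np.sum(self.w * r * r))
        djdu = 2.0 * self.w * r * np.sign(u)
        return cost, djdu


def total_cost(net: VascularNetwork, sol: FlowSolution, constraints,
               normalize: bool = True) -> float:
    """Sum of constraint costs over all constraints; 0 iff all satisfied."""
    for c in constraints:
        if c.edge_id not in net.vessels:
            raise KeyError(f"constraint on missing edge {c.edge_id}")
    return sum(constraint_cost(sol.velocity_of(c.edge_id), c, normalize)[0]
               for c in constraints)


# ------------------------------------------------------------ adjoint gradient

def _cost_and_gradient(sys_: NetworkSystem, cs: _ConstraintSet, d: np.ndarray
                       ) -> tuple[float, np.ndarray, FlowSolution]:
    """Misfit and its full diameter gradient via one forward + one adjoint solve."""
    import scipy.sparse.linalg as spla

    g = sys_.conductances(d)
    a_mat, rhs = sys_.assemble(g)
    lu = spla.splu(a_mat)
    p = sys_.bc_values.copy()
    p[sys_.free] = lu.solve(rhs)
    sol = sys_.solution_from_pressures(p, d)

    cost, djdu = cs.cost_and_dJdu(sol.velocity)
    if not np.isfinite(cost):
        bad = cs.ce[~np.isfinite(sol.velocity[cs.ce])]
        raise FloatingPointError(
            f"non-finite cost; offending constrained edge index {bad[:5].tolist()}")

    area = np.pi * d**2 / 4.0
    coeff = g / (area * 1000.0)          # du/d(p_a - p_b)
    dp = p[sys_.ia] - p[sys_.ib]

    # adjoint rhs: dJ/dp at free vertices
    nfree = len(sys_.free)
    rhs_adj = np.zeros(nfree)
    fa = sys_.free_pos[sys_.ia[cs.ce]]
    fb = sys_.free_pos[sys_.ib[cs.ce]]
    contrib = djdu * coeff[cs.ce]
    m = fa >= 0
    np.add.at(rhs_adj, fa[m], contrib[m])
    m = fb >= 0
    np.add.at(rhs_adj, fb[m], -contrib[m])
    lam_free = lu.solve(rhs_adj)         # A symmetric: A^T = A
    lam = np.zeros(len(sys_.vertex_ids))
    lam[sys_.free] = lam_free

    dgdd = edge_conductance_derivative(d, sys_.lengths, sys_.hematocrit,
                                       sys_.plasma_viscosity, sys_.dialect)
    grad = -(lam[sys_.ia] - lam[sys_.ib]) * dgdd * dp
    # direct dependence of the constrained velocities on their own diameter
    dcoeff = dgdd / (area * 1000.0) - g * (np.pi * d / 2.0) / (area**2 * 1000.0)
    np.add.at(grad, cs.ce, djdu * dp[cs.ce] * dcoeff[cs.ce])
    return cost, grad, sol


def cost_gradient_adjoint(net: VascularNetwork, sol: FlowSolution, constraints,
                          normalize: bool = True, dialect: str = "in_vitro"
                          ) -> np.ndarray:
    """d(total cost)/d(diameter) for every edge, aligned with sorted edge ids.

    Accounts for both the direct dependence of the constrained velocities on
    their own diameter and the indirect dependence of all velocities on the
    pressure field.  ``sol`` is accepted for interface symmetry; the state
    is recomputed internally from the network's current diameters.
    """
    sys_ = NetworkSystem(net, dialect=dialect)
    cs = _ConstraintSet(sys_, list(constraints), normalize)
    _, grad, _ = _cost_and_gradient(sys_, cs, sys_.diameters)
    return grad


# ------------------------------------------------------------------- tuning

def _bounds_for(sys_: NetworkSystem, net: VascularNetwork, opts: TuningOptions):
    lo = np.empty(len(sys_.edge_ids))
    hi = np.empty(len(sys_.edge_ids))
    for i, eid in enumerate(sys_.edge_ids):
        e = net.vessels[int(eid)]
        prior = e.d_prior if e.d_prior is not None else e.diameter
        if e.frozen:
            lo[i] = hi[i] = e.diameter
            continue
        if e.vtype in PIAL_TYPES:
            beta = (opts.beta_sa_measured if e.has_diameter_measurement
                    else opts.beta_sa_unmeasured)
        else:
            beta = opts.beta_other
        lo[i] = (1.0 - beta) * prior
        hi[i] = (1.0 + beta) * prior
    return lo, hi


def tune_diameters(net: VascularNetwork, constraints, opts: TuningOptions | None = None,
                   dialect: str = "in_vitro"):
    """Minimise the velocity-misfit over box-constrained diameters.

    Returns ``(tuned network, history)`` where history is a list of dicts
    with keys iteration / cost / max_rel_step.  The cost is non-increasing
    across accepted iterates and every diameter stays inside its category
    box around ``d_prior``.
    """
    opts = opts or TuningOptions()
    constraints = list(constraints)
    sys_ = NetworkSystem(net, dialect=dialect)
    cs = _ConstraintSet(sys_, constraints, opts.normalize)
    lo, hi = _bounds_for(sys_, net, opts)
    d0 = np.clip(sys_.diameters.copy(), lo, hi)
    history: list[dict] = []

    if opts.method == "lbfgsb":
        d_final, history = _tune_lbfgsb(sys_, cs, d0, lo, hi, opts)
    elif opts.method == "pgd":
        d_final, history = _tune_pgd(sys_, cs, d0, lo, hi, opts)
    else:
        raise ValueError(f"unknown tuning method {opts.method!r}")

    tuned = net.copy()
    for i, eid in enumerate(sys_.edge_ids):
        tuned.vessels[int(eid)].diameter = float(d_final[i])
    return tuned, history


def _tune_lbfgsb(sys_, cs, d0, lo, hi, opts):
    from scipy.optimize import minimize

    history = []
    prev = {"d": d0.copy()}

    def fun(d):
        cost, grad, _ = _cost_and_gradient(sys_, cs, d)
        return cost, grad

    def cb(dk):
        step = float(np.max(np.abs(dk - prev["d"]) / np.maximum(prev["d"], 1e-12)))
        cost, _, _ = _cost_and_gradient(sys_, cs, dk)
        history.append({"iteration": len(history) + 1, "cost": cost,
                        "max_rel_step": step})
        prev["d"] = dk.copy()

    c0, _, _ = _cost_and_gradient(sys_, cs, d0)
    history.append({"iteration": 0, "cost": c0, "max_rel_step": 0.0})
    if c0 <= opts.cost_tolerance:
        return d0, history
    res = minimize(fun, d0, jac=True, method="L-BFGS-B",
                   bounds=np.stack([lo, hi], axis=1),
                   options={"maxiter": opts.max_iterations,
                            "ftol": 0.0, "gtol": 0.0, "maxls": 40},
                   callback=cb)
    d = np.clip(res.x, lo, hi)
    cost, _, _ = _cost_and_gradient(sys_, cs, d)
    if history and cost > history[-1]["cost"]:
        # keep the best iterate seen (scipy may return the last, not best)
        d = prev["d"]
    return d, history


def _tune_pgd(sys_, cs, d0, lo, hi, opts):
    """Projected gradient descent with backtracking (Armijo) line search."""
    d = d0.copy()
    cost, grad, _ = _cost_and_gradient(sys_, cs, d)
    history = [{"iteration": 0, "cost": cost, "max_rel_step": 0.0}]
    gnorm = float(np.max(np.abs(grad))) or 1.0
    alpha = opts.pgd_step_init * 0.01 * float(np.median(d)) / gnorm
    for it in range(1, opts.max_iterations + 1):
        if cost <= opts.cost_tolerance:
            break
        accepted = False
        for _ in range(40):
            d_new = np.clip(d - alpha * grad, lo, hi)
            step_vec = d - d_new
            if not np.any(step_vec):
                break
            cost_new, grad_new, _ = _cost_and_gradient(sys_, cs, d_new)
            if cost_new <= cost - 1e-4 * float(grad @ step_vec):
                accepted = True
                break
            alpha *= opts.pgd_step_shrink
        if not accepted:
            break
        step = float(np.max(np.abs(d_new - d) / np.maximum(d, 1e-12)))
        d, cost, grad = d_new, cost_new, grad_new
        history.append({"iteration": it, "cost": cost, "max_rel_step": step})
        alpha *= opts.pgd_step_grow
    return d, history


# -------------------------------------------------- standard root constraints

def _root_edges(net: VascularNetwork, role: str, vtype: str) -> list[int]:
    """Ids of the tree edges incident to surface roots of the given role."""
    adj = net.adjacency()
    out = []
    for v in sorted(net.vertices_of_role(role), key=lambda v: v.id):
        tree_edges = [e for e in adj[v.id] if e.vtype == vtype]
        out.extend(e.id for e in tree_edges)
    return out


def da_root_range_constraints(net: VascularNetwork) -> list[VelocityConstraint]:
    """Range 2-10 mm/s on every most-upstream DA (DA root) edge."""
    return [VelocityConstraint(eid, "range", u_min=DA_ROOT_RANGE[0], u_max=DA_ROOT_RANGE[1])
            for eid in _root_edges(net, "da_root", "DA")]


def av_root_range_constraints(net: VascularNetwork) -> list[VelocityConstraint]:
    """Range 0.4-2 mm/s on every AV edge at the outflow boundaries."""
    return [VelocityConstraint(eid, "range", u_min=AV_ROOT_RANGE[0], u_max=AV_ROOT_RANGE[1])
            for eid in _root_edges(net, "av_root", "AV")]
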
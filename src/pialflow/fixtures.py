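"""Seeded synthetic pial topologies and sparse measurements.

The case-specific pial reconstructions the method was developed on are
not available as machine-readable data, so this module generates a
structurally equivalent stand-in: two surface-artery trees fed by an MCA
and an ACA feeder branch from a single circle-of-Willis inflow, facing
each other across a watershed line and optionally connected by
leptomeningeal collaterals (LMCs).  Sparse, noisy velocity "measurements"
are synthesised from a solved reference state so that inverse-model
recovery can be tested against known ground truth.

Everything is deterministic per seed.  All fixture data are synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .generation import GenerationConfig, build_network
from .inverse import (LMC_DEFAULT_TARGET, VelocityConstraint,
                      av_root_range_constraints, da_root_range_constraints)
from .network import VascularNetwork
from .solver import FlowSolution

__all__ = ["FixtureConfig", "synth_pial", "synth_measurements", "default_fixture"]


@dataclass
class FixtureConfig:
    """Geometry and measurement parameters of the synthetic pial fixture."""

    footprint_mm: tuple[float, float] = (1.0, 1.0)
    n_sa_per_side: int = 6
    lmc_count: int = 3
    sa_diameter_range: tuple[float, float] = (16.0, 38.0)
    lmc_diameter_median: float = 4.5
    lmc_diameter_sigma: float = 0.15   # log-normal spread
    feeder_diameter: float = 42.0
    feeder_length: float = 1500.0      # hydraulic length of each SA-to-CoW stub
    sa_tortuosity: float = 1.1
    lmc_tortuosity: float = 1.2
    measurement_fraction: float = 0.4
    velocity_noise_sd: float = 0.10    # multiplicative (log-normal sigma)
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.measurement_fraction <= 1.0:
            raise ValueError("measurement_fraction must be in [0, 1]")
        if self.n_sa_per_side < 2 or self.lmc_count < 0:
            raise ValueError("need n_sa_per_side >= 2 and lmc_count >= 0")


def synth_pial(cfg: FixtureConfig, rng: np.random.Generator) -> VascularNetwork:
    """Two SA trees (MCA left, ACA right) joined at a single CoW inflow.

    LMC edges span the midline between facing branch tips, honouring the
    placement rules used for collateral addition (pairwise spacing > 310 um,
    length <= 1000 um).  With ``lmc_count`` = 0 the two trees touch only at
    the CoW vertex.
    """
    w = cfg.footprint_mm[0] * 1000.0
    h = cfg.footprint_mm[1] * 1000.0
    d_hi, d_lo = max(cfg.sa_diameter_range), min(cfg.sa_diameter_range)
    net = VascularNetwork()
    cow = net.add_vertex((0.5 * w, -90.0, 0.0), role="cow_inflow")

    inner_tips: dict[str, list[tuple[int, float]]] = {"MCA": [], "ACA": []}
    for side, x_feed, x_trunk, x_inner, x_outer in (
            ("MCA", 0.08 * w, 0.22 * w, 0.44 * w, 0.05 * w),
            ("ACA", 0.92 * w, 0.78 * w, 0.56 * w, 0.95 * w)):
        feeder = net.add_vertex((x_feed, -30.0, 0.0))
        net.add_vessel(cow.id, feeder.id, cfg.feeder_diameter, cfg.feeder_length,
                       "SA_to_CoW", side)
        ys = np.linspace(0.08 * h, 0.92 * h, cfg.n_sa_per_side)
        prev = feeder.id
        for k, y in enumerate(ys):
            frac = k / max(cfg.n_sa_per_side - 1, 1)
            d_trunk = d_hi - (d_hi - d_lo) * 0.55 * frac
            node = net.add_vertex((x_trunk + rng.uniform(-0.02, 0.02) * w,
                                   y + rng.uniform(-15.0, 15.0), 0.0))
            chord = max(net.distance(prev, node.id), 1.0)
            net.add_vessel(prev, node.id, d_trunk, chord * cfg.sa_tortuosity, "SA", side)
            prev = node.id
            # inner branch (towards the watershed line), two segments
            mid = net.add_vertex(((node.position[0] + x_inner) / 2.0,
                                  y + rng.uniform(-25.0, 25.0), 0.0))
            tip = net.add_vertex((x_inner + rng.uniform(-0.01, 0.01) * w,
                                  y + rng.uniform(-25.0, 25.0), 0.0))
            d_br = max(0.62 * d_trunk, d_lo)
            for a, b in ((node.id, mid.id), (mid.id, tip.id)):
                chord = max(net.distance(a, b), 1.0)
                net.add_vessel(a, b, d_br, chord * cfg.sa_tortuosity, "SA", side)
            inner_tips[side].append((tip.id, y))
            # outer branch, single segment
            out = net.add_vertex((x_outer + rng.uniform(-0.01, 0.01) * w,
                                  y + rng.uniform(-25.0, 25.0), 0.0))
            chord = max(net.distance(node.id, out.id), 1.0)
            net.add_vessel(node.id, out.id, max(0.55 * d_trunk, d_lo),
                           chord * cfg.sa_tortuosity, "SA", side)

        # intra-side arcade: chain adjacent inner tips so near-watershed
        # branches form loops and carry real baseline flow (pial networks
        # are anastomotic, not purely tree-like)
        tips = sorted(inner_tips[side], key=lambda t: t[1])
        for (t1, _), (t2, _) in zip(tips, tips[1:]):
            chord = max(net.distance(t1, t2), 1.0)
            net.add_vessel(t1, t2, max(0.45 * d_hi, d_lo),
                           chord * cfg.sa_tortuosity, "SA", side)

    if cfg.lmc_count:
        _attach_lmcs(net, cfg, inner_tips, rng)
    return net


def _attach_lmcs(net, cfg, inner_tips, rng):
    """Connect facing inner tips across the midline, spacing > 310 um."""
    mca = sorted(inner_tips["MCA"], key=lambda t: t[1])
    aca = sorted(inner_tips["ACA"], key=lambda t: t[1])
    chosen: list[tuple[int, int, float]] = []
    for tid, y in mca:
        if len(chosen) >= cfg.lmc_count:
            break
        if chosen and min(abs(y - cy) for *_, cy in chosen) <= 310.0:
            continue
        partner = min(aca, key=lambda t: abs(t[1] - y))[0]
        length = net.distance(tid, partner) * cfg.lmc_tortuosity
        if length > 1000.0:
            continue
        chosen.append((tid, partner, y))
    if len(chosen) < cfg.lmc_count:
        raise ValueError(
            f"cannot place {cfg.lmc_count} LMCs with >310 um spacing and <=1000 um "
            f"length on a {cfg.footprint_mm} mm fixture")
    for tid, partner, _ in chosen:
        d = cfg.lmc_diameter_median * float(np.exp(rng.normal(0.0, cfg.lmc_diameter_sigma)))
        net.add_vessel(tid, partner, d,
                       net.distance(tid, partner) * cfg.lmc_tortuosity, "LMC", "none")


def synth_measurements(net: VascularNetwork, full_solution: FlowSolution,
                       cfg: FixtureConfig, rng: np.random.Generator):
    """Sparse noisy velocity constraints + diameter-measurement flags.

    A random fraction of SA edges is marked as measured
    (``has_diameter_measurement`` is set on the network in place) and their
    solved velocities, perturbed by multiplicative log-normal noise, become
    precise targets.  Measured LMCs get noisy targets too; unmeasured LMCs
    get the median of the measured LMC targets (fallback 0.53 mm/s).  Range
    constraints 2-10 mm/s / 0.4-2 mm/s are added at every DA / AV root.

    Returns ``(constraints, ground_truth)`` with ground truth mapping
    edge id -> unperturbed |u| for recovery experiments.
    """
    constraints: list[VelocityConstraint] = []
    truth: dict[int, float] = {}

    def noisy(u):
        return float(abs(u) * np.exp(rng.normal(0.0, cfg.velocity_noise_sd)))

    sa_ids = sorted(e.id for e in net.vessels_of_type("SA"))
    n_meas = int(round(cfg.measurement_fraction * len(sa_ids)))
    measured = set(rng.choice(sa_ids, size=n_meas, replace=False).tolist()) if n_meas else set()
    for eid in sa_ids:
        if eid in measured:
            u = full_solution.velocity_of(eid)
            if abs(u) < 1e-9:
                continue
            net.vessels[eid].has_diameter_measurement = True
            truth[eid] = abs(u)
            constraints.append(VelocityConstraint(eid, "target", u_meas=noisy(u)))

    lmc_ids = sorted(e.id for e in net.vessels_of_type("LMC"))
    lmc_meas = [eid for eid in lmc_ids if rng.uniform() < cfg.measurement_fraction]
    lmc_targets = {}
    for eid in lmc_meas:
        u = full_solution.velocity_of(eid)
        if abs(u) >= 1e-9:
            lmc_targets[eid] = noisy(u)
            truth[eid] = abs(u)
    median = float(np.median(list(lmc_targets.values()))) if lmc_targets else LMC_DEFAULT_TARGET
    for eid in lmc_ids:
        constraints.append(VelocityConstraint(eid, "target",
                                              u_meas=lmc_targets.get(eid, median)))
    constraints.extend(da_root_range_constraints(net))
    constraints.extend(av_root_range_constraints(net))
    return constraints, truth


def default_fixture(seed: int = 0,
                    fixture_cfg: FixtureConfig | None = None,
                    gen_cfg: GenerationConfig | None = None) -> VascularNetwork:
    """Fully assembled default fixture network (pial + trees + capillaries)."""
    fixture_cfg = fixture_cfg or FixtureConfig(rng_seed=seed)
    gen_cfg = gen_cfg or GenerationConfig(rng_seed=seed)
    rng = np.random.default_rng(seed)
    pial = synth_pial(fixture_cfg, rng)
    return build_network(pial, gen_cfg, rng)
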
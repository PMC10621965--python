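"""Shared fixtures: the default synthetic network, tuned base state, scenarios.

Heavy objects (assembled fixture, tuned network) are session-scoped so the
pipeline runs once for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from pialflow.analysis import assign_sides
from pialflow.fixtures import FixtureConfig, default_fixture, synth_measurements
from pialflow.inverse import TuningOptions, tune_diameters
from pialflow.network import VascularNetwork
from pialflow.scenarios import ScenarioState, build_state
from pialflow.solver import solve_flow

FIXTURE_SEED = 1
MEASUREMENT_SEED = 101


@pytest.fixture(scope="session")
def fixture_config():
    return FixtureConfig(rng_seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_net(fixture_config):
    """Default assembled fixture network (untuned)."""
    return default_fixture(seed=FIXTURE_SEED, fixture_cfg=fixture_config)


@pytest.fixture(scope="session")
def fixture_solution(fixture_net):
    return solve_flow(fixture_net)


@pytest.fixture(scope="session")
def standard_constraints(fixture_net, fixture_solution, fixture_config):
    """Noisy SA targets + LMC targets + DA/AV root ranges, with ground truth."""
    rng = np.random.default_rng(MEASUREMENT_SEED)
    cons, truth = synth_measurements(fixture_net, fixture_solution,
                                     fixture_config, rng)
    return cons, truth


@pytest.fixture(scope="session")
def tuned_base(fixture_net, standard_constraints):
    """Fixture network after inverse tuning with the standard constraints."""
    cons, _ = standard_constraints
    tuned, history = tune_diameters(fixture_net, cons,
                                    TuningOptions(max_iterations=300))
    return tuned, history


@pytest.fixture(scope="session")
def base_state(tuned_base):
    net, _ = tuned_base
    return net, solve_flow(net)


@pytest.fixture(scope="session")
def classification(base_state):
    net, sol = base_state
    return assign_sides(net, sol)


@pytest.fixture(scope="session")
def mca_feeder_edge(base_state):
    net, _ = base_state
    return [e.id for e in net.vessels_of_type("SA_to_CoW") if e.side == "MCA"][0]


@pytest.fixture(scope="session")
def scenario_states(base_state, mca_feeder_edge):
    """Solved networks for the four canonical states."""
    net, sol = base_state
    out = {"Base": (net, sol)}
    for name in ("MCAo", "MCAo_LMC_dil", "MCAo_LMC_SA_DA_dil"):
        pert = build_state(net, ScenarioState(name, occlusion_edge=mca_feeder_edge))
        out[name] = (pert, solve_flow(pert))
    return out


# ------------------------------------------------------------- tiny builders

def two_vessel_chain(d1=10.0, d2=10.0, length=100.0,
                     p_in=100.0, p_out=10.0) -> VascularNetwork:
    net = VascularNetwork()
    a = net.add_vertex((0, 0, 0), role="cow_inflow")
    m = net.add_vertex((length, 0, 0))
    b = net.add_vertex((2 * length, 0, 0), role="av_root")
    net.add_vessel(a.id, m.id, d1, length, "SA")
    net.add_vessel(m.id, b.id, d2, length, "AV")
    net.boundary_conditions = {a.id: p_in, b.id: p_out}
    return net


def random_network(rng: np.random.Generator, n_internal=8, n_extra=30,
                   p_in=100.0, p_out=10.0) -> VascularNetwork:
    """Connected random network with one inflow and one outflow BC."""
    net = VascularNetwork()
    a = net.add_vertex((0, 0, 0), role="cow_inflow")
    b = net.add_vertex((1000, 0, 0), role="av_root")
    vids = [a.id, b.id]
    for _ in range(n_internal):
        vids.append(net.add_vertex((rng.uniform(0, 1000),
                                    rng.uniform(0, 1000), 0)).id)
    for i in range(1, len(vids)):  # spanning chain keeps it connected
        net.add_vessel(vids[i - 1], vids[i], rng.uniform(5, 30),
                       rng.uniform(50, 300), "SA")
    for _ in range(n_extra):
        u, v = rng.choice(vids, 2, replace=False)
        net.add_vessel(int(u), int(v), rng.uniform(5, 30),
                       rng.uniform(50, 300), "C")
    net.boundary_conditions = {a.id: p_in, b.id: p_out}
    return net
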
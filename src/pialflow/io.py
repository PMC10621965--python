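"""Readers/writers for network and result tables.

CSV is the canonical interchange format (two tables: vertices and edges);
GraphML and ASCII VTK polydata (.vtp) are secondary exports for generic
graph tools and 3D viewers.  A run manifest (seed, config hash, package
version) accompanies CLI output directories.
"""

from __future__ import annotations

import json
from pathlib import Path
from xml.etree import ElementTree as ET
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .network import VascularNetwork
from .solver import FlowSolution

__all__ = ["write_network", "read_network", "write_solution", "export_graphml",
           "export_vtp", "write_manifest"]

VERTEX_COLUMNS = ["id", "x", "y", "z", "role", "boundary_pressure_mmHg"]
EDGE_COLUMNS = ["id", "v1", "v2", "diameter_um", "length_um", "vtype", "side",
                "is_connector", "has_diameter_measurement", "frozen", "d_prior_um"]


def write_network(net: VascularNetwork, directory) -> tuple[Path, Path]:
    """Write vertices.csv / edges.csv into a directory; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vrows = [{
        "id": v.id, "x": v.position[0], "y": v.position[1], "z": v.position[2],
        "role": v.role,
        "boundary_pressure_mmHg": net.boundary_conditions.get(v.id, ""),
    } for v in sorted(net.vertices.values(), key=lambda v: v.id)]
    erows = [{
        "id": e.id, "v1": e.v1, "v2": e.v2, "diameter_um": e.diameter,
        "length_um": e.length, "vtype": e.vtype, "side": e.side,
        "is_connector": e.is_connector,
        "has_diameter_measurement": e.has_diameter_measurement,
        "frozen": e.frozen, "d_prior_um": e.d_prior,
    } for e in sorted(net.vessels.values(), key=lambda e: e.id)]
    vpath, epath = directory / "vertices.csv", directory / "edges.csv"
    pd.DataFrame(vrows, columns=VERTEX_COLUMNS).to_csv(vpath, index=False)
    pd.DataFrame(erows, columns=EDGE_COLUMNS).to_csv(epath, index=False)
    return vpath, epath


def read_network(directory, haematocrit: float = 0.3,
                 plasma_viscosity: float = 1.2) -> VascularNetwork:
    """Read a network written by :func:`write_network` (lossless round-trip)."""
    directory = Path(directory)
    vdf = pd.read_csv(directory / "vertices.csv")
    edf = pd.read_csv(directory / "edges.csv")
    for col in ("id", "x", "y", "z", "role"):
        if col not in vdf.columns:
            raise ValueError(f"vertices table is missing column {col!r}")
    for col in ("id", "v1", "v2", "diameter_um", "length_um", "vtype"):
        if col not in edf.columns:
            raise ValueError(f"edges table is missing column {col!r}")
    if vdf["id"].duplicated().any():
        dup = int(vdf["id"][vdf["id"].duplicated()].iloc[0])
        raise ValueError(f"duplicate vertex id {dup}")
    if edf["id"].duplicated().any():
        dup = int(edf["id"][edf["id"].duplicated()].iloc[0])
        raise ValueError(f"duplicate edge id {dup}")

    net = VascularNetwork(haematocrit, plasma_viscosity)
    for r in vdf.itertuples(index=False):
        net.add_vertex((r.x, r.y, r.z), role=r.role, id=int(r.id))
        bp = getattr(r, "boundary_pressure_mmHg", None)
        if bp is not None and not (isinstance(bp, float) and np.isnan(bp)) and bp != "":
            net.boundary_conditions[int(r.id)] = float(bp)
    ids = set(net.vertices)
    for r in edf.itertuples(index=False):
        if int(r.v1) not in ids or int(r.v2) not in ids:
            raise ValueError(f"edge {int(r.id)} references an absent vertex")
        net.add_vessel(int(r.v1), int(r.v2), float(r.diameter_um), float(r.length_um),
                       str(r.vtype), str(getattr(r, "side", "none")), id=int(r.id),
                       is_connector=bool(getattr(r, "is_connector", False)),
                       has_diameter_measurement=bool(
                           getattr(r, "has_diameter_measurement", False)),
                       frozen=bool(getattr(r, "frozen", False)),
                       d_prior=float(getattr(r, "d_prior_um", r.diameter_um)))
    return net


def write_solution(net: VascularNetwork, sol: FlowSolution, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vdf, edf = sol.to_frames(net)
    vdf.to_csv(directory / "pressures.csv", index=False)
    edf.to_csv(directory / "flows.csv", index=False)


def export_graphml(net: VascularNetwork, path) -> None:
    import networkx as nx

    nx.write_graphml(net.to_networkx(), path)


# --------------------------------------------------------------- VTK polydata

def _data_array(name, values, dtype="Float64", ncomp=None):
    attrs = f'type="{dtype}" Name="{escape(name)}" format="ascii"'
    if ncomp:
        attrs += f' NumberOfComponents="{ncomp}"'
    body = " ".join(f"{v:.10g}" if isinstance(v, float) else str(v) for v in values)
    return f"<DataArray {attrs}>\n{body}\n</DataArray>"


VTYPE_CODE = {"SA": 0, "SA_to_CoW": 1, "LMC": 2, "DA": 3, "C": 4, "AV": 5}
SIDE_CODE = {"MCA": 0, "ACA": 1, "none": 2}


def export_vtp(net: VascularNetwork, path, solution: FlowSolution | None = None) -> None:
    """ASCII XML VTK polydata: vertices as points, vessels as line cells.

    Per-cell arrays: diameter, vtype (integer code), side code, and — when a
    solution is given — flow, velocity and WSS; per-point pressure.  Without
    a solution a geometry-only file is written.
    """
    vids = sorted(net.vertices)
    vidx = {v: i for i, v in enumerate(vids)}
    eids = sorted(net.vessels)

    pts = []
    for v in vids:
        pts.extend(net.vertices[v].position.tolist())
    conn, offs = [], []
    for e in eids:
        ed = net.vessels[e]
        conn.extend((vidx[ed.v1], vidx[ed.v2]))
        offs.append(len(conn))

    cell_arrays = [
        _data_array("diameter_um", [float(net.vessels[e].diameter) for e in eids]),
        _data_array("vtype", [VTYPE_CODE[net.vessels[e].vtype] for e in eids], "Int32"),
        _data_array("side", [SIDE_CODE[net.vessels[e].side] for e in eids], "Int32"),
    ]
    point_arrays = []
    if solution is not None:
        cell_arrays += [
            _data_array("flow_um3_s", [solution.flow_of(e) for e in eids]),
            _data_array("velocity_mm_s", [solution.velocity_of(e) for e in eids]),
            _data_array("wss_Pa", [float(solution.wss[solution.edge_index(e)[0]])
                                   for e in eids]),
        ]
        point_arrays.append(_data_array("pressure_mmHg",
                                        [solution.pressure_of(v) for v in vids]))

    xml = f"""<?xml version="1.0"?>
<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">
<PolyData>
<Piece NumberOfPoints="{len(vids)}" NumberOfLines="{len(eids)}">
<Points>
{_data_array("Points", [float(x) for x in pts], ncomp=3)}
</Points>
<Lines>
{_data_array("connectivity", conn, "Int64")}
{_data_array("offsets", offs, "Int64")}
</Lines>
<PointData>
{chr(10).join(point_arrays)}
</PointData>
<CellData>
{chr(10).join(cell_arrays)}
</CellData>
</Piece>
</PolyData>
</VTKFile>
"""
    Path(path).write_text(xml)
    ET.fromstring(xml)  # guarantee well-formed output


def write_manifest(directory, seed: int, config: dict | None = None) -> None:
    import hashlib

    from . import __version__

    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": config or {},
        "pialflow_version": __version__,
    }
    Path(directory, "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
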
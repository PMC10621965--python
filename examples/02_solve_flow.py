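"""Solve steady Poiseuille flow on the default network and report perfusion.

Pressure boundary conditions are 100 mmHg at the circle-of-Willis inflow
and 10 mmHg at every ascending-vein root.  The printout gives median RBC
velocity per vessel type (mm/s) and the cerebral-blood-flow summary: total
inflow normalised per surface area, tissue volume and mass.
"""

from statistics import median

from pialflow import cbf_summary, default_fixture, solve_flow

net = default_fixture(seed=1)
sol = solve_flow(net)

by_type = {}
for e in net.vessels.values():
    by_type.setdefault(e.vtype, []).append(abs(sol.velocity_of(e.id)))
print(f"{'type':>9} {'n':>6} {'median |u| mm/s':>16}")
for vtype, us in sorted(by_type.items()):
    print(f"{vtype:>9} {len(us):>6d} {median(us):>16.3f}")

s = cbf_summary(net, sol)
print(f"\ntotal inflow: {s.total_inflow_um3_s:.3e} um^3/s "
      f"over {s.footprint_area_mm2:.2f} mm^2, depth {s.depth_mm:.2f} mm")
print(f"flow per area:   {s.flow_per_area_ml_min_mm2:.4f} ml/min/mm^2")
print(f"flow per volume: {s.flow_per_volume_ml_min_cm3:.2f} ml/min/cm^3")
print(f"CBF:             {s.cbf_ml_min_100g:.0f} ml/min/100g")
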
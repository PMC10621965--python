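# pialflow

Blood-flow simulation in semi-realistic cortical microvascular networks,
built to study how **leptomeningeal collaterals (LMCs)** — pial vessels
connecting the middle and anterior cerebral artery territories (MCA, ACA)
— redistribute blood during ischaemic stroke.

The package is aimed at computational physiologists and neurovascular
researchers who want a desk-scale, fully scripted version of the workflow:

1. **Generate** a vessel graph that mimics the cortical vasculature: a pial
   surface-artery (SA) network fed by MCA and ACA branches from a single
   circle-of-Willis (CoW) inflow, descending-artery (DA) penetrating trees,
   a stacked hexagonal capillary lattice (diameter 4 µm, length 62 µm,
   tortuosity 1.37), and ascending veins (AV) at a DA:AV root ratio of 1:3.
2. **Solve** steady network flow with Poiseuille's law. Each vessel has
   conductance

   ```
   G = π d⁴ / (128 µ_p µ_rel(d, H_D) L)
   ```

   where `µ_rel` is the empirical in vitro viscosity law of Pries et al.
   (diameter- and haematocrit-dependent; constant discharge haematocrit
   H_D = 0.3, no phase separation). Vertex pressures solve the sparse
   conductance Laplacian with Dirichlet boundary conditions of 100 mmHg at
   the CoW and 10 mmHg at every AV root. Wall shear stress uses the
   parabolic-profile estimate `WSS = 32 q µ_eff / (π d³)`.
3. **Tune** vessel diameters with an adjoint-based inverse model so solved
   RBC velocities match sparse measurements: precise targets `(|u|−u_meas)²`
   on measured SAs and LMCs, range parabolas (zero inside 2–10 mm/s for DA
   roots, 0.4–2 mm/s for AV roots). The gradient with respect to *all*
   diameters costs one extra linear solve (adjoint method); diameters are
   box-constrained to ±5 % (measured SAs), ±20 % (unmeasured pial vessels)
   and ±50 % (everything else) of their priors.
4. **Perturb**: MCA occlusion (a 50 µm feeder segment constricted to 10 %
   of its diameter), LMC dilation (×1.7), SA/DA dilation (+10 %), passive
   linear-elastic diameter coupling, and random removal/addition of LMCs
   (addition honours a 310 µm spacing and 1000 µm length rule).
5. **Analyse**: MCA/ACA territory assignment via upstream flow tracing and
   the planar Voronoi tessellation of DA roots (the watershed line is the
   boundary between differently labelled cells), SAs on shortest paths to
   LMCs, 250 µm distance-to-LMC bins, relative changes of mean/integral
   flow and mean pressure, flow-direction changes, and CBF per area,
   volume and mass (tissue density 1046 kg/m³).

The case-specific in vivo reconstructions this methodology was developed
on are not available as data, so `pialflow.fixtures` generates seeded
synthetic pial topologies with the same structure (two territories, a
watershed line, LMC candidates, sparse noisy velocity measurements with
known ground truth). All fixture data are synthetic.

## Worked example

```bash
python examples/03_tune_diameters.py
```

```
75 constraints on 7394 tunable vessels
cost: 1.376 -> 3.37e-03 in 300 iterations
DA roots: |u| range 5.53-9.85 mm/s (target 2.0-10.0); out of range: 5 before, 0 after tuning
AV roots: |u| range 0.46-1.94 mm/s (target 0.4-2.0); out of range: 4 before, 0 after tuning
```

Before tuning, several penetrating-tree root velocities sit outside their
physiological ranges; the inverse model pulls every DA-root and AV-root
velocity into 2–10 mm/s and 0.4–2 mm/s respectively while matching the SA
targets, without any diameter leaving its prior box.

```bash
python examples/04_stroke_scenarios.py
```

```
   class                 MCAo         MCAo_LMC_dil   MCAo_LMC_SA_DA_dil
 MCA DAs               -65.4%               -23.2%                -6.2%
  MCA Cs               -55.4%               -21.1%                -5.1%
 ACA DAs                +1.3%                -1.8%               +23.0%
  ACA Cs                +1.4%                -1.9%               +20.3%
```

Each cell is the relative change of integral (summed) flow versus Base.
Occlusion starves the MCA territory while the ACA side is barely touched;
dilating the collaterals recovers a large part of the MCA-side perfusion
at a small cost to the ACA side; dilating all arteries lifts perfusion in
both territories. `examples/05_lmc_density.py` shows that the recovery is
monotone in the number of collaterals (0 % / 50 % / 100 % LMC scenarios).

A thin CLI wraps the same pipeline for shell use:

```bash
pialflow --seed 7 fixture --out net/
pialflow solve --network net/ --out base/ --vtp
pialflow scenario --network net/ --state MCAo --out mcao/
pialflow analyze --base net/ --state mcao/ --out report/
```

## Layout

```
src/pialflow/
  network.py     graph types, validation, per-type statistics
  viscosity.py   empirical relative-viscosity laws (+ analytic derivative)
  solver.py      sparse Poiseuille solver, conductances, WSS
  generation.py  DA-root refinement, AV roots, trees, lattice, assembly
  fixtures.py    synthetic pial topologies and sparse measurements
  inverse.py     velocity constraints, adjoint gradient, diameter tuning
  scenarios.py   MCAo, dilations, elasticity, LMC removal/addition
  analysis.py    territories, path classes, distance bins, ΔQ/Δq/Δp, CBF
  io.py          CSV tables, GraphML, VTK polydata, manifests
  cli.py         thin command-line interface
```

See `docs/methods.md` for the model assumptions, parameter defaults and
their rationale, and known limitations.
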
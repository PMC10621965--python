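# Methods

## Flow model

The vasculature is a graph of cylindrical vessels. Steady flow obeys
Poiseuille's law per edge, `q = G Δp`, with conductance
`G = π d⁴ / (128 µ_p µ_rel(d, H_D) L)`; mass conservation at every interior
vertex yields a sparse symmetric positive-definite linear system in the
vertex pressures, solved by sparse LU factorisation. Dirichlet boundary
conditions are 100 mmHg at the single circle-of-Willis inflow vertex and
10 mmHg at every ascending-vein root, held fixed across all states. Units
are µm / mmHg / mm·s⁻¹ / µm³·s⁻¹ / mPa·s throughout; the single conversion
1 mmHg = 133.322 Pa lives inside the conductance.

Assumptions: rigid vessels (unless the elastic coupling is enabled),
constant discharge haematocrit 0.3 network-wide, no RBC phase separation,
RBC velocity equal to bulk mean velocity, no pulsatility, no
autoregulation. These match the scope of a redistribution study — the
interest is in how the pressure field reroutes flow, not in capillary-scale
rheology.

**Viscosity.** The diameter/haematocrit dependence of apparent blood
viscosity follows the empirical in vitro law of Pries and co-workers
(`mu45(d) = 220 e^{−1.3d} + 3.2 − 2.44 e^{−0.06 d^0.645}`, shape exponent
`C(d)` with the standard d¹² sigmoid). The in vivo variant (with the
`(d/(d−1.1))²` endothelial-surface-layer factor) is available behind
`dialect="in_vivo"`; in vitro is the default because no wall-layer
correction is part of the baseline model. Plasma viscosity defaults to
1.2 mPa·s and is configurable. Analytic `dµ_rel/dd` is implemented and
verified against finite differences — it enters the adjoint gradient.

**Wall shear stress** uses the parabolic-profile estimate
`WSS = 32 |q| µ_eff / (π d³)` (reported in Pa).

**Degenerate inputs.** A component not connected to any Dirichlet vertex
makes the system singular; this is detected structurally (BFS from the
boundary vertices) and raised with the offending vertex ids, because the
sparse factorisation does not reliably flag exact singularity. Sign
convention: q > 0 flows from the lower-id endpoint to the higher-id one;
direction changes between two states are sign flips on the common edge
set, with flows below 10⁻⁹ of the state's maximum treated as dead.

## Network generation

Starting from a pial SA graph, DA roots are sampled uniformly into the
convex hull of the pial vertices (minimum spacing 100 µm, counts balanced
between the two halves of the hull so neither territory is systematically
starved) until `round(density × hull area)` roots exist; each root is
connected to the nearest SA edge, splitting it at the orthogonal
projection (ties to the lower edge id). AV roots surround each DA root on
a rhombic pattern (radius 150 µm, random phase, 3 per DA root).

Penetrating trees are synthesised algorithmically — the reference tree
database from rat cortex is not distributed — as random bifurcating trees
with Murray-law tapering (`d_parent³ = Σ d_child³`, split fraction
U(0.4, 0.6)), segment length 120 µm and root calibres 15–20 µm (DA) /
24–36 µm (AV), all scaled by 2/3 to account for the thinner mouse cortex;
trees terminate at 6 µm calibre or at the lattice depth. The capillary bed
is a stacked honeycomb with uniform diameter 4 µm, hydraulic length 62 µm
and tortuosity 1.37 (chord = 62/1.37 µm; layers one chord apart). Tree
leaves join the nearest lattice vertex through a 4 µm connector (flagged
`is_connector` so statistics can exclude the artificial plumbing).

The free generator parameters (tree calibres, segment length, lattice
depth of 4 layers, connector calibre) were fixed once so that the
assembled default network reproduces physiological baselines: DA-root
velocities of a few mm/s, AV-root velocities around 1 mm/s, near-dormant
collaterals (≈0.1–1 mm/s), capillary flows of order 1 pl/s, and capillary
length density dominating all other types. They are configuration values,
not fitted quantities.

## Synthetic fixture

`fixtures.synth_pial` emulates the structure of a real pial reconstruction
at ~1 mm² scale: per side a feeder, a tapering trunk (16–38 µm), inner
branches towards the watershed line, outer branches, and an intra-side
arcade chaining the inner tips (pial networks are anastomotic; without the
arcade the near-watershed branches would be dead-ended and carry no
baseline flow). LMCs connect facing inner tips across the midline,
honouring the >310 µm spacing and ≤1000 µm length rules; the two feeder
stubs carry a hydraulic length of 1500 µm to stand in for the upstream
M2–M4 path, which also provides the occlusion site.

The default LMC calibre (log-normal, median 4.5 µm) is chosen so that the
*areal* collateral conductance relative to the territory demand matches
the full-scale situation: the fixture covers ~1/28 of the original
footprint but carries a similar number of collaterals, so keeping
real-scale calibres would make the collaterals disproportionately strong
conduits and mask the occlusion. With the default, an MCA occlusion drops
the MCA-side mean SA pressure by ~50 % while collateral dilation recovers
a large fraction of DA inflow — the qualitative pattern the scenario suite
asserts.

Synthetic measurements mark a fraction (default 0.4) of SAs as measured
and perturb their true velocities by multiplicative log-normal noise
(σ = 0.10, the typical line-scan repeatability scale); unmeasured LMCs
receive the median of the measured LMC targets (fallback 0.53 mm/s).
What passing tests show about real data is therefore limited: the fixture
has exact Poiseuille physics, uniform haematocrit and a regular capillary
lattice, so recovery/redistribution results demonstrate correctness of
the machinery, not predictive accuracy for any particular animal.

## Inverse model

The misfit is a sum of one-sided parabolas on velocity magnitudes
(targets and ranges), each optionally normalised by the squared target (or
range midpoint) so mm/s-scale differences across vessel types weigh
comparably (default on). The gradient with respect to every diameter is
computed with the adjoint method: with `A p = b` the reduced pressure
system, solve `A λ = ∂J/∂p` (A is symmetric) and assemble
`∇_d J = ∂J/∂d − (λ_a − λ_b) (∂G/∂d)(p_a − p_b)` per edge, where `∂J/∂d`
is the direct cross-section/conductance term on constrained edges.
Correctness is asserted against central finite differences at 10⁻⁵
relative (vector norm over sampled components; per-component comparison is
dominated by FD truncation noise on near-zero entries).

Optimisation is box-constrained: diameters stay within ±5 % (measured
SAs), ±20 % (unmeasured SA/SA-to-CoW/LMC) or ±50 % (DA/C/AV) of their
priors; frozen edges (the occluded segment) never move. Two optimisers
share the cost/gradient: projected gradient descent with Armijo
backtracking (`method="pgd"`), and box-constrained L-BFGS-B
(`method="lbfgsb"`, the default). L-BFGS-B was made the default because on
the ~7×10³-parameter fixture it reaches the 1 %-recovery tolerance within
a few hundred iterations where first-order descent stalls; both satisfy
the same contracts (monotone accepted cost, boxes respected). The solution
is ambiguous — far more parameters than constraints — so only the cost,
not the diameter field, is reproducible across initialisations; tests
assert cost equality accordingly. Termination: cost ≤ tolerance
(default 10⁻¹⁰) or the iteration cap (default 500; examples use 300,
which brings the normalised cost to ~10⁻³ on the noisy fixture, i.e.
residuals at or below the measurement noise).

## Scenario states

* **MCAo** — a centred 50 µm sub-segment of the MCA feeder is split out,
  constricted to 10 % of its baseline diameter, and frozen.
* **MCAo & LMC-dil** — additionally every LMC is dilated, uniformly ×1.7
  (per-vessel factors can be supplied where measurements exist).
* **MCAo & LMC/SA/DA-dil** — additionally all SA and DA vessels dilate by
  10 %. The artificial feeder stubs are excluded (they are plumbing, and
  the occluded segment must not dilate), as they are from SA statistics.

Transforms are pure: the input network is never mutated, so a state is
reproducible from (network, state, seed).

**Elasticity.** Passive diameter changes follow a linearised tube law
around the Base state: `d = d_state (1 + c (p_mid − p_mid,Base))` with
compliance `c` in fractional diameter change per mmHg, iterated with the
flow solve to a fixed point (tolerance 10⁻⁸ on the max relative diameter
change). No published constants are adopted; the default
`c = 10⁻³ mmHg⁻¹` for all types was set a priori so that the ~50–70 mmHg
post-occlusion pressure drops produce passive constrictions below 10 %,
the regime in which elasticity only slightly perturbs the rigid results.
Dilation factors apply to the pre-elastic baseline diameters.

**LMC density variation.** `remove_lmcs` keeps a uniform random
`round(f·n)` subset; `add_lmcs` sequentially samples MCA-side pial
vertices, connects each to the closest ACA-side vertex, and accepts the
candidate iff it is >310 µm from every existing LMC and ≤1000 µm long,
drawing diameters from the configured log-normal.

## Analysis definitions

Territory labels: every DA root is traced upstream through the pial
network, always following the incident edge with the largest inflow, until
an MCA- or ACA-side feeder edge is reached (dead, flow-free branches fall
back to pressure ascent towards the flowing network; inflow ties resolve
to the first maximal edge encountered, which for the fixture means the
MCA-first edge ordering). DA/AV tree edges inherit their root's label
(AV roots take the label of the nearest DA root's Voronoi cell),
capillaries the label of the planar Voronoi cell containing their
midpoint. Cells are clipped to the convex hull of the DA roots, which also
defines the CBF footprint; clipped areas tile the footprint exactly.

Relative changes are `(agg(new) − agg(base))/agg(base)` with mean (Δq_rel,
Δp_rel) or sum (ΔQ_rel) aggregation. Flow values enter as magnitudes —
flows reverse under occlusion and perfusion is reported as a positive
quantity — with a `magnitudes=False` switch for signed analyses; pressures
are always signed. Integral DA inflow sums |q| over DA-root edges;
integral capillary flow sums |q| over capillary edges. SA-to-CoW stubs are
excluded from SA statistics; capillaries farther than 200 µm (planar) from
any DA edge can be masked out of velocity/flux summaries as border
artefacts. Distance-to-LMC bins use the planar distance from edge midpoint
to the nearest LMC segment, 250 µm spacing; with no LMCs everything falls
into a single overflow bin (−1). CBF divides total CoW inflow by footprint
area, by area × vascularised depth, and converts per-mass with
1046 kg/m³.

## Problem sizes and determinism

The default fixture spans ~1 mm² and ~7 × 10³ vessels with a four-layer
capillary lattice — a deliberate desk-scale configuration; generation plus
a Base solve completes in a few seconds, the full tuning run in under a
minute. A full-depth, multi-mm² network is reachable through the same
configuration objects. Because the lattice is only ~0.3 mm deep while the
pial supply is full-strength, per-volume CBF values run a few-fold above
cortical literature means; the CBF check is therefore an
order-of-magnitude interval, not a point comparison. All randomness flows
through explicitly seeded `numpy` generators; regenerating any fixture or
rerunning any CLI command with the same seed is bit-identical.

## Known limitations

No phase separation or haematocrit heterogeneity, no oxygen transport, no
autoregulation or time dependence, no reperfusion dynamics. Penetrating
trees are statistical stand-ins, not morphologically matched to any
animal. The watershed of the fixture is a straight midline by
construction. Tuned diameter fields are one member of a solution manifold
and should not be interpreted vessel-by-vessel.
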
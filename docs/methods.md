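# Methods

`tumorflow` simulates steady-state fluid transport in vascularised
(tumour) tissue whose microvascular network is known explicitly — every
vessel segment with its 3-D coordinates, diameter and centerline
length. Two compartments are coupled: Poiseuille blood flow on the
vascular graph, and Darcy flow through the porous interstitium, joined
by Starling's law across the vessel wall.

## Vascular compartment

Each segment j carries a conductance `g_j = pi d_j^4 / (128 mu_j l_j)`
with an effective viscosity `mu_j` from the empirical in-vivo
apparent-viscosity law for blood in narrow tubes (a function of lumen
diameter and discharge haematocrit, capturing the Fahraeus–Lindqvist
minimum near 7 um and the in-vivo endothelial-surface-layer correction;
haematocrit is uniform at H = 0.45, plasma viscosity 1.05 cP,
configurable). Conservation of flux at every junction gives the nodal
system `K p = -Q0`.

Terminal ("boundary", degree-1) nodes are where conditions live.  When
pressures or fluxes are known everywhere, `solve_poiseuille` is a
direct sparse solve.  In whole-tumour networks almost all terminal data
are unknown, so `estimate_flow` instead minimises

    1/2 k_p  sum_k w_k (p_k - p0_k)^2  +  1/2 k_tau sum_j l_j (tau_j - s_j tau0_j)^2

subject to flux conservation at every interior node and at explicit
flux boundaries (blind ends).  `w_k` is half the summed length of
segments incident at node k; `tau_j = d_j dp_j / (4 l_j)` is the wall
shear stress as a linear function of nodal pressure.  The shear-target
sign `s_j` must match the (unknown) flow direction, so the sparse
saddle-point solve is repeated with signs updated from the current
flows until no segment changes direction (cap 100 iterations; zero-flow
segments keep their previous sign).  Because each re-solve minimises a
convex quadratic on the constraint manifold and each sign update can
only lower the shear penalty, the objective is non-increasing across
direction iterations — this is asserted in the tests.

Defaults `p0 = 31 mmHg`, `tau0 = 15 dyn/cm^2`, `k_p = 0.1`, and `k_tau`
chosen to balance the two penalty terms on an initial pressure-only
solve; all are configuration, not constants, and both targets accept
per-node / per-segment arrays.  Solves use sparse LU with one step of
iterative refinement, which keeps interior mass-balance residuals near
1e-14 relative (<= 1e-10 contract).

## Boundary assignment and perfusion calibration

Terminal nodes near the hull surface (within twice the mean vessel
diameter by default) are "surface" nodes assumed to join peritumoural
vessels.  A seeded draw assigns a high/low pressure pair (defaults
30/20 mmHg; 45/15 mmHg is the second stock pair) to 5% of them
(floor rule, minimum one of each extreme), rejecting placements that
would put opposite extremes inside an axis-aligned exclusion ellipsoid
whose principal diameters are 5% of the tissue bounding box — steep
local gradients between adjacent extremes are unphysiological.  Of the
remaining terminal nodes, 33% become blind ends (zero flux, matching
reported blind-end fractions in carcinomas) and the rest stay unknown
for the estimation scheme.  All draws are pure functions of the seed.
`calibrate_to_perfusion` loops candidate pressure pairs and seeds until
the simulated tissue perfusion matches a measured target within a
relative tolerance (default 20%), logging every trial.

## Interstitial compartment

Darcy flow `u = -kappa grad p` with `p -> p_inf` far away.  The
vasculature is discretised into point sources with maximum spacing
delta along every segment (one source per sub-segment midpoint; its
radius r0 equals the vessel radius, its vascular pressure is linearly
interpolated from the nodal solution).  Each source is regularized over
its sphere, giving the kernel

    G(r) = [3 - (r/r0)^2] / (8 pi kappa r0),  r <= r0
    G(r) = 1 / (4 pi kappa r),                r >  r0

continuous with continuous gradient at r = r0.  Starling's law
`J_v = L_p S (dp - sigma dPi)` closes the dense linear system

    sum_j (G_ij - (kappa_i / L_p,i) dG_ij) q_j = p_b,i - p_inf - sigma_i (Pi_b - Pi_v)

for the strengths q (internally cm^3/s, reported in ul/min).  Baseline
parameters: kappa = 1.7e-7 cm^2/(mmHg s), L_p = 2.8e-7 cm/(mmHg s),
sigma = 0.82, Pi_b - Pi_v = 5 mmHg, p_inf = 0 (isolated subcutaneous
tissue without lymphatics).  Heterogeneous kappa uses the evaluating
source's own conductivity inside its kernel — an approximation, since
the variable-coefficient problem has no such closed kernel; it is
implemented exactly as stated and flagged here.

**Self-interaction closure.** The kernel gradient is exactly zero at
r = 0, which would make an isolated source's strength independent of
the wall conductance — unphysical, and inconsistent with the strong
L_p sensitivity the model must show.  The default closure evaluates the
self-gradient at the vessel wall, `A_ii = 3/(8 pi kappa r0) +
1/(4 pi L_p r0^2)`, which restores both limits (L_p -> 0 gives q -> 0
and IFP -> p_inf; L_p -> inf gives the pure Green's system).  An
alternative "lumped" closure identifying J_v,i with q_i is selectable
(`self_term="lumped"`); both closures are validated against the
finite-difference oracle.  Dense assembly and direct solves are used
below 20,000 sources (row-chunked assembly bounds memory); above that
the solver goes matrix-free/iterative.

## Coupling

Each iteration solves the source system, computes the transvascular
flux `J_v,i = -2 pi kappa_i r_v,i l_i sum_j dG_ij q_j` (same self-term
convention), and updates the vascular pressure seen by each source to
the wall value `p_b <- p_b - K_i J_v,i` with `K_i = 1/(L_p S_i)`.  The
vascular network is not re-solved by default (transvascular losses are
tiny against intravascular flow); a callback re-solves it per iteration
for sensitivity studies, and `update_pb=False` reproduces the
uncoupled single-pass solution exactly.  Convergence is declared when
`max_i |dq_i|` falls below 1e-6 ul/min (cap 50 iterations); failure to
converge is reported honestly, never asserted away.

**Desk-scale regime.**  The fixed point of this update is J_v = 0 for
any network: the update keeps transferring the hydrostatic drop across
the wall until filtration stops.  What distinguishes regimes is where
the tolerance stops the iteration.  With baseline parameters the
per-source wall resistance (~1.5e12 mmHg s/cm^3) exceeds the collective
Green's interaction unless roughly 1e5 or more sources cooperate —
whole-tumour scale.  Desk-scale fixtures (1e3–1e4 sources) are
wall-dominated: the update converges in 3–5 iterations having
transferred most of the drive, so converged coupled IFP magnitudes are
far below whole-tumour values (fractions of a mmHg rather than tens).
The spatial structure survives — the radial IFP profile remains
core-elevated and bin-wise non-increasing, and parameter orderings
(below) are robust — so qualitative claims are tested as orderings,
never as magnitudes, and the uncoupled single-pass IFP is reported
alongside the coupled value.

## Hull, perfusion and maps

The tumour surface is the convex hull of all network nodes,
Loop-subdivided with new vertices projected back to the hull along
centroid rays (volume by the divergence theorem; a 10 um-offset paired
surface provides normal pressure gradients).  Tissue perfusion sums
(i) blood inflow at surface terminal nodes and (ii) interstitial inflow
through the hull, quadratured by greedy non-overlapping spheres packed
on the surface vertices (radius capped at half the local vertex
spacing).  Because non-overlapping discs cover only ~75% of the
surface, the quadrature weights are renormalised by hull area over
packed disc area; with that, the recovered outflow of a central source
is 97% of its strength.  Mass converts hull volume at 1 g/cm^3.  Only
inflow counts by default (a net-flux option subtracts outflow).
Perfusion is reported in ml/min/100g.

Radial profiles bin fields by normalised radius (centroid distance over
centroid-to-hull distance along the ray); planar maps average fields
over isotropic 140 um pixels.

## Normalization scenarios

Vascular-normalization therapy is modelled as linear radial ramps from
tumour values at the core to physiological values at the periphery:
diameters towards d/1.99, L_p towards 0.44e-7 cm/(mmHg s), sigma
towards 0.91, and (optionally) kappa towards 8.53e-9 cm^2/(mmHg s).
Each ramp is independently switchable; all off is the identity.
Segment diameters ramp at the segment midpoint's normalised radius,
per-source parameters at each source.  The shipped regression asserts
the ordering that kappa-normalization shifts mean IFP more than
lumen-only normalization on the same fixture.

## Synthetic study fixtures

Real whole-tumour networks behind the study conditions are not
distributable, so seeded generators emulate their summary statistics:
log-normal diameters (defaults 8.9 ± 2.8 um, colorectal-xenograft-like;
glioma-like 17.9 ± 9.3 um at ~5% density also exercised), branch
lengths ~89 um, and a target vascular density inside an ellipsoidal
domain.  Trees bifurcate inward from surface roots (so interior nodes
are degree-3 junctions and branch statistics apply directly to
segments) and are joined into one component by short connectors.
Diameters are drawn from the target log-normal and sorted so thicker
branches sit nearer the roots — a distribution-matched choice rather
than a strict Murray recursion, which drifts from the diameter targets;
the generator is statistical scaffolding, not an angiogenesis model.
What passing tests show about real data is therefore limited: the
solvers are exact on their contracts and the qualitative spatial
behaviour is right, but absolute IFP/perfusion magnitudes at
whole-tumour scale depend on network data the fixtures do not contain.

## Numerical choices

- Units: geometry um; all solver arithmetic in {cm, s, mmHg}; flows
  reported nl/min (vascular) and ul/min (sources), shear dyn/cm^2,
  velocities um/s or mm/s, perfusion ml/min/100g.
- Source solve: dense LU; residual contract 1e-10 relative.
- Saddle solves: sparse LU plus one iterative-refinement step.
- Duplicate-node merge tolerance 1e-3 um; stored (tortuous) segment
  lengths are trusted, never recomputed from chords.
- FD oracle: 7-point Laplacian, exact DST factorisation for uniform
  conductivity; box faces carry the monopole far-field value
  p_inf + Q_tot/(4 pi kappa r) so truncation error sits at the
  higher-multipole level (zero-Dirichlet is an option but its bias on a
  1/r field is ~r_eval/L).  Verified second-order accurate; 0.4% error
  at h = r0/4 for a single source.
- Problem sizes: the default test fixture is an 800 um tumour-like
  network at 1.5% density (~1000 segments, ~1700 sources); the
  acceptance script uses 900 um at 2% (~1400 segments, ~3200 sources)
  plus a 12-replicate ensemble.

## Known limitations

- One-way coupling: vascular pressures are updated from Starling
  losses but the network flow is not re-solved by default; the coupled
  fixed point drains filtration entirely at desk scale (see above).
- Haematocrit is uniform; no phase separation, pulsatility or vessel
  compliance.
- Oncotic pressures are fixed (no protein transport) and there are no
  lymphatic sinks.
- Convex hulls only; strongly non-convex tumour shells would need an
  alpha-shape surface.
- Heterogeneous-kappa kernels are the stated closed-form approximation.
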
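# tumorflow

Coupled vascular–interstitial fluid transport on explicit microvascular
networks.

Solid tumours develop disorganised, leaky vasculature and a dense
extracellular matrix; together these elevate interstitial fluid
pressure (IFP) in the tumour core and throttle the convective delivery
of drugs. Understanding — and therapeutically reversing — that state
requires resolving fluid exchange at the scale of individual vessels
across a whole tumour. `tumorflow` is for researchers who have (or can
synthesise) a segmented vascular network — nodes with 3-D coordinates,
segments with diameters and lengths — and want micron-resolved
predictions of blood flow, transvascular filtration, IFP/IFV fields,
tissue perfusion, and the response to vascular-normalization therapy.

## The model

**Vascular compartment.** Poiseuille flow on the vessel graph: segment
conductance g_j = π d_j⁴ / (128 μ_j l_j), with μ_j from the empirical
in-vivo blood viscosity law μ(d, H) (Fåhræus–Lindqvist effect,
discharge haematocrit H = 0.45). Flux conservation at junctions gives
K p = −Q₀. Because terminal boundary data are unmeasurable in vivo,
unknown boundaries are estimated by constrained optimisation: minimise

  ½ k_p Σ_k w_k (p_k − p₀)² + ½ k_τ Σ_j l_j (τ_j − s_j τ₀)²

subject to mass conservation, where τ_j is wall shear stress and the
target signs s_j are iterated to a flow-direction fixed point.
Surface terminal nodes receive stochastic high/low pressures (with an
exclusion rule preventing adjacent opposite extremes), a fraction of
the rest are blind ends, and the assignment can be calibrated against
a measured mean tissue perfusion.

**Interstitial compartment.** Darcy flow u = −κ∇p with far-field
pressure p_∞, driven by point sources of transvascular flux placed
along every vessel with maximum spacing δ and regularized over spheres
of the local vessel radius. The kernel

  G(r) = [3 − (r/r₀)²]/(8πκr₀) for r ≤ r₀, 1/(4πκr) for r > r₀

and Starling's law J_v = L_p S (Δp − σΔΠ) close a linear system for
the source strengths q:

  Σ_j (G_ij − (κ_i/L_p,i) G′_ij) q_j = p_b,i − p_∞ − σ_i(Π_b − Π_v).

IFP and IFV anywhere follow by superposition — no volumetric mesh is
required. A fixed-point loop feeds the Starling losses back into the
vascular pressures until source strengths stop changing (tolerance
1e−6 µl/min). Tissue perfusion combines vascular inflow at surface
terminals with interstitial inflow through a sphere-packed convex-hull
quadrature. Normalization scenarios ramp diameters, L_p, σ and
(optionally) κ from tumour values at the core to physiological values
at the periphery.

An independent finite-difference Darcy oracle (7-point Laplacian,
DST-factorised) validates the Green's-function machinery; the shipped
ten-source comparison agrees to < 0.1% relative L2.

## Worked example

```python
import tumorflow as tf

spec = tf.SyntheticNetworkSpec(seed=7, extent_um=(800.0,) * 3,
                               vascular_density_pct=1.5)
cfg = tf.RunConfig(source_spacing_um=50.0, hull_subdivision=1)
model = tf.TumourFluidModel.from_synthetic(spec, cfg)
res = model.fit(seed=3)
print(res.summary())
```

prints

```
Coupled tumour fluid-transport results
======================================================
Nodes / segments                  744 / 743
Boundary nodes                    363
Mean vessel diameter (um)         8.92 +/- 2.78
Vascular density (%)              3.086
Hull volume (cm^3)                1.4134e-04
------------------------------------------------------
Blood pressure (mmHg)             30.98 +/- 0.43
Blood flow (nl/min)               0.316 +/- 1.59
Wall shear stress (dyn/cm^2)      2.76 +/- 13.23
Direction iterations              5 (converged: True)
------------------------------------------------------
Sources                           1680 (spacing 50 um)
Coupling iterations               3 (converged: True)
IFP (mmHg)                        4.43e-05 +/- 7.36e-06
IFV (um/s)                        1.89e-06 +/- 5.8e-07
------------------------------------------------------
Perfusion (ml/min/100g)           23.44
  vascular (ml/min)               3.313e-05
  interstitial inflow (ml/min)    0.000e+00
```

Reading it: the estimated blood pressures cluster tightly around the
31 mmHg target with flow concentrated in a few high-shear paths; the
743-segment network carries 1680 Starling sources; the coupled
iteration converged in three passes. Perfusion here is dominated by
the vascular route. On a fixture this small the converged coupled IFP
is tiny — the per-vessel wall resistance dominates the collective
source interaction, which only flips at whole-tumour source counts
(see `docs/methods.md`, "Desk-scale regime") — but its radial profile
keeps the core-elevated shape:

```python
print(res.ifp_profile(n_bins=5).to_frame().to_string(index=False))
```

```
 r_norm     mean       sd   n
    0.1 0.000061 0.000001   6
    0.3 0.000058 0.000003  54
    0.5 0.000053 0.000004 154
    0.7 0.000046 0.000004 300
    0.9 0.000039 0.000004 476
```

A shell interface wraps the same pipeline:

```
tumorflow generate --seed 3 --out net/          # write a synthetic network
tumorflow run --network net/ --seed 3 --out out # full coupled run + artefacts
tumorflow sweep --network net/ --parameter sigma --values 0,0.25,0.5,0.75,1 --out sweep.csv
tumorflow normalize --network net/ --kappa --out norm.json
```

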
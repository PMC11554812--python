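# Methods

`myoperf` simulates blood perfusion of the left-ventricular wall during
maximal (hyperemic) vasodilation with a *compliant multi-compartment Darcy
model*: the intramural coronary vasculature is homogenized into three
porous compartments that coexist at every material point — small arteries
(diameters ≈ 100–500 μm), arterioles (≈ 8–100 μm) and capillaries
(≈ 4–8 μm) — each carrying its own pressure field p_i(x, t) on the same
domain Ω.

## Governing equations

For each compartment i = 1, 2, 3 on Ω with zero-flux outer boundary:

    −∇·(K_i ∇p_i) + (nL)_i C_i ∂(p_i − P_im)/∂t + Σ_j β_{i,j}(p_i − p_j) = θ_i

* `K_i` — Darcy permeability, `K_i = (κ/μ)·φ_i` with porosity
  `φ_i = (nL)_i A_i`;
* `C_i = dA_i/dΔp` — distensibility of the mean vessel cross-section A_i
  with respect to the transluminal pressure `Δp_i = p_i − P_im`;
* `β_{i,j} = (β_i + β_j)/2` for the hierarchically adjacent pairs (1,2) and
  (2,3), with the Poiseuille-network conductance `β_i = δ_i (nL)_i A_i²`;
  the non-adjacent pair (1,3) exchanges no mass (no artery→capillary
  anastomoses in a tree-like network);
* `θ₁` — arterial source: each epicardial outlet k injects its flow q_k
  uniformly over its perfusion territory Ω^k, `θ₁ = Σ_k χ^k q_k/|Ω^k|`;
  `θ₂ = 0`; `θ₃ = −γ(p₃ − p_ra)` is the venous return to right-atrial
  pressure.

The compliance term is where cardiac contraction acts: the intramyocardial
pressure P_im squeezes the vessels, and because A₂, A₃ shrink when Δp falls,
systole expels stored blood downstream (venous outflow peaks in systole)
while impeding arterial inflow (the systolic impediment / intramyocardial
pump).  The wall itself does not deform; contraction enters only through
P_im.

## Constitutive laws (hyperemic, fully passive walls)

Areas in mm², Δp in Pa:

* A₁ = 0.07 (rigid; C₁ = 0);
* A₂: logistic branch `0.0030 + 0.0050·σ(3.02·10⁻⁴ Δp)` for Δp < 0 joined
  at Δp = 0 to the logarithmic fit `0.0011 ln(1.2Δp + 3500) − 0.0033`
  (Δp ≥ 0 uses the logarithmic branch);
* A₃ = `10⁻⁶ + 2.4·10⁻⁵·σ(3·10⁻⁴ Δp + 0.5)`.

C_i is the exact analytic derivative of the implemented area law, not the
separately published rounded closed forms; this keeps the compliance term
the exact differential of the porosity.  The published formulas are retained
as a cross-check and agree within 2% (coefficient rounding).  The printed
coefficients leave a ≈ 3.1% value discontinuity between the two A₂ branches
at Δp = 0; we keep it (the laws are evaluated pointwise and the solver never
differentiates across the junction), and provide an optional C²-refit of the
sigmoid (`constitutive.refit_a2_sigmoid`) that restores value/slope/
curvature continuity for studies where smoothness matters.

Unit notes: dimensional analysis of the governing equations forces κ to
carry m² (stored value 1.75·10⁻¹⁰), δ_i to carry mm⁻²·s⁻¹·Pa⁻¹, γ to carry
Pa⁻¹·s⁻¹ and C_i mm²·Pa⁻¹; the numeric values are the published ones.  All
pressures are stored in Pa internally (1 mmHg = 133.322 Pa); constitutive
areas are evaluated in mm² with Δp in Pa exactly as the coefficient
magnitudes require; geometry is in mm and converted to SI inside the
assembler.

## Driving pressures

The ventricular pressure P_LV(t) is a parametric C¹ waveform: diastolic
baseline (default 8 mmHg) with a smoothstep rise (30% of the systolic
interval), a plateau at exactly the personalized peak pressure, and a
smoothstep relaxation fall (20% of the systolic interval, ≈ 53 ms at the
default period — a physiological isovolumic-relaxation time).  The two
personalization knobs are the peak pressure and the systolic fraction of
the period (defaults: 140 mmHg, 0.37, period 0.714 s).  The aortic inlet
waveform uses the same family with a nonzero diastolic floor (default
0.55·peak) and a decay extending into diastole; an optional affine
adjustment matches a prescribed mean, and tabulated waveforms can be
imported from CSV in place of the parametric family.

Phase splitting: "systole" for flow morphology is the *ejection* interval —
the bump support minus the terminal relaxation ramp — because the aortic
valve closes at the onset of relaxation while P_LV keeps decaying into early
diastole.  With the full bump support as systole, the early-diastolic
coronary refill surge would straddle the boundary and be misattributed.

P_im follows P_LV with a linear transmural profile: 0.9·P_LV at the
endocardium to 0.3·P_LV at the epicardium,
`P_im = [0.9 − 0.6 λ(x)]·P_LV(t)`.  The transmural coordinate λ solves a
Laplace problem (0 on the endocardial surface, 1 on the epicardial one,
zero-flux on the base), which reproduces the linear depth fraction exactly
on a slab and generalizes smoothly to curved walls.

## Geometry and territories

Idealized wall generators: a rectangular slab (endocardium z = 0,
epicardium z = top, lateral faces = base) and a half-ellipsoid shell
truncated at the equatorial plane.  Both produce structured tetrahedral
meshes via a face-consistent 6-tet decomposition; volumes are exact for the
slab and within the angular-faceting error for the shell.  Supplied meshes
are read from ASCII VTU or Gmsh MSH 4.1 with the three named surfaces.
All volumetric integrals use lumped (node-centred) volumes so conservation
statements are exact sums.

Each outlet k (position, radius r^k, optional lumped path resistance R_k) is
projected to its nearest mesh node and a radius-weighted eikonal distance
|∇d^k| = 1/r^k is solved as a Dijkstra shortest path on the mesh edge graph
with weights (edge length)/r^k — exact on the graph metric, deterministic,
and adequate at the default h = 1.5 mm (the graph-vs-continuum gap is a
mesh-refinement property).  Nodes join the territory of minimal modified
distance; ties break toward the lowest outlet id; larger feeding radii
claim proportionally larger territories.  A legacy radius-blind Euclidean
mode exists behind a flag for comparison only.

## Epicardial coupling (reduced outlet model)

The 3D epicardial tree is replaced by one lumped branch per outlet
honouring the porous-side coupling contract: the outlet flow is driven by
the gap between the aortic pressure and the territory mean of p₁ through
the coupling conductance α in series with R_k,

    q_k = (P_ao(t) − ⟨p₁⟩_{Ω^k}) / (R_k + 1/α),      α = 3·10⁻¹⁰ m³ s⁻¹ Pa⁻¹.

R_k defaults to 0 (healthy epicardial pressure drops are a few mmHg) and can
be raised per-outlet to emulate epicardial resistance or stenoses.
Retrograde flow is admissible.  Only the flux survives of the 3D model; no
velocity profiles, no FFR, no stenosis geometry.

## Discretization and solution

P1 tetrahedral finite elements; implicit pressures with all nonlinear
coefficients frozen at the previous time level (semi-implicit, first order,
Δt = 2 ms default); lumped (row-sum) quadrature for compliance, exchange and
sink terms.  The 3N system is symmetric positive definite (the venous sink
removes the Neumann null space) and is solved by sparse direct factorization
by default (problem sizes here are ≤ a few 10⁴ unknowns); a Jacobi-
preconditioned conjugate-gradient path is available (`solver="cg"`) and
agrees with the direct solve to 10⁻⁸.  Accepted solutions must satisfy
‖Mx − b‖/‖b‖ < 10⁻¹⁰.

**Conservative compliance accounting.**  The frozen product
(nL)C^n·Δ(Δp) is not an exact increment of φ, so summed around a periodic
cycle it leaves an O(Δt) bias (measured ≈ 1.5% of cycle inflow at Δt = 2 ms,
halving with Δt).  The stepper therefore tracks the accounted linearized
porosity φ̂^{n+1} = φ(Δp^n) + (nL)C^n·ΔΔp and feeds the committed defect
φ(Δp^n) − φ̂^n into the next right-hand side — the mixed-form conservative
linearization familiar from Richards-equation solvers.  The correction is
O(Δt²) per step, leaves the matrix untouched, and makes the accounted
storage telescope: inflow and venous outflow then balance over a periodic
cycle to the periodicity tolerance (measured ≈ 4·10⁻⁵ relative).

**Interface fixed point.**  Per step, outlet flows and the Darcy solve are
iterated with under-relaxation on the flows (η = 0.1, tolerance ε = 10⁻¹⁰ on
the normalized flow/pressure diffs, Euclidean norm for flows and volume-
weighted L² for pressures, s_max = 200).  The relaxed variable is the flow
because it is the stiffest interface quantity.  Because the coefficients are
frozen during a step, the per-step map is affine and converges geometrically
with factor |1 − η(1 + α·d⟨p₁⟩/dq)|; the step matrix is factorized once per
step and reused across iterations, and the flows are warm-started by linear
extrapolation from the two previous steps.

**Initialization and periodicity.**  The transient starts from the steady
rigid-coefficient solution at t = 0 and runs whole heartbeats until the
cycle-to-cycle volume-weighted L² difference of all nodal pressures falls
below 1% (configurable; ≤ 10 beats), reporting the last full cycle.

## Outputs

* Arteriolar flow β₁,₂(p₁ − p₂) and capillary flow β₂,₃(p₂ − p₃) per unit
  tissue volume (s⁻¹), with conductances at the solver's frozen time level;
* MBF: time-averaged capillary flow converted by
  `× 60 × 100 / ρ_tissue` to ml·min⁻¹·(100 g)⁻¹ (ρ_tissue = 1.05 g/ml;
  hyperemic non-ischemic values are ≳ 150);
* vessel diameters d_i = 2√(A_i/π) at the nodal Δp (the rigid A₁ = 0.07 mm²
  corresponds to d₁ ≈ 298.5 μm, not the ≈ 150 μm a mid-class artery would
  suggest — the printed area value is kept deliberately);
* transmural sample traces at requested depths via λ (depth interpreted
  through the wall's z-extent; intended for slab-like domains);
* flow-morphology ratios (systolic/diastolic peak and mean, mean/peak per
  phase) of the total inflow over the ejection window.

## In-silico studies

*Rigid comparison*: C_i ≡ 0 and A_i frozen at Δp = 0 makes every coefficient
constant; arterial inflow and venous outflow become instantaneously
identical and follow the aortic pressure (systolic peak), isolating the role
of vessel compliance in the phasic pattern.

*Sensitivity sweeps* vary κ (log-spaced 5·10⁻¹⁰…5·10⁻⁸), a homogeneous
scale on (nL)_i or δ_i (0.75×–2×), or per-compartment (nL) scale triples,
and summarize each run by global mean MBF, per-territory MBF variance,
phase-split mean inflows and mean arteriolar pressure.  Expected trends:
κ controls how strongly neighbouring territories communicate (regional MBF
variance falls as κ grows; the global mean barely moves); MBF grows
logarithmically-concavely with (nL); diastolic inflow is far more sensitive
to (nL) and δ than systolic inflow in absolute terms — the conductance gain
is partly cancelled in systole because (nL) also scales the compliance
squeeze.

## Synthetic study substrate — and what it does not show

Patient CT geometries and segmented coronary trees are out of scope.  The
experiments run on an idealized slab wall (default 60×60×10 mm ≈ 36 ml,
about a third of an LV free-wall volume, so each of the 4–8 synthetic
outlets feeds a territory of physiological size) with heterogeneous outlet
radii (0.6–1.5 mm) on a deterministic jittered grid.  The test and example
problem sizes (h = 5–6 mm, 3–6 beats) are chosen so the whole suite runs on
a laptop-class single core; they resolve the transmural direction with only
3 layers, so transmural statements are qualitative sign checks, not resolved
profiles.  Passing tests demonstrate the mechanisms (phasic flow, systolic
impediment, territory control of MBF heterogeneity), not patient-level
numbers: absolute MBF and pressure means depend on geometry, outlet layout
and the imported waveforms.

## Known limitations

* No autoregulation or vascular tone: the constitutive curves are hyperemic
  only; rest-state perfusion would need different A_i(Δp) laws.
* No poromechanics: Ω is fixed; contraction acts only through P_im.
* Uniform vessel properties across the wall (no subendocardial capillary
  densification); scalar (isotropic) permeabilities.
* The 0D outlet surrogate carries no wave propagation or epicardial volume;
  timing offsets between aortic and ventricular waveforms are a configurable
  lag, default 0.
* First-order time accuracy; Δt = 2 ms resolves the default waveform, but
  morphology ratios shift by a few percent under Δt refinement.
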
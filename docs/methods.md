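# Methods

`vfsim` couples a quasi-one-dimensional unsteady glottal flow model to a
finite-strain finite-element model of the layered vocal fold, on a
parameterized synthetic rabbit larynx. This note records the model
equations, the numerical choices, the defaults and why they were chosen,
and what the synthetic setup can and cannot say about real larynges.

## Tissue model

The vocal fold is isotropic Saint Venant–Kirchhoff hyperelastic: with
deformation gradient F and Green–Lagrange strain E = (FᵀF − I)/2, the
second Piola–Kirchhoff stress is

    S = λ tr(E) I + 2μ E,

objective under large rotations. Two layers carry distinct Young's moduli:
a stiff *body* (E_b, tens of kPa) and a compliant superficial *cover*
(E_c, single-digit kPa); Poisson ratio ν = 0.3 and density
ρ_s = 1000 kg/m³ for both. Elements whose centroid lies within
`cover_thickness` of the lumen surface are cover, the rest body.

Discretization: 4-node linear tetrahedra with single-point quadrature
(exact for the constant-gradient element). Internal forces assemble
∫ F·S : ∇N; the consistent tangent (material + geometric parts) is
assembled analytically into a precomputed CSR pattern. Mass is lumped
(row-sum), so the assembled mass equals ρ_s × volume exactly.

Dynamics: implicit Newmark (average acceleration, β = 1/4, γ = 1/2) with
Newton iteration on the nonlinear residual. The Jacobian is dominated by
the mass term M/(β Δt²), so a cached factorization is reused across Newton
iterations and coupling sub-iterations and refreshed only when the
iteration contracts poorly; the residual itself is always exact, so the
converged states are unaffected. Newton tolerance is 1e-9 relative to a
force scale, with a stagnation exit at the round-off floor (needed when
the tissue is made quasi-rigid for limiting cases). With zero damping the
integrator conserves a small-amplitude vibration's energy to better than
0.1% over 100 periods (verified in the test suite).

Damping is Rayleigh, C = α M + β_R K_t(u). Default α = 0,
β_R = 3e-5 s, i.e. ζ ≈ 6% of critical at the ~650 Hz phonation frequency.
This is deliberately at the upper end of "light": fold *contact* is not
modeled (closure is handled on the fluid side, below), so the
collision-bound limit cycle must be bounded by tissue dissipation to keep
the thin cover elements from inverting when the folds interpenetrate. A
few percent of critical damping is also the physiological range for
vocal-fold tissue.

Fluid pressure acts as a follower load on the deformed lumen surface
(−p·n dS with the instantaneous normal); its load stiffness is neglected
in the Newton Jacobian, which only affects the iteration path.

## 1D glottal flow

On axial stations x with prescribed cross-sectional area A(x, t) the model
solves

    ∂A/∂t + ∂(Au)/∂x = 0,
    ρ ∂u/∂t + ρ u ∂u/∂x = −∂p/∂x + ∂τ/∂x,

with constant inlet pressure P_in and outlet pressure P_out = 0. Air
density is ρ = 1.0 kg/m³ and the effective viscosity is four times that of
air (μ_eff = 7.2e-5 Pa·s), lowering the Reynolds number — both stated
conventions of the modeling tradition this follows.

Incompressibility makes continuity integrable: Q(x) = Q_in − ∫₀ˣ ∂A/∂t dx′
exactly (the discrete form uses the trapezoid rule, so the conservative
cell residual is zero to round-off). The single unknown per step, the
inlet flux Q_in, solves the momentum balance integrated from inlet to
outlet with a scalar Newton iteration; the unsteady (air-column
inertance) and viscous terms are implicit, so there is no stiff stability
limit. An advective CFL guard (default limit 5) rejects grossly
oversized steps.

The loss term τ is a pluggable closure (`LossModel`) because its original
closed form is a machine-learned function not reproducible here. The
physics-based default:

- **Viscous loss**: plane-Poiseuille gradient of a rectangular slot,
  dτ = −C_v μ_eff u / D_h² dx with C_v = 12 (D_h/gap)², which reduces to
  the exact lubrication limit 12 μ u / gap² in the narrow glottis and is
  negligible in the wide duct.
- **Separation rule**: downstream of the minimum-area station, the jet is
  assumed detached at the first station whose wall divergence angle
  exceeds 10°. Past that station no pressure is recovered: the convective
  (Bernoulli) head is frozen at its separation value, and wall friction is
  dropped (the jet no longer touches the walls). The *unsteady* term keeps
  acting over the whole duct, so the supraglottal air column retains its
  inertance. This last point is essential: pinning p = P_out from the
  separation station (a tempting simplification) removes the inertive
  supraglottal load and the coupled system then cannot self-excite at
  realistic driving pressures.
- **Entrance correction**: an effective-area factor on the contraction
  segment, default 1.0 (off); the hook accepts learned non-dimensional
  functions of Reynolds number and shape descriptors.

Reported station velocity downstream of separation is the jet-core value
(flux over the frozen separation-station area, capped by the local duct
area), so the reported total pressure p + ρV²/2 is non-increasing along
the jet; the area-averaged velocity is kept separately for the momentum
integrals. In the steady limit the model reduces exactly to the Bernoulli
closed form with p = P_out beyond separation.

## Synthetic larynx geometry

The generator replaces unavailable MRI reconstructions with an idealized
bilateral fold in a straight rectangular duct (x axial, y
anterior–posterior, z lateral), retaining the anatomical features that
drive the interaction: a long, gently converging inferior surface (30°
from the axis), a short flat glottal tip, a steeply diverging (55°)
superior surface, an inclined fold plane (θ up to 60° from the transverse
axis), anterior–posterior taper of the gap (the posterior glottis never
fully closes), and a rigid downstream ventricle, false vocal fold and
supraglottal expansion that enter through the lumen area profile.

The mesh is a structured hex grid split into tetrahedra (6 per hex),
mirrored exactly in z for the two folds, graded toward the medial surface
(exponent 1.6) so the compliant cover stays resolved even at coarse
resolution. Exterior faces are fixed; the medial surfaces are the loaded
(lumen) boundary.

Cross-sections inside the fold are taken on planes that follow the fold
inclination (the deterministic stand-in for streamline-normal planes); a
plane normal to the duct axis never sees the full oblique constriction
and overestimates the minimum area several-fold at realistic θ. The
arc-length coordinate is the mid-span axial position. An area floor
(default 1% of the rest glottal area) represents incomplete closure.

**Default dimensions** (all overridable): duct 8 mm (lateral) × 6 mm
(anterior–posterior), fold tip+superior extent 2.6 mm, rest half-gap
0.12 mm (an *adducted* rest state, as in the surgically approximated
experimental preparation), cover thickness 1.4 mm, false-fold half-gap
0.8 mm, ventricle 1.5 mm. The reasoning behind these numbers: the
source experiments tuned tissue moduli so a model on the true geometry
matched each animal's observed frequency; here the geometry is the free
quantity instead, so the dimensions were set — once, via a no-flow
ringdown probe of the medial-surface resonance and linear modal analysis —
so that the tabulated Sample-3 moduli (E_b = 80 kPa, E_c = 8 kPa) place
the phonation frequency in the measured rabbit range (~500–600 Hz,
5–6 cycles per centisecond) and the fold self-excites at the tabulated
720 Pa inlet pressure. The five sample presets carry the published
per-sample inlet pressures, layer moduli, and inclination angles.

What the synthetic geometry does *not* emulate: the curved, anteriorly
skewed supraglottal channel (so no jet impingement losses or
anterior–posterior flow asymmetry), subject-specific cross-sectional
shapes, and fold collision mechanics. Passing tests therefore validate
the numerics and the qualitative self-oscillation physics, not
subject-specific predictions.

## Partitioned coupling

Each time step sub-iterates: lumen-profile extraction from the current
interface displacement → 1D flow solve (with dA/dt taken as the discrete
(A_k − Aⁿ)/Δt, which keeps the continuity bookkeeping consistent) →
pressure mapped to lumen facets by arc-length interpolation → implicit
solid step → Aitken dynamic under-relaxation of the interface
displacement, until the relative interface change falls below 1e-6 (or an
absolute 1e-12 m floor). The separation station is evaluated on the first
sub-iteration and pinned for the rest of the step: the discrete index
jump otherwise makes the fixed point non-smooth and the iteration can
orbit instead of contracting. A stagnation fallback strengthens the
under-relaxation if the residual stops improving. Typical cost is 3–4
sub-iterations per step.

Runs start from rest with the inlet pressure ramped over 1e-4 s by a
half-cosine — short enough to preserve the violent first opening while
avoiding a discontinuous impulsive start. The reference time step is
1e-6 s (1e-4 centiseconds); desk-scale runs use 1e-5 s with the implicit
integrator, ~150 steps per vibration cycle.

Recorded per run: marker lateral displacement (medial-surface node
nearest mid-span, mid-gap; node id stored), minimum glottal area, inlet
flux, fluid-to-tissue power Ė = Σ(−p n)·v dS and its trapezoidal
integral E, kinetic and strain energy, accumulated Rayleigh dissipation,
sub-iteration counts, and pressure-profile snapshots. The energy ledger
closes: over 2 ms windows the fluid work matches Δ(kinetic + strain) +
dissipation to ~0.01% of the peak strain energy.

## Post-processing

- **Fundamental frequency**: magnitude spectrum of the mean-removed
  marker trace, full window, no padding; the fundamental is the largest
  non-DC bin (ties to the lowest frequency), optionally refined by
  maximizing the continuous-frequency DTFT magnitude near the peak.
- **Power transfer**: Ė = ∫ f·v dS with per-facet power density
  returned for surface maps; the 1D-driven pipeline supplies
  pressure-only tractions, but the interface accepts general (shear +
  normal) traction fields for other flow backends.
- **Total pressure**: p + ρV²/2 per station.
- **Profile comparison**: two pressure profiles are resampled on a common
  arc-length grid; max and RMS differences (absolute and normalized by
  P_in) are reported with the segment (inferior / glottal gap /
  supraglottal) of the maximum.

## Known limitations

- No fold contact: interpenetration is handled only by the flow-side area
  floor, so limit-cycle amplitudes (and the energy they dissipate) are
  larger than in a contact-resolved model. In particular, at the Sample-3
  drive the accumulated work E climbs steadily (per-cycle input ≈ tissue
  dissipation ≈ 40% of the startup work) instead of the near-elastic
  plateau a lightly damped, contact-limited fold exhibits; reproducing
  that plateau requires operating near phonation onset, which conflicts
  with the tabulated driving pressure on this idealized geometry.
- The coupled oscillation rides ~10–20% above the linear modal frequency
  (finite-strain stress stiffening under the static load plus closure
  nonlinearity); frequencies quoted from linear modal analysis are lower
  bounds.
- The quasi-1D flow sees only area, not cross-sectional shape; all
  3D-flow phenomena (vortices, jet skewness, lateral asymmetries) are out
  of scope.
- Left–right symmetric configurations only.
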
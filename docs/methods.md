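# Methods

`uterosim` is a forward electromagnetic model of pregnant-uterus
contractions: it simulates the propagation of the myometrial transmembrane
potential and computes the surface electromyogram (EMG) and magnetomyogram
(MMG) it generates at the abdomen.  This note documents the model, its
assumptions, the numerical choices, and the places where our implementation
deviates (deliberately, and with analysis) from the published parameter
tables it reproduces.

## Model overview

The pipeline has three quasi-static steps on a four-compartment spherical
volume conductor — fetus F, amniotic cavity U, myometrium M (a spherical
shell), abdomen A (an offset sphere):

1. **Monodomain reaction–diffusion** for the transmembrane potential
   v_m(r, t) on M:

   ∇·( ς/(ς+1) G_e′ ∇v_m ) = a_m c_m ∂v_m/∂t + a_m (J_ion − J_stim),

   with no-flux boundaries and resting initial conditions.  This is the
   equal-anisotropy-ratio reduction of the bidomain equations
   (G_i′ = ς G_e′).

2. **Volume-conductor solve** for the interstitial/abdominal potential φ:
   ∇·( (ς+1)/ς G_e′ ∇φ ) = −∇·(G_e′ ∇v_m) in M, Laplace with isotropic
   conductivities in U and A (and F when the vernix switch λ ≠ 0),
   potential and normal-current continuity at the internal interfaces,
   no flux through the abdominal surface, and no flux through the fetal
   surface when λ = 0 (insulating vernix caseosa).  Quasi-statics makes
   every time instant an independent elliptic solve.

3. **Currents and magnetic field**: the impressed current density is
   J_s = −G_i′∇v_m (nonzero only where tissue is de- or repolarizing);
   the total current adds the ohmic return currents.  B is evaluated by
   Biot–Savart volume quadrature over the element-wise currents.  Under
   quasi-statics this is equivalent to solving ∇×(B/μ₀) = J with decay at
   infinity and avoids meshing an air box around the body.  The MMG signal
   is ⟨B, n̂_A⟩ at each sensor.

### Ionic model

The cell model is a two-variable modified FitzHugh–Nagumo system tuned to
the plateau-type action potential of human myometrium at term:

    J_ion = −(1/ε₁)[ k (v_m−v₁)(v₂−v_m)(v_m−v₃) − w ],
    ∂w/∂t = ε₂ (β v_m − γ w + δ).

Defaults (SI): ε₁ = 200 Ω·m², ε₂ = 0.09 s⁻¹, k = 10⁴ V⁻², v₁ = −20 mV,
v₂ = −40 mV (the excitation threshold), v₃ = −65 mV, δ = 52 mV, γ = 0.1,
β = 1, c_m = 0.01 F/m², v_mr = −56 mV, and a_m = 4/d + 2/l = 5.7587×10⁵ m⁻¹
for a closed-cylinder myocyte of diameter 7 µm and length 450 µm.
Pacemakers enter as J_stim = (1/ε₁) Σ νᵢ hᵢ(r, t) with indicator-like
supports; the reference pacemaker is a fundal cap (0.15 ≤ ‖r‖ ≤ 0.16 m,
z ≥ 0.15 m) active for 0.1 s with ν = 2 V.

**Units.**  The J expressions above evaluate to membrane-referred current
densities (A/m²; ε₁ is a membrane resistivity).  The tissue-level balance
needs volume densities (A/m³), which is the surface-to-volume factor a_m
made explicit in the monodomain equation; in the space-clamped (0D)
reduction a_m cancels:  c_m dv_m/dt = −J_ion + J_stim.  This is the only
dimensionally consistent reading, and the only one that reproduces the
reported dynamics (plateau tens of seconds, re-excitation on the minutes
scale).

With the recovery variable frozen on its nullcline at rest,
w₀ = (β v_mr + δ)/γ = −40 mV, the zeros of J_ion solve

    (v−v₁)(v₂−v)(v−v₃) = (β v_mr + δ)/(kγ),

whose roots for the defaults are exactly v₁* = −60.000 mV,
v₂* = −48.508 mV, v₃* = −16.492 mV: the resting branch, the threshold, and
the excited (plateau) branch.  Note the *full* 2D system's equilibrium is
v ≈ −57.0 mV, slightly below the nominal resting potential, so an
unstimulated tissue drifts a millivolt down from v_mr; this matters when
defining "return to rest" (below).

### Conductivity design

Extracellular conductivities come from Archie's law,
σ̃_e = σ_ℳ/(1−p)^m with bulk σ_ℳ = 0.5 S/m, myocyte volume fraction
p = 0.6 and cementation factor m = 4/3 (long thin cylinders), and from a
cubical-grid blocking model:

    σ_el = σ̃_e (1 − π d²/(4 d_T²)) = 0.68 S/m,
    σ_et = σ̃_e (1 − d l/(d_T l_T)) = 0.22 S/m,

with grid pitches d_T = d + 2Δ_e, l_T = l + 2Δ_e, Δ_e = 0.5 µm.
Compartment conductivities: G_A = G_F = 0.2 S/m, G_U = 1.74 S/m (amniotic
fluid).

Fiber tensors are cylindrically symmetric,
G′(r) = (σ_l − σ_t) a₃a₃ᵀ + σ_t I, with the fiber direction a₃(r) designed
from a layer description f(r) = 0 and a fundus-to-cervix curve of symmetry:
t̂₁ (meridional) and t̂₂ = t̂₁×n̂ (circumferential) span the tangent plane
and a₃ = t̂₁cos α + t̂₂sin α.  The sign branch is fixed by ⟨t̂₁, k̂⟩ > 0
with the curve parametrized fundus→cervix, so α = 0 gives fibers running
from the fundus toward the cervix.  On the axis of symmetry the frame is
singular and a₃ = 0, i.e. a point of isotropic conductivity σ_t I.  The
spherical closed form was re-derived from the axis-aligned matrix
construction (the package cross-validates all three construction routes to
1e−8).  The default fiber angle is α = 45°, a compromise between the
circular and oblique fiber populations of the uterine wall.

### The anisotropy ratio and a documented inconsistency

The intracellular tensors are G_i′ = ς G_e′.  ς is calibrated so the
monodomain front along the fiber travels at a prescribed speed c.  The
traveling-wave ansatz v_m(ξ·r − ct) with w frozen at rest gives the
classical bistable front speed

    c = sqrt(Ã D / 2) (v₁* − 2v₂* + v₃*),
    D = (ς/(1+ς)) σ_el/(a_m c_m),   Ã = k/(ε₁ c_m),

hence ς = g(x), g(x) = x/(1−x),
x = 2c²ε₁ a_m c_m² / (σ_el k (v₁*−2v₂*+v₃*)²), valid for
ε₁ < σ_el k (v₁*−2v₂*+v₃*)² / (2c² a_m c_m²) (otherwise ς < 0).
`anisotropy_ratio` implements this closed form; `calibrate_varsigma_numeric`
is an independent bisection oracle that matches the *measured* speed of a
1D cable simulation.  The closed form is exact in the frozen-recovery limit
(verified to <1% with ε₂ reduced 10×); at the physiological ε₂ = 0.09 s⁻¹
the measured front runs ≈10% faster than the formula because the medium
ahead of the front slowly drifts off the nominal resting state.

**Inconsistency.**  With the default parameter set the admissible interval
is ε₁ ∈ (0, 187) Ω·m², which the default ε₁ = 200 violates at
c = 1.15 cm/s — equivalently, the maximum attainable monodomain front speed
is ≈1.11 cm/s (analytic; ≈1.2 cm/s measured), reached only as ς → ∞.  The
reference value ς = 0.8 and the reference speed c = 1.15 cm/s are therefore
mutually inconsistent for this parameter set: with ς = 0.8 the model
propagates at 0.74 cm/s (analytic) / 0.82 cm/s (measured, converged under
h- and dt-refinement).  We keep the model faithful, run the reference
configuration at ς = 0.8, and report the speed the equations actually
produce; the package raises a calibration error (naming the admissible ε₁
interval) if asked to derive ς at 1.15 cm/s.

## Numerics

* **Meshing** is an internal deterministic generator: 1D cables, 2D
  annuli, and 3D balls/shells built by radially extruding a subdivided
  icosahedral sphere triangulation, prisms split into tetrahedra with a
  global-min-index diagonal rule (conforming across neighbours).
  Compartment interfaces coincide exactly with mesh layers; the abdominal
  band is warped along each ray so the outer boundary lies exactly on the
  offset abdominal sphere.  The uterine wall always gets ≥2 element layers.
* **Spatial discretization**: P1 simplicial FEM, lumped mass by default.
  The stiffness null space is exactly the constants (no-flux).
* **Time stepping**: IMEX — implicit (backward-Euler) diffusion with a
  one-time sparse factorization, explicit cubic reaction, exact exponential
  update of the linear recovery variable.  Default dt = 10 ms; a blow-up
  guard (|v_m| > 1 V) raises a stability error advising a smaller step.
  Halving dt or h changes the measured front speed by <0.5%.
* **0D integrator**: stiff multistep (BDF) by default; a fixed-step
  implicit-midpoint integrator (default dt = 1 ms) is provided for
  convergence studies.
* **Elliptic solves**: one conforming discretization across compartments
  (potential continuity by construction, flux continuity weakly), pure
  Neumann system gauged by a zero-mean constraint over the abdominal
  surface nodes via a bordered Lagrange system, factorized once per mesh
  and reused across time snapshots.  λ = 0 removes the fetal interior from
  the solve (its nodes report NaN); λ ≠ 0 includes it with G_F.
* **Biot–Savart**: element-midpoint quadrature of J × r/r³; element
  contributions within half an element diameter of an observation point
  are excluded (with a warning) — sensors belong outside the conductor.
* **Front speed measurement**: linear fit of −40 mV upstroke arrival times
  over the central 50% of the cable (R² reported, warn below 0.95).
* **Waveform metrics**: duration is the time between the upward and
  downward crossings of the resting level; the plateau window runs from
  the peak to the onset of rapid repolarization, detected when the trace
  falls >5 mV below its own value 2 s earlier (the slowly declining
  plateau stays within that band).
* **Refractory period**: two identical pulses (ν = 2 V, 0.1 s) in the 0D
  model, bisected to 1 s.  A response counts as a full AP when v_m had
  returned below rest before the second pulse and the *post-offset* peak
  (1 s after the stimulus ends) is within 5 mV of the unconditioned AP's.
  The raw maximum is stimulus-dominated (the pulse forces v_m up ~70 mV
  regardless of recovery), so the post-offset peak is the discriminating
  measure.

## Verification

The suite validates the solver stack against independent closed forms:
current-loop field μ₀I/(2R) (<1%); surface potential of a dipole in an
insulated homogeneous sphere against the Legendre series (<2%, via a
singularity-subtracted solve); the external magnetic field of a tangential
dipole in a spherical conductor against the closed-form spherical-conductor
solution (<5%, with a compact smooth source standing in for the point
dipole); magnetic silence of radial sources (<1% of the tangential
reference); zero net B-flux through a closed sensor sphere; conservation of
the mass-weighted mean of v_m under pure diffusion; annihilation of
counter-propagating fronts; and bit-identical reruns.

## Problem sizes

Everything runs at desk scale: the waveform/speed quantities use a 20 cm
1D cable (401 nodes, h = 0.5 mm, dt = 10 ms, probe at 10 cm) — these are
converged values, see above.  The 3D demonstration of the contracting
spherical shell uses a radius-4 cm shell (≈31k tetrahedra) so the ~3 mm
front width is resolved; the full paper-size geometry is supported and
used (coarsely) to exercise the potential/field pipeline.  The
contracting-volume-fraction curve of the scaled shell is a single,
approximately symmetric transient, saturating at 100% because the wave
transit time (~15 s) is shorter than the AP duration; on the full-size
uterus (transit ~60 s) the same curve peaks below saturation.

## What the reference configuration reproduces — and what it does not

Measured by this package (see `scripts/acceptance.py`):

* peak depolarization −17.0 mV (reference −16 mV) — reproduced;
* plateau mean −20.6 mV (reference −25 mV) — the plateau declines from
  −16.5 mV (excited branch) to −28.7 mV (repolarization knee) spending
  most time near the top; no window consistent with the stated plateau
  definition averages to −25 mV;
* duration before hyperpolarization 28.4 s on the cable, 31.1 s in 0D
  (reference ≈35 s);
* refractory interval 49 s under the 5 mV criterion (reference 240 s —
  which matches *complete* relaxation of w, numerically stationary at
  ≈240 s ≈ 2.2/(ε₂γ); a zero-tolerance peak criterion gives ≈135 s);
* front speed 0.82 cm/s at ς = 0.8 (reference 1.15 cm/s — see the
  inconsistency analysis above).

## Limitations

Spherical uterus and fetus only (no pear-shaped or image-derived
geometry); single homogeneous wall layer; constant fiber angle unless a
spatial α function is supplied; equal anisotropy ratios (no independent
intra/extracellular tensors, no full bidomain time integration); no Ca²⁺
dynamics, bursting, or pressure/force generation; no sensor noise or
gradiometry.  The synthetic study conditions exercise wave initiation,
propagation, anisotropic current generation and field projection — they do
not emulate inter-subject anatomical variability, tissue heterogeneity, or
measurement noise, so passing tests validate the forward physics, not
clinical discrimination.
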
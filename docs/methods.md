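# Methods

This note documents the models implemented in `cytomech`, the choices made
where the design was genuinely open, and what the test suite does and does
not establish.

## Unit system

Lengths in μm, moduli and pressures in MPa, forces in μN (1 MPa·μm² = 1 μN),
time in s.  This micro-scale system keeps all quantities within a few orders
of magnitude of unity and avoids underflow in the truss assembly.  Curve
files exchange forces in nN (1 μN = 1000 nN); every column and config key
carries its unit in its name (`E_MPa`, `force_nN`, `tau_sigma_s`).

## Materials

Each of the five subcomponents (cytoplasm, microtubules, microfilaments,
membrane, nucleus) carries a linear-elastic pair (E, ν).  The equivalent
compressible Neo-Hookean parameters use the convention C10 = μ/2 and
D1 = 2/K, i.e.

    C10 = E / (4 (1 + ν)),      D1 = 6 (1 − 2ν) / E,

which reproduces all twenty tabulated (C10, D1) pairs of the two reference
cell types within 0.3% (the tables round inputs to three significant
figures; the package compares at 1% tolerance).  ν = 0.5 maps to D1 = 0 and
is flagged incompressible rather than rejected.  The inverse conversion is
exact algebra on (μ, K), so the round trip is the identity to machine
precision.

Only the cytoplasm is viscoelastic: a standard linear solid with relaxed
modulus E_R (= k₁), relaxation times τ_σ (constant load) and τ_ε (constant
deformation), relaxation modulus

    E(t) = E_R (1 + (τ_σ − τ_ε)/τ_ε · exp(−t/τ_ε)),

instantaneous modulus E₀ = E_R τ_σ/τ_ε and Maxwell arm
k₂ = E₀ − E_R, η = k₂ τ_ε.  The long-term modulus is implemented verbatim in
its source convention E_∞ = E_R (1 + ν), which mixes Poisson's ratio into a
time-domain modulus (it descends from an indentation-specific reduction);
because that convention is debatable, `sls_derive` exposes
`einf_convention={"as_printed", "shear_consistent"}`, defaulting to
as-printed.  Admissibility τ_σ ≥ τ_ε > 0 (non-negative Maxwell spring) is
enforced at construction.

The two reference sets differ by the cytoplasm stiffness ratio
Q = E₁/E₂ = 12.78 (printed value; the ratio of the rounded table entries is
12.8, 0.16% away).  `scale_set` multiplies or divides the non-fixed roles'
moduli by Q and re-derives their Neo-Hookean pairs; which roles stay fixed
is an explicit argument (default: cytoplasm) because the published mixed
sets keep the cytoplasm of the *starting* type rather than of the target
type, and an explicit argument avoids guessing.

## Geometry

The cytoskeleton is the 6-strut/24-cable expanded-octahedron ("Jessen")
tensegrity: 12 nodes at the cyclic sign permutations of (0, ±1, ±2) scaled
by u = R_cell/√5, so every node lies on the cell sphere (the lattice is
inscribed in the full sphere; whether the source inscribed it in the
truncated adherent shape is unstated, and the sphere is the simpler
well-defined choice).  Struts join the pairs differing only in the sign of
the "±2" coordinate (length 4u, three mutually orthogonal parallel pairs);
the 24 edges of length √6·u are the cables; cable/strut length ratio √6/4.
Cross sections are 190 nm² (struts) and 18 nm² (cables), stored in μm².

Two reference orientations are exposed.  `config1` is the canonical frame,
with one strut pair parallel to the loading (z) axis and its nodes nearest
the poles.  `config2` is `config1` rotated 45° about a **transverse** (x)
axis.  A rotation about the loading axis itself — the naively symmetric
choice — provably leaves both virtual experiments invariant (plane
indentation along z and axisymmetric aspiration about z are covariant under
any z-rotation), so it cannot represent "a different disposition"; the
transverse rotation genuinely changes which junctions face the indenter or
pipette.  An arbitrary extra rotation matrix can be supplied to explore
other dispositions.

The adherent-cell outline (16 μm sphere truncated at 14 μm height) gives a
substrate contact radius √(R² − (h − R)²) = √28 ≈ 5.29 μm; the source quotes
"about 6 μm" for the same numbers, a discrepancy worth knowing about when
comparing contact radii.  The height precondition is 0 < h ≤ 2R (a
hemispherical or flatter cap is admissible).

## Tensegrity statics

Without prestress the lattice is a mechanism, so form finding comes first:
the self-stress is the null space of the nodal equilibrium matrix in the
force-density variable (SVD).  For this topology the null space is
one-dimensional with density ratio strut:cable = −3/2 and member-force ratio
|F_strut|/|F_cable| = √6.  `apply_prestress` scales that self-stress so the
cables carry a chosen tensile prestrain (default 0.01 — no experimental
value for cytoskeletal prestress magnitude is established, some prestress is
mandatory for stiffness, and 1% cable strain keeps all members comfortably
linear; the value is recorded in every output) and stores rest lengths
L₀ = L/(1 + N/EA), which makes the built geometry an exact equilibrium.

The solver is an incremental Newton–Raphson on the 36 nodal coordinates with
the exact material + geometric tangent

    K_m = (EA/L₀) n nᵀ + (N/L)(I − n nᵀ)

per member, tension-only (bilinear) cables — zero force and stiffness when
slack — and a residual-norm line search with step halving.  Defaults: 50
increments, Newton tolerance 1e-10 μN, 60 iterations per increment.  The
assembled tangent matches the central-difference Hessian of the total strain
energy to better than 1e-6 relative, and every converged solution balances
reactions against applied loads to below 1e-8 μN.

Strut Euler buckling is *not* modelled: struts stay linear in compression,
and `apply_prestress` emits a `StrutBucklingWarning` whenever a strut force
exceeds the Euler floor π²EI/L² (with I = A²/4π for a solid circular
section).  With real microtubule cross sections this warning fires already
at the default prestrain — real microtubules do buckle — so it is a flag on
interpretation, not an error.

Degenerate tangents are handled in two regimes.  An *unprestressed*
mechanism (no rest lengths, no regularization floor) raises
`SingularSystemError`, detected by condition number since rounding keeps the
matrix formally invertible.  On a *prestressed* path the tangent can pass
through isolated singular points (slack-cable mechanisms, critical points of
the symmetric branch under deep indentation); there a small Tikhonov shift
(1e-8 of the mean diagonal, grown as needed) is applied to the Newton
direction only — convergence is always judged on the true residual.

**Indentation** is a rigid plane descending from the highest junction;
junctions crossed by the plane are displaced straight down with it (they
ride with the indenter — no transverse slip).  This choice, besides being
the plain reading of "displaced downward by δ", keeps the response
refinement-invariant: leaving the transverse components free makes the
symmetric configuration lose stability near 1.3 μm depth (compressed struts
push the contact nodes sideways once their cables slacken), and the computed
branch then depends on step size.  With the riding contact, 50 vs 400
increments agree to ~1e-9 relative over the full 1.5 μm sweep.  Support:
the 4 lowest junctions are fully fixed, mimicking focal adhesion sites
(exposed as an option).

**Aspiration** loads every junction with radial distance < R_p on the
aspirated side with an equal share of the total suction force ΔP·πR_p²,
and fixes the 4 lowest junctions.  (Fixing only the opposite-pole pair
leaves a rigid rotation about their chord.)  With the default geometry the
junction radii are u ≈ 3.58, 2u and √5·u μm, so pipettes with
D_c/D_p ≥ 3 (R_p ≤ 2.67 μm) contain no junction: the load set is empty, an
`EmptyLoadWarning` is emitted, and the cytoskeleton contributes nothing —
which is itself the model's statement about how pipette size gates
cytoskeletal engagement.

## Virtual experiments

The AFM protocol ramps the indenter at 9.5 μm/s to 1.5 μm and holds for
60 s; MPA ramps pressure linearly over 1 s and holds for 60 s at ratios
D_c/D_p ∈ {1.5, 2, 3, 4, 5.5}.  The explicit-dynamics transients of a full
FE treatment are replaced by quasi-static evolution, consistent with the low
loading rates (ramp times well below the relaxation times).

The CM-AFM force generalizes the step-relaxation closed form to the finite
ramp through the hereditary integral with the SLS kernel; δ^{3/2}(s) is
piecewise-linear on an internal grid (512 ramp intervals plus all sample
times) and each interval convolves with the exponential kernel in closed
form, so output sampling does not perturb the integral.  At the default
9.5 μm/s the hold-phase force differs from the ideal step form by ≤0.35%
(ramp time 0.158 s against τ_ε = 9.5 s); the step form is recovered exactly
in the infinite-rate limit.  The loading denominator follows the relaxation
convention (1 − ν); the Hertz loading form keeps its (1 − ν²) — both appear
verbatim in the source formulations and a `denominator` option can force
either.

The CM-MPA length applies Boltzmann superposition of the single-exponential
creep compliance over the pressure ramp, in closed form; a zero-duration
ramp reproduces the creep equation exactly and the long-time asymptote is
ramp-independent.  Mapping the cytoplasm SLS onto the creep constants is not
uniquely prescribed; the package uses E₁ = E_R, E₂ = k₂, τ = τ_σ (relaxed
spring, Maxwell spring, constant-load time constant — the natural creep-side
identification) and exposes the constants directly for users who prefer
another mapping.

**CTM coupling is parallel**: for AFM the tensegrity indentation reaction at
the instantaneous depth is added to the continuum force; for MPA the secant
axial stiffness of the aspirated junctions (total load over mean axial
junction displacement, a documented heuristic) adds to the continuum secant
stiffness, L = F/(F/L_cm + k_cs).  Parallel coupling is the only
reduced-order coupling that preserves both components' individual
calibrations, and it is declared in every CTM output's metadata.  Its known
limitation: because the lattice and the continuum share the full imposed
displacement, the cytoskeletal share is much larger than in a tied
finite-element embedding (hundreds of nN against a few nN of continuum force
at 1.5 μm), and scaling all member moduli by Q scales the lattice force
exactly by Q.  Consequently CM/CTM comparisons here are *directional* —
CTM stiffer in AFM, CTM aspirating less in MPA, orientation- and
pipette-size-sensitivity — and the empirically reported asymmetry that
*softening* the cytoskeleton matters more than stiffening it cannot emerge
from a parallel coupling (it requires the series compliance of the continuum
around the embedded lattice).  Membrane and nucleus enter only through the
material tables and Q-scaling sweeps, not as separate mechanical layers.

## Inverse fitting

Three model objects follow the model/results idiom (`fit()` returns a
results object with estimates, standard errors, covariance and a
`summary()` table):

* **Hertz loading** — linear least squares in E (closed form).
* **SLS relaxation** — trust-region least squares in
  (E_R, log τ_ε, Δτ ≥ 0) with τ_σ = τ_ε + Δτ, which enforces admissibility
  by construction; degenerate (constant-force) records drive Δτ → 0.
  Initialization from the record's asymptotes (E_R from the tail, the
  instantaneous/relaxed ratio for Δτ/τ_ε), with 5 multi-starts spread over
  a decade in τ_ε; tolerances 1e-12.  Records shorter than ~2 τ_ε are
  flagged as weakly identifying rather than rejected.
* **Aspiration creep** — the same machinery in (E₁, E₂ ≥ 0, τ), initialized
  from L_p(0⁺) and L_p(∞).

Uncertainties are Jacobian-based (σ²(JᵀJ)⁻¹ at the optimum, delta method for
the reparameterization); a seeded residual bootstrap (200 resamples by
default) is available behind a flag.  Closed-loop tests recover 25 random
admissible parameter draws per model to better than 1e-4 relative from
noise-free records, and the tabulated reference parameters within 10%
(relaxation) / 15% (creep nuisance parameters) at 5% multiplicative noise
with 600 samples.

## Synthetic data

`generate_synthetic_curve` produces deterministic, seeded records of the
three closed forms with multiplicative Gaussian noise
y·(1 + sd·N(0,1)) — the simplest model of the roughly signal-proportional
scatter of force and projection-length read-outs.  Defaults mirror the
experimental protocols: 600 samples over 60 s, 1.5 μm depth, 5% noise in
the noisy suites.  What synthetic records do *not* contain: drift,
heteroscedastic baseline noise, contact-point uncertainty, adhesion, or
cell-to-cell variability.  Passing recovery tests therefore demonstrates
estimator correctness and noise robustness, not performance on real AFM/MPA
records.

## Problem sizes and determinism

The test suite and the acceptance script run the full-resolution models:
50-increment sweeps on the 36-DOF lattice (fractions of a second), 600-point
fits, and 50-seed Monte-Carlo consistency checks (a few seconds).  All
randomness flows from explicit seeds; repeated runs are bit-identical.

## Known limitations

* No volumetric continuum mesh: the continuum is analytical (half-space /
  Hertz), so finite-size, compressibility and pipette-fillet effects of a
  full FE model are out of reach; the half-space aspiration forms assume
  incompressibility and infinitesimal strain and are labelled as such in
  output metadata.
* One element per member; no strut buckling, no cable viscosity (the
  tables assign viscoelasticity to the cytoplasm only).
* Parallel CM/CTM coupling exaggerates the cytoskeletal force share and
  cannot reproduce soft-side/stiff-side asymmetry (see above).
* The indentation contact is a plane engaging junctions, not a resolved
  sphere-on-membrane contact.
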
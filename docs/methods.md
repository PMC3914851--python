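# Methods

## Model overview

The left ventricle is idealised as a closed-end, thin-walled cylinder that
remains cylindrical under load. The wall is a 2×2 block of homogeneously
deforming membrane regions — three healthy (RI, RII, RIII) and one scar (S)
— coupled kinematically: regions stacked in the same circumferential column
share the circumferential stretch, regions in the same longitudinal row
share the longitudinal stretch and the in-plane shear. The six shared
unknowns are λθ_R, λθ_S, λz_R, λz_S, κ_R, κ_S; the radial stretch of every
region follows from incompressibility, 1/(λθ·λz).

Force balance is the Law of Laplace for a pressurised closed-end cylinder:
each circumferential column carries the hoop load P·r·h and each
longitudinal row carries the full axial load π·P·r², with r the mid-wall
radius and h the total deformed height, both evaluated from the current
state. Per-region wall forces are Cauchy stresses times deformed areas
(H·T/λθ circumferentially, L·T/λz longitudinally), and the shear angle of
the axial force vector in each row is φ = atan(κ/λz). This yields six
residual equations in newtons; a state is accepted when the residual
max-norm is ≤ 1e-9 N.

The torque-free condition σθz = σzz·κ/λz is absorbed into the definition of
φ and is not one of the six solved equations; `FourRegionModel.
shear_consistency` reports the per-region mismatch as a diagnostic rather
than enforcing it.

## Healthy myocardium

Passive behaviour: a laminate of nine layers with myocyte angles evenly
spaced from −50° to +50° (the range and count are the physiological
summary; equal layer thicknesses). Every layer sees the same planar
deformation and obeys the Fung exponential energy
W = ½c(e^Q − 1), Q = b_ff·E_ff² + b_xx(E_cc² + E_rr²) + b_fx(E_fc² + E_cf²)
in its own fiber/cross-fiber/radial axes. Defaults: c = 880 Pa,
b_ff = 18.5, b_xx = 3.58, b_fx = 1.63 (standard canine constants; the
largest exponent belongs to the fiber direction of a fiber-reinforced
tissue). Cauchy stress is σ = −pI + 2F·∂W/∂C·Fᵀ with the Lagrange
multiplier chosen so the radial normal stress vanishes in every region
(thin-membrane plane stress). Because push-forward and the multiplier are
linear in the second Piola–Kirchhoff stress, layers are averaged at the
stress-resultant level.

Active behaviour: an elastance model. The active stress acts along each
layer's myocyte axis as a second Piola–Kirchhoff dyad σ_a·m₀⊗m₀ pushed
forward with F, with

σ_a(ls, t) = σ₀(ls) · ½(1 − cos ω(ls, t)),
σ₀(ls) = Tmax · Ca₀² / (Ca₀² + ECa₅₀²),  ECa₅₀ = Ca₀max/√(e^{B(ls−l₀)} − 1),

and a piecewise-linear twitch phase ω (rise over t₀, relaxation over
tr = m·ls + b). The ½ normalises the twitch so its peak equals σ₀ exactly
(at t = t₀); σ₀ is zero at or below the slack length l₀ = 1.58 µm and
saturates toward Tmax = 135.7 kPa. Defaults: Ca₀ = Ca₀max = 4.35 µmol/L,
B = 4.75 µm⁻¹, m = 1.0489 s/µm, b = −1.429 s, t₀ = 0.15 s, one twitch
simulated over 0.8 s. Sarcomere length is the layer's current
fiber-direction stretch times the reference length ls₀ = 1.65 µm, clamped
at 2.4 µm with a logged warning. Because the ESPVR takes the maximum over
the contraction and the twitch peak is exactly σ₀, the results are
insensitive to the time-course parameters as long as the grid resolves the
peak. All contraction parameters live in the config; none are hard-coded.

## Scar

The scar is a single membrane of crimped collagen fibers (volume fraction
ω_col) in an isotropic neo-Hookean ground substance Wg = c_g(I₁ − 3), with
W = (1 − ω_col)·Wg + ω_col·W_col.

### Fiber law (helical-spring uncrimping)

Each collagen fiber is a filament of diameter d and Young's modulus E_col
coiled into a helix of centreline diameter D (given as the ratio q = D/d)
with initial crimp angle θ₀ between filament tangent and fiber axis. The
law is derived, not fitted: axial force on the helix loads the wire in
torsion (moment F·R·sinθ), bending (F·R·cosθ) and axial stretch
(F·cosθ); Castigliano's theorem gives the tangent compliance per unit
reference fiber length. Two kinematic closures make it one-dimensional:
the filament is inextensible at leading order, so the crimp angle at fiber
stretch λ satisfies cosθ = λ·cosθ₀, and the helix radius shrinks as
R = R₀·sinθ/sinθ₀ (conserved filament arc per turn). With a circular wire
(A/J = 8/d², A/I = 16/d²) and an incompressible filament (G = E/3) the
tangent stiffness is

dP/dλ = E_col·cosθ₀ / D(λ),
D(λ) = (q²/4)·(1 − λ²a²)/(1 − a²)·(24 − 8λ²a²) + λ²a²,  a = cosθ₀,

a polynomial in λ², integrated from λ = 1 by 24-node Gauss quadrature. The
law satisfies, by construction: P(1) = 0; monotone stiffening; locking at
λ_lock = 1/cosθ₀ where the coil is straight, beyond which
dP/dλ = E_col·cosθ₀ (the straight-filament response); and P → E_col(λ − 1)
as θ₀ → 0 (the compliant coil regime vanishes). Fibers carry no load in
compression (P = 0 for λ < 1) — the standard convention for crimped
collagen, adopted because slack fibers buckle rather than push. The law
sits behind a single interface (`fiber_pk_stress` / `fiber_energy`) so an
alternative recruitment law can be swapped in.

With the reference parameters (θ₀ = 25.5°, q = 2.39, E_col = 1.16 MPa) the
initial fiber modulus is ≈ 41 kPa, locking at 10.8% stretch — an
exponential-like stiffening curve typical of collagenous scar.

### Orientation average

Fiber directions follow the wrapped von Mises density
ρ(φ) = exp(γ·cos2φ)/(π·I₀(γ)) on (−90°, +90°], applied about the mean
angle μ by shifting the density argument. The collagen stress is the
orientation average of (P(λ)/λ)·N⊗N by fixed 64-node Gauss–Legendre
quadrature — deterministic by construction, no sampling. The density
integrates to 1 on the half-circle to ~1e-15 at the default resolution.
States in which some fiber families cross the slack (λ = 1) or locking
(λ = λ_lock) thresholds make the orientation integrand only piecewise
smooth; the fixed rule then carries a relative quadrature error of order
1e-7, far below the model's constitutive uncertainty, and the stress and
energy routines share the same nodes so they remain mutually consistent to
1e-9.

## Numerical solution

Newton iteration with complex-step derivatives: every constitutive branch
is taken on real parts only, so residuals are analytic in the complex sense
and Im f(x + i·h·e_j)/h gives exact Jacobian columns at h = 1e-20 (the
result is step-insensitive over 1e-12…1e-30). The residual path is
vectorised over a leading batch axis, so one batched call evaluates the
whole Jacobian. If a residual function is not complex-step differentiable
the solver logs a warning and falls back to central differences. Steps are
damped by halving (up to 10 times) when they leave the admissible region or
fail to reduce the scaled residual norm; at most 50 iterations per
increment. Loading uses natural continuation: each pressure or time
increment starts from the previous converged state.

Diastole: an equally spaced passive pressure ramp from 0 to 1.3 kPa in 100
increments (config-controlled). Because every increment is solved to
1e-9 N, the end state is path-independent: 50 and 100 increments agree to
~1e-10 relative, comfortably inside the ≤0.2% discretisation band the
simulation protocol allows.

ESPVR: 10 equally spaced volumes from the reference (unloaded) cavity
volume to the EDV of the case. At each volume the cavity volume is held
fixed — pressure joins the six deformations as a seventh unknown, with the
volume constraint satisfied to 1e-10 relative — while the twitch runs over
100 uniform time points; the ESPVR pressure is the discrete maximum. If
the grid fails to bracket the 13 kPa systolic pressure it is extended
upward, and symmetrically downward (a strongly contracting ventricle can
cross 13 kPa below its unloaded volume), with a log message either way.
End-systolic volume is interpolated on the (pressure, volume) curve by
monotone piecewise-cubic (PCHIP) interpolation; the curve is never
extrapolated. EDV for the ejection fraction is the volume at 1.3 kPa, not
the unloaded volume.

Cavity volume uses the exact cylindrical-sector lumen of each wall block:
V = h·(l/(2r))·(r − t/2)², summed over the four regions at the common
mid-wall radius. This reproduces the zero-thickness sector limit and the
closed-form full-cylinder volume (verified to 1e-10 in the suite). All
internal units are SI; volumes are reported in mL and pressures in kPa or
mm Hg (133.322 Pa).

## Geometry and parameter defaults

Canine-sized LV: total mid-wall circumference 10 cm, height 5 cm, healthy
wall 0.8 cm, scar 0.4 cm thick, scar spanning half the circumference and
half the height (25% of wall area) — unloaded cavity volume 24.3 mL
(22.3 mL for the all-healthy baseline, whose S block gets full wall
thickness). Scar defaults: θ₀ = 25.5°, D/d = 2.39, E_col = 1.16 MPa,
c_g = 5.72 kPa, γ = 0.771, ω_col = 0.4, μ = 0° (circumferential — the
stiff axis of equibiaxially tested mature infarcts). The config file uses
unit-suffixed keys (`_cm`, `_deg`, `_kPa`, `_MPa`, `_um`, `_s`) converted
to SI at build time; sweep grids are inclusive `start:stop:count`.

## Synthetic biaxial data and fitting

The generator emulates an equibiaxial stress–stretch test of scar tissue:
plane-stress forward curves (σθθ, σzz) on λ ∈ [1.00, 1.15] (16 points —
a range chosen to span the crimp-to-locked transition of the reference
fiber law; the source experiments' exact protocol range is not a published
number), plus additive zero-mean Gaussian noise scaled to the peak stress
of each component, clipped at zero as a tension-only rig would report, and
reproducible from a seed. With circumferential mean alignment the
generated curves are anisotropic with σθθ > σzz, stiffening
exponential-like — the qualitative signature of mature infarct scar.

What the generator does *not* emulate: heteroscedastic transducer noise,
preconditioning hysteresis, stretch-level misregistration between the two
axes, and specimen-to-specimen variability. Recovery tests on these data
therefore demonstrate the identifiability and correctness of the estimator
under the model's own assumptions, not performance on laboratory data.

Fitting estimates five parameters (θ₀, E_col, D/d, c_g, γ) with ω_col and
μ held fixed, by bounded trust-region least squares (`scipy.optimize.
least_squares`, TRF) on the joint, equally weighted residuals of both
stress components, with 5 perturbed multi-starts (seeded) to guard the
non-convex fiber-law surface. Estimates at the bounds are flagged. From
noise-free synthetic data the truth is recovered to well under 1%; at 2%
noise R² per component stays above 0.99.

## Design choices where the design was open

- **Volume formula.** The source description of the sector volume is
  typographically ambiguous; the exact sector-lumen geometry above was
  adopted because it is the unique form consistent with both limiting
  cases.
- **Fung exponent labels.** Published tables label the first exponent with
  a cross-fiber-looking subscript while the energy names it b_ff; 18.5 is
  assigned to the fiber direction — the only assignment consistent with a
  fiber-reinforced tissue.
- **Twitch normalisation.** The elastance literature's ½(1 − cos ω) is
  used so the twitch peak equals σ₀; formulations omitting the ½ simply
  rescale σ₀, which is configurable.
- **Active stress push-forward.** The active dyad is applied as a second
  Piola–Kirchhoff stress (force per reference area along m₀), so the
  Cauchy contribution scales with the squared fiber stretch.
- **Tension-only fibers** and **downward ESPVR grid extension** as
  discussed above.

## Known limitations

- Thin-wall membrane theory: no transmural stress variation, no torsion,
  no border zones, no growth/remodeling — the model targets mechanism
  identification, not patient-specific stress analysis.
- The piecewise coupling (regions share edge displacements) makes the
  stress field discontinuous between regions.
- Baseline pump-function magnitude: with the published passive constants
  the thin-wall model fills to EDV ≈ 1.6× the unloaded volume at 1.3 kPa,
  giving baseline SV ≈ 13.7 mL and EF ≈ 0.38. Thick-wall ventricles of the
  same constants fill more (endocardial layers see higher stress), so
  absolute SV/EF here sit below values reported for finite-element models;
  all *relative* effects (scar-angle, density, stiffness, dispersion
  directions) are the quantities this model is built to rank, and are
  insensitive to this offset.
- The fiber law's wire-level constants (shape factors, G = E/3) are fixed
  internally; only the four microstructural parameters are exposed.
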
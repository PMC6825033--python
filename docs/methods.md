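# Methods

This note documents the model, the numerics, and the design choices behind
`fibrocrack`.  It is written for a reader who wants to know exactly what the
package computes and where its desk-scale defaults stand relative to a
full-resolution study.

## Constitutive model

The aortic wall is modelled as a fiber-reinforced hyperelastic solid at
finite strains.  With `b = F F^T`, `J = det F`, and squared fiber stretches
`I4 = M.(F^T F)M`, `I6 = M'.(F^T F)M'` along two mean fiber directions, the
effective (undamaged) energy density splits additively:

    Psi0_iso = (mu/2)(I1 - 3 - 2 ln J) + (kappa/4)(J^2 - 1 - 2 ln J)
    Psi0_ani = (k1/2k2) * sum_{i in {4,6}} [exp(k2 <Ii-1>^2) - 1]

a compressible neo-Hookean ground matrix plus the standard exponential
(HGO-type) fiber term.  The volumetric function `(kappa/4)(J^2-1-2 ln J)` is
convex with a stress-free reference; `kappa` here plays the role of the
first Lame constant in the small-strain limit (the linearized moduli are
shear `mu` and `lambda = kappa`).  Fibers store energy in tension only
(`Ii > 1`); the switch is a config flag (`fibers_tension_only`) because the
behaviour of compressed fibers is a genuine modelling ambiguity.  Both
energy parts, including the volumetric term, are degraded by the damage
functions (no tension/compression split of the driving energy is used).

Parameters and units: `mu`, `k1`, `kappa` in kPa; `k2` dimensionless;
`alpha` in degrees from the circumferential direction.  Lengths are mm,
forces mN, pressures kPa (1 mmHg = 0.133322 kPa), and loading is
parameterized by a dimensionless pseudo-time.

## Crack phase field

A scalar field `d` (0 = intact, 1 = ruptured) regularizes a sharp crack over
the length scale `l` through the anisotropic crack surface density

    gamma(d, grad d) = (1/2l) (d^2 + grad d . L grad d),
    L = l^2 (I + omega_M M(x)M + omega_Mp M'(x)M'),

whose structure tensor `L` makes crack surfaces cheap when their normal is
orthogonal to the fibers: as `omega -> inf` the crack is forced parallel to
the fiber direction, `omega = 0` is the isotropic solid, and ellipticity
restricts `omega > -1`.  Degradation is quadratic, `g(d) = (1-d)^2`, for
both the isotropic and the anisotropic energy.

Failure is driven by the dimensionless source

    Hbar = Psi0_iso/(gc_iso/l) + Psi0_ani/(gc_ani/l),

with separate critical fracture energies for the ground matrix and the
fibrous content; `gc/l` is treated as a single configuration parameter (the
layer tables are stated that way), with `l` chosen separately against the
mesh rule `l > 2h`.  Irreversibility enters through the history field
`H = max_t <Hbar - 1>`: the Macaulay bracket keeps the solid fully intact
until the failure surface `Hbar = 1` is crossed, after which the
rate-independent evolution law

    (1 - d) H = d - (1/2) Div(L grad d)

governs `d` (superposition of the two failure mechanisms, hence the 1/2 on
the divergence).  An optional artificial viscosity `eta` adds
`eta * dd/dt` on the left; the default is `eta = 0` since the studies treat
time as a pure load parameter.

Two operator variants live in one solver: the evolution law above
(`grad_factor = 1/2`, the default used in all coupled runs), and the pure
crack-surface Euler-Lagrange operator `d - Div(L grad d) = 0`
(`grad_factor = 1`), which is what the 1-D profile oracle `d = exp(-x/l)`
solves.  Keeping the prefactor explicit avoids silently testing one
operator against the analytic solution of the other.

## Discretization and the one-pass staggered solve

Standard displacement-based elements with full integration: 4-node
quadrilaterals (2x2 Gauss) in plane strain, 4-node tetrahedra (1-point for
mechanics, exact linear-tet matrices for the phase field) in 3-D.  The
structured tube mesh subdivides hexahedral cells into 6 tetrahedra with the
Kuhn (main-diagonal) pattern, which is conforming across cells; grid planes
are aligned with the tear edges so the void is represented exactly.

Each pseudo-time step performs exactly one pass:

1. **Mechanics at frozen d.**  Total-Lagrangian Newton iteration on the
   first Piola-Kirchhoff residual with the consistent tangent
   `A = d^2 Psi / dF dF`.  Pressure is a follower load on the deformed
   inner surface with its (unsymmetric) load-stiffness included.  A
   backtracking line search on the residual norm accepts the full Newton
   step whenever it reduces the residual, so quadratic convergence is
   preserved away from rupture while the cascade of element breakage stays
   solvable.  Trial states with inverted elements or fiber-energy overflow
   are treated as line-search rejections, and ultimately as step failures.
2. **History update** at quadrature points from the effective (undegraded)
   energies of the converged displacements.
3. **Phase field.**  The Euler equation is linear in `d`; one sparse SPD
   solve yields the nodal field, followed by the projection
   `d <- clip(d, d_n, 1)`.  The projection enforces the bounds and nodal
   irreversibility exactly; it is needed because the strongly anisotropic
   `L` (the layer tables use omega = 1e3) violates the discrete maximum
   principle on coarse meshes.

Newton failure halves the pseudo-time increment, mirroring the published
protocol (increments of 1e-2 reduced to 1e-4 under instability); when the
minimum increment is exhausted the run reports its last converged state
rather than aborting — the same premature-termination behaviour the
original sensitivity study describes for strong anisotropy under Q1
elements.  Identical inputs produce bitwise identical trajectories; there
is no randomness anywhere in the solver.

Numerical safeguards: a residual stiffness floor `g >= 1e-7` in the FE
stress/tangent evaluation (not in the point-wise API) keeps fully broken
elements invertible; the fiber exponential raises a diagnostic error beyond
`k2<I-1>^2 > 500`.  Because crack-face contact is out of scope, the solver
leaves the volumetric (kappa) stress undegraded wherever J < 1
(`degrade_compressed_volume = False`): ruptured material still resists
interpenetration, the penalty a contact formulation would otherwise supply.
Without it, the elements lining the tear void are crushed flat
(det F -> 0.01) once the surrounding layer ruptures under the
supra-physiological pressure and the run ends by element inversion.  The
crack driving energy is not affected by this choice; the point-wise
constitutive API defaults to the fully degraded model.

## Parameter identification

The four homogeneous test modes are, in the (theta, z, r) frame: uniaxial
extension along theta and z, and simple shear on the r-plane along theta
and z.  Closed forms assume full incompressibility with the Lagrange
pressure eliminated via the lateral traction-free conditions; the lateral
stretch of the uniaxial modes solves a scalar equilibrium equation
(safeguarded vectorized Newton).  Because the fibers lie in the theta-z
plane, in-plane shear does not stretch them and the shear response is
exactly `sigma = mu * gamma` — which is why those tests pin down `mu`.

The identification minimizes the unweighted sum of squared Cauchy-stress
residuals over all modes (trust-region least squares, bounds
mu, k1 in (0, 1e3] kPa, k2 in (0, 1e2], alpha in (0, 90) degrees, 5 seeded
multistarts, ties broken by smaller k2) and reports per-mode R^2 and the
normalized RMSE  `eps = sqrt(chi2/(N-q)) / sum_modes mean(sigma)`, q = 4.

**Identifiability.**  With noiseless synthetic curves the four parameters
are recovered to machine precision from a 2x-perturbed start.  Under 1 kPa
of Gaussian noise (on curves reaching ~70 kPa), Monte-Carlo runs show mu,
k1 and alpha recovered with <5% mean bias while k2 scatters widely: on
deformation ranges up to gamma = 0.5 and lambda = 1.2 the exponent trades
off against k1, and only the product response is well determined (fitted
curves match the noiseless truth to ~0.3 kPa RMSE).  Conclusions that rely
on k2 alone need wider stretch ranges than these protocols provide.

## Synthetic data generator

The experimental stress-strain curves behind the identification are not
deposited, so the generator emulates them from the constitutive model
itself: per-mode deformation grids (defaults: 25 points, shear to
gamma = 0.5, stretch to lambda = 1.2, the ranges spanned by the published
figures) with i.i.d. Gaussian stress noise.  It reproduces the magnitudes
and shapes of the real test modes but none of their systematic effects —
no preconditioning drift, no mode-to-mode specimen variation, no
heteroscedastic transducer error.  Passing recovery tests therefore
demonstrates correctness of the estimation machinery, not robustness to
real experimental artefacts.

## Benchmark studies and desk-scale defaults

**Notched-plate sensitivity (plane strain).**  Unit square, slit from the
mid-left edge to the center, one fiber family at 45 degrees; mu = k1 = 1
kPa, k2 = 1, kappa = 3 kPa, gc_iso/l = gc_ani/l = 1e-2 kPa, l = 0.1 mm.
The bottom edge is held vertically, the top edge ramps upward
(pseudo-time = applied displacement in mm).  Desk default h = 0.018 mm
(~3.1k elements, satisfying l > 2h) with displacement increments of 5e-3 mm;
the acceptance suite runs the sweep at h = 0.024 mm (~1.8k elements) with
increments of 2.5e-3 mm;
the full discretization (~38.8k elements) is available via
`--full-scale`.  Reported quantities per omega_M: the crack angle (principal
direction of element centroids with d >= 0.8 beyond the notch tip, measured
from the horizontal) and the peak top-edge reaction.  Runs that terminate
early under strong anisotropy report their last converged state; the angle
estimator carries a few degrees of scatter at desk resolution, which matters
in the saturated regime (omega_M >= 10) where the angle curve is nearly flat.

**Aortic segment with an initial tear.**  Six concentric layers
(4 x 0.375 mm media, 2 x 0.5 mm adventitia) on Ri = 15 mm, H = 40 mm; the
tear is a meshed void spanning the innermost three medial sub-layers, beta
degrees of arc, 2 mm axially; *media 3* carries the degenerated (fitted)
constants and the low critical energies, all other layers the stiffened
table values; fibers run at +/-44.71 degrees to the local circumferential
direction, per layer, in a discrete sense.  Loading follows the two-cycle
saw-tooth protocol (80-120 mmHg physiological with axial stretch 1.2 and
10-degree twist; 600 mmHg supra-physiological with 30-degree twist), with
snapshots at instants A/B/C = 0.4/1.2/1.6.  The tear faces are
traction-free; only the inner lumen surface is pressurized (a flag allows
pressurizing the tear faces).  `kappa` is set per layer as `3 mu` —
the kappa/mu ratio of the plate study — because no bulk modulus is stated
for the layered wall and 3 kPa against mu ~ 100 kPa would make the wall
volumetrically softer than in shear.  Desk default: n_theta = 24, n_z = 10
(~10k tetrahedra) with dt = 0.05 for test runs, and n_theta = 36, n_z = 16
(~19k) as the study default; the full ~1e5-element meshes are reached
with `--full-scale`.  At these resolutions l = 0.1875 mm is far below 2h,
so the diffusive crack width is deliberately under-resolved: damage
localizes element-wise and all conclusions drawn at desk scale are
qualitative (damage-zone volumes and their ordering, not crack-path
geometry).

Reported tube metrics: per snapshot instant, the volume and volume fraction
of *media 3* with element-mean d >= 0.8, and the total damaged volume over
all layers.  At instant A no damage zone exists for either tear size (the
stress concentration raises d near the tear but below threshold); at
instant B a localized rupture zone has formed around the tear, several
times larger for the 60-degree tear than for the 30-degree one, and growing
with mesh refinement as the concentration sharpens (e.g. 46 vs 161 mm^3 at
n_theta = 36, n_z = 16).  The tear-size ordering is stable across the
desk-scale meshes tested.

## Known limitations

- One-pass splitting slightly underestimates crack speed by construction;
  step-halving convergence of the damage history is verified only on smooth
  problems.
- P1/Q1 elements with full integration: no locking remedies by default
  (moderate kappa/mu = 3); selective-reduced integration is not implemented.
- No residual stresses (opening angle), viscoelasticity, active tone,
  growth/remodelling, crack-face contact, or fluid-structure interaction.
- The crack-angle estimator (PCA of a thresholded point cloud) is robust for
  band-like cracks but noisy for short or branched cracks.
- Checkpointing stores the quadrature-point history as a compressed array
  (`.npz`) next to the text outputs; restarting mid-protocol reproduces the
  remaining trajectory only with identical settings.
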
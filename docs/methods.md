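# Methods

## Model class

`mixdim` solves coupled systems of reaction–diffusion equations on a
single simplicial parent mesh of dimension d ∈ {2, 3}. Volume
compartments Ωᵐ are sets of cells sharing an integer tag; surfaces Γᑫ
are sets of tagged facets (co-dimension 1 only). Each volume species
obeys ∂u/∂t = ∇·(D∇u) + f with boundary condition D∇u·n = −R on every
tagged surface it touches; each surface species obeys the analogous
equation with the Laplace–Beltrami operator. f, g and R are sums of
reaction contributions with signed stoichiometry; a positive boundary
rate is a flux into the volume. Reactions are local: a volume reaction
references one volume's species; a surface reaction one surface's; a
volume–surface reaction may also see traces from one bordering volume,
a volume–surface–volume reaction from both (interior interfaces only).

Assumptions: fixed geometry, diffusion as the only transport mechanism,
deterministic mean-field kinetics, smooth rate laws. Discontinuous
switches (channel closure at a threshold) are modeled as *events* —
latching parameter assignments triggered by conditions on time,
parameters, or compartment averages — rather than discontinuities
inside rates, which the parser rejects.

## Units

Base units are μm, s, molecule. Volume concentrations are μM, surface
densities molecules/μm², with 1 μM = 602.214076 molecules/μm³ (Avogadro
scaled). Volume rates must carry the dimension of μM/s; surface-bound
rates that of μM·μm/s ≡ molecules/(μm²·s)/602.214076; declared units
are converted to the volume side and surface side separately, so the
same reaction adds μM·μm/s to a volume equation and molecules/(μm²·s)
to a surface equation. Unit checking is per declared rate unit against
the binding compartment's requirement; no inference inside
sub-expressions is attempted.

## Discretization

* **Space.** P1 Lagrange elements on all compartments. Mass and
  stiffness matrices use exact closed-form integration; surface
  gradients are computed in each triangle's tangent plane via the Gram
  inverse of the edge matrix, which yields the Laplace–Beltrami
  stiffness without parametrization. Trace operators are boolean vertex
  injections (volume dof → surface dof); their transposes scatter
  boundary loads back.
* **Nonlinear terms.** Reaction loads and Jacobian blocks use vertex
  (mass-lumped) quadrature: ∫ f(u) φᵢ ≈ wᵢ f(uᵢ) with wᵢ the lumped
  mass. This makes the reaction Jacobian diagonal per vertex pair,
  exactly consistent with the symbolic derivatives, and preserves P1's
  second-order convergence (verified by the shipped convergence study).
  A consequence worth knowing: with the *consistent* mass matrix in the
  time term, extremely large τ·(∂f/∂u) can make the Newton matrix
  M/τ − diag(w ∂f/∂u) indefinite; the restart mediation reduces τ when
  this bites.
* **Time.** Implicit Euler: M(uⁿ⁺¹ − uⁿ)/τ + Kuⁿ⁺¹ = b(uⁿ⁺¹, tⁿ⁺¹),
  solved by Newton–Raphson with the exact symbolic Jacobian. Tolerances:
  absolute residual 1e−10, relative 1e−8 (2-norm), max 25 iterations.
  Linear solves use a sparse direct factorization by default (ILU-
  preconditioned GMRES, relative residual 1e−10, is available). For
  linear autonomous kinetics the Jacobian is constant and its
  factorization is cached per step size; event-driven parameter changes
  invalidate the cache.
* **Step control.** Optional adaptivity from the previous step's Newton
  count: grow ×1.25 at ≤3 iterations, shrink ×0.7 at ≥8, hold
  otherwise, clamped to [τ_min, τ_max]. The rule is monotone: fewer
  iterations never yield a smaller step. On divergence the step
  restarts at τ×0.5, up to 10 restarts. Restarting on negative
  concentrations is available but off by default: P1 transport with a
  consistent mass matrix is not monotone, so sharp fronts undershoot
  slightly at *any* step size, and a restart cannot cure a spatial
  phenomenon. Tiny negatives are clamped to zero in written outputs
  only, never in the solver state.
* **Axisymmetry.** 2D (r, z) meshes may declare `axisymmetric: true`;
  every volume and boundary integral is weighted by r (exactly, for the
  P1 interpolant of r), the r = 0 axis carries zero measure and acts as
  a natural no-flux boundary, and reported totals carry the 2π factor.

## Events and scalar couplings

Events are checked at each prestep against the state at the beginning
of the step; they latch (fire once) unless declared repeating, and a
restart rolls provisional firings back. Well-mixed scalar couplings
model an unmeshed exterior pool S exchanging with a field F through a
surface: before the solve, S_est = S + τ·c·∫Γ k (F(tₙ) − S(tₙ)) dΓ
(predictor, with S_est exposed to the rate laws during the solve);
after it, S(tₙ₊₁) = S + τ·c·∫Γ k (F(tₙ₊₁) − S_est) dΓ (corrector,
consistent with implicit Euler). For a clamped field the per-step
multiplier on (S − F) is 1 − cτ(1 − cτ), matching the implicit factor
1/(1 + cτ) through second order in cτ; the shipped tests assert this
closed form exactly.

## Reductions

* **Conservation elimination.** Left-null vectors of the stoichiometry
  matrix, restricted to species that share a compartment and a
  diffusion coefficient, have spatially uniform initial data, and are
  untouched by surface-coupled reactions, define conserved totals; one
  member per independent vector is eliminated and replaced by
  (total − others) in all rates. Detection is linear-algebraic (exact
  rational null space), not name-based. The uniform-initial-data
  restriction is what makes the eliminated field reconstructible
  without solving an extra diffusion equation.
* **Well-mixed (0D) reduction.** One state per species; volume rates
  carry over; boundary rates are scaled by surface/volume measure with
  the same unit conversions as the PDE assembly. Space-dependent
  parameters have no well-mixed meaning and are rejected.

## Verification problem and study sizes

The reference problem is membrane phosphorylation in a slab: A is
phosphorylated at the z = 0 face at k_kin·A|_Γ (k_kin = 50 μm/s) and Ap
dephosphorylated in the bulk at k_p = 10 s⁻¹; both diffuse with equal
D; A_tot = 1 μM; L = 1 μm. With equal diffusivities the total A + Ap
stays uniform, and the steady phosphorylated profile is
u(z) = C cosh((L − z)/λ), λ = √(D/k_p),
C = k_kin A_tot / (√(D k_p) sinh(L/λ) + k_kin cosh(L/λ)).
The closed form is verified in the tests against an independent 1D
finite-difference boundary-value solve. The slab parameters are pinned
package constants chosen so that the profile has O(1) variation across
the thickness at D = 10 μm²/s; the verification contract is convergence
*order* and error *ordering* in D, which are robust to this choice.

Study sizes (chosen to keep the full suite at desk scale):

* Mesh refinement: n = 3, 6, 12, 24 cells per edge (≤ 31 250 unknowns
  at the finest level), each solved to steady state with large implicit
  steps — implicit-Euler steady states are independent of τ, so this is
  equivalent to a direct steady solve; steadiness is declared when the
  relative L2 change per unit time falls below 1e−10. L2 errors against
  the analytic profile use quadrature exact to degree 4. Expected and
  observed: order ≈ 2 for D ∈ {10, 100, 1000} μm²/s, with errors
  strictly decreasing in D at every level (smoother profiles).
* Time refinement: fixed n = 16 mesh, τ = 0.02 s halved 4 times to
  t = 0.2 s, errors in the discrete L2 norm against a reference
  trajectory at τ_finest/16 (self-convergence isolates the O(τ) error
  from the spatial floor). Observed order ≈ 1.1.
* Plateau: fixed n = 8 mesh, τ swept from 4 s down to 1/64 s to
  t = 3 s, errors against the analytic steady state. Large-τ errors are
  dominated by the undamped transient; small-τ errors flatten at the
  spatial floor. The onset (log-log interpolated crossing of 2× the
  floor) decreases with D because finer floors require better-resolved
  transients.
* Well-mixed limit: membrane-binding fixture (k_on = 5 μm/s,
  k_off = 1 μM·μm³/(molecule·s), unit cube, n = 6) at D = 2, 20,
  200 μm²/s, τ = 2e−4 s so that time-discretization error does not
  mask the spatial deviation; deviation of compartment averages from a
  high-accuracy ODE integration shrinks monotonically and is < 1% at
  the largest D.

## What the synthetic fixtures do and do not show

The generators produce idealized geometries: structured slabs
(Kuhn-subdivided hexahedra), rectangles, and nested spheres/disks built
by radially mapping a structured cube mesh onto a ball (cube shells map
to concentric spheres, so the organelle interface is an exact lattice
sphere, snapped to the nearest shell). Element quality is uniform and
moderate; tags are exact by construction. Real electron-microscopy-
derived meshes have heterogeneous element quality, curved boundaries
and imperfect tags — passing convergence and conservation tests here
demonstrates correctness of the discretization and solver, not
robustness to pathological meshes. Mesh conditioning is out of scope;
externally produced meshes are accepted as Gmsh MSH 4.1 ASCII.

## Numerical choices and degenerate inputs

* Degeneracy: entities with measure < 1e−12 × (bbox scale)^dim are
  rejected, naming the entity. Cells are reoriented to positive signed
  volume on construction.
* Interior facets separating like-tagged cells are rejected unless the
  facet tag is declared an internal membrane (catches tagging mistakes).
* Normal orientation on interior interfaces: the positive flux
  direction is outward from the first-listed bordering volume
  (ascending tag at mesh level; declaration order at model level).
* Quadrature for L2 errors: collapsed Gauss–Jacobi on the simplex,
  exact to the requested degree (default 4).
* Output alignment: outputs are reported at the nearest accepted step
  not exceeding the requested time; no temporal interpolation. CSV
  numbers carry 17 significant digits so repeat runs are bit-identical.

## Known limitations

Single-process, direct-solver-first design: desk-scale problems (≲10⁵
unknowns) are the target envelope. No moving boundaries, advection,
electrodiffusion or stochasticity. Surface species on an interior
interface live on a single dof set (no per-side surface fields). The
well-mixed reduction holds prestep scalars at their initial values.
SBML is not read or written; the YAML schema is deliberately minimal.
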
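# Methods

## Model class

`ontosel` analyses selection on quantitative traits that are fixed over an
individual's lifetime (non-plastic, e.g. a constant allocation rule) but
shape its ontogeny, in populations structured by discrete birth-assigned
classes (sexes, ploidies, habitats) and by age. A model declares, per class
`j`:

* internal states `x_j(a)` (size, condition, ...) with developmental rates
  `dx_j/da = g_j(z_j, x_j, v)` from fixed initial values;
* mortality `mu_j(z_j, x_j, v)` and class-oriented fecundities
  `f_ij(z_j, x_j, v)` (offspring of class `i` per unit time);
* a genetic system: transmission weights `gamma_ij` (expected mutant-allele
  copies per class-`i` offspring of a class-`j` carrier) and trait exposures
  `dz/du` (1/2 for a diploid heterozygote, 1 for a haploid carrier), with
  optional pleiotropic constraints forcing several (class, trait) slots to
  share one allelic value.

The environment (density, competitor distributions) is assumed to sit at the
attractor set by the resident traits `v`; rate functions receive a
per-resident environment object so concrete models can cache their
equilibrium quantities. None of the rates depend on age explicitly — all
age dependence is mediated by states, which is a modelling assumption, not a
numerical one.

The fate of a rare mutant allele is read off its basic reproductive number
`R0(u, v)`: the Perron root of the allelic next-generation matrix
`gamma_ij R_ij(u_j, v)`, with `R_ij = int_0^inf l_j(a) f_ij(z_j, x_j(a), v) da`
along the mutant's survivorship/state path. Directional selection is the
gradient of `R0` in the mutant allelic values at `u = v`; quadratic
(stabilising vs disruptive) selection is its Hessian at a singular point.
Both are computed as integrals over age of Hamiltonian-based kernels, with
costates pricing marginal survival and development in units of future
class-oriented reproduction:

    H_ij = l_j f_ij − lam^l_ij mu_j l_j + lam^x_ij · g_j.

Under constant class proportions at birth (`f_ij = c_ij f_j`, as in the
two-sex example) the `nc × nc` class-oriented costate systems collapse to
one class-specific system per parent class; the package picks this
automatically and the class-oriented path remains available (`mode=`).

## Numerical choices

* **Age truncation.** All `[0, inf)` integrals are truncated at the age
  `a_max` where the slowest-dying class's survivorship first falls below a
  tolerance (default `1e-9`), found by event detection with a doubling
  horizon. Every integrand carries a survivorship factor or decays with the
  costates' terminal condition, so the truncation error is of that order.
* **Trajectories and lifetime fecundities.** Per-class survivorship/state
  ODEs are solved with adaptive RK45 (`rtol 1e-10`, `atol 1e-16`; the tight
  absolute tolerance keeps the deep survivorship tail meaningful).
  `R_ij` accumulates as an extra quadrature state of the same solve.
* **Costates.** Survivorship costates use the integral identity
  `lam^l(a) = (1/l(a)) int_a^{a_max} l f dtau` rather than their forward
  ODE, which divides by vanishing survivorship and amplifies late-age error;
  the forward ODE is kept as a residual check (`costate_residuals`,
  max-norm residuals ≲ 1e-6 where `l ≥ 1e-5`). Tail reproduction, backward
  survivorship and state costates are integrated jointly backward from
  `a_max` (all stable in that direction); states themselves are *not*
  integrated backward (unstable when growth is contracting) but evaluated
  from an O(h^4) cubic-Hermite interpolant of the forward solve. The
  backward system is jointly linear in (l, tail, lam^x), so the solution is
  rescaled to enforce `l(0) = 1` exactly, cancelling the forward solve's
  accumulated relative error at the terminal point.
* **Derivatives of user rates.** Central finite differences with relative
  step `1e-6 · max(1, |argument|)` for first derivatives; `1e-4` relative
  steps for the Hamiltonian second derivatives (curvature values are
  `~1e-2`–`1` here, so the larger step balances truncation against
  round-off). Models never need to supply analytic derivatives.
* **Age quadrature of kernels.** Kernels are evaluated on a uniform grid
  (default 801 points) and integrated by Simpson's rule; the integrands are
  smooth and exponentially decaying, so this is far below the other error
  budgets.
* **Singular strategies.** Zeros of the stacked gradient (free coordinates
  plus one summed component per shared-trait group) are found by
  quasi-Newton root-finding (scipy `hybr`) from a user guess, each
  evaluation re-solving the full resident + costate system. A coordinate
  pushed to the lower trait bound with an outward gradient is pinned there
  ("boundary-pinned") and the reduced system re-solved. A 1-D grid scanner
  (`gradient_on_grid`) supports bracketing and diagnostics. For the built-in
  example, the implicit fixed-point relation for the optimal growth rates
  (ratio of lifetime costate integrals over twice the survival cost) is
  implemented as an independent oracle; it is itself solved as a root
  problem because damped iteration oscillates in the male trait. Acceptance
  tolerance on the polished gradient: `1e-5` (sup norm).
* **Convergence stability.** Central-difference Jacobian of the gradient
  (relative step `1e-3`), classified by the leading eigenvalue of its
  symmetric part; "marginal" within `1e-6` of zero relative to `‖J‖`. No
  frozen-environment shortcut is taken: the resident values enter the
  environment as well as the focal rates.
* **Quadratic selection.** The six age-resolved Hessian components (direct
  trait curvature; state-, survivorship- and birth-frequency-mediated
  interactions) are assembled from Hamiltonian second differences and the
  perturbation set: state sensitivities by the variational ODE (whose
  propagator, the fundamental matrix, has a closed exponential form when
  `dg/dx` is age-constant), survivorship sensitivities by integrating direct
  plus state-mediated mortality effects, and birth-frequency sensitivities
  by the at-singularity linear solve around the resident next-generation
  matrix. Off-diagonal class blocks carry only the birth-frequency
  component. Inputs whose gradient exceeds `1e-4` are rejected — the
  formulas assume a singular point. The assembly's correctness gate is a
  fully independent route: Richardson-extrapolated second differences of
  `R0(u, v*)` in the mutant allelic values (agreement ≲ `1e-3` relative in
  the tests, typically `1e-4`–`1e-6`). The off-singularity birth-frequency
  response is out of scope, so Hessians are only offered at singular points.
* **Shared traits.** A pleiotropic constraint is handled by the chain rule:
  the constrained gradient is the sum over group members, the constrained
  curvature the sum of all pairwise Hessian blocks of the group (the mixed
  female-male block is identically zero in the built-in example, because
  the sexes are coupled only through birth-class frequencies, which a fixed
  primary sex ratio pins). Second-order machinery beyond this sum rule
  (e.g. constrained uninvadability corrections) is not implemented.

## The worked sexual-niche model

Two sexes, one trait each (basal growth rate `v_f`, `v_m`), one state
(size). Growth `dx/da = z_j − alpha x`, mortality `mu_e_j + beta_j z_j^2`,
female fecundity `x_f (1 − N_T/K)`, male siring by size-matching competition
`exp(−kappa (x_m − x_f)^2)` normalised over resident males. Resident
demography is closed form: the package evaluates survivorship/size paths,
the equilibrium density (which makes the resident reproductive number
exactly one whenever the population persists), the secondary sex ratio and
the standing size densities analytically, and uses them both for speed and
as independent oracles for the generic solvers.

All integrals over standing size distributions are computed in the age
variable (size is monotone in age; the standing age density is
`mu e^{−mu a}`), because the size density itself has an integrable endpoint
singularity at the maximum size whenever mortality exceeds the size-loss
rate — Gauss–Legendre on the age form (200 nodes per sex, horizon at
survivorship `1e-14`) converges spectrally, while quadrature in the size
variable stalls at the singularity. Degenerate non-growing males
(`v_m = 0`) collapse to a point mass at size zero and are handled by the
same age-form integrals.

One derivation is worth recording: the model-specific closed form of the
male size-mediated quadratic kernel used as the oracle for the generic
state-state component is

    c · kappa · ((1 − e^{−alpha a})/alpha)^2 · l_m(a)
      · ∫ (collective egg rate of size-x_f females)
          · C(x_m(a), x_f) · (2 kappa (x_m(a) − x_f)^2 − 1) dx_f,

i.e. prefactor `c·kappa` from the class-specific weight (1/2), the male
birth frequency `c` and the curvature `2·kappa·(...)` of the matching
kernel. This form agrees with the generic finite-difference machinery and
with the independent `R0` curvature route to better than `2e-4`.

## Individual-based simulator

A fixed-step scheme (default `dt = 0.2` time units): binomial deaths at
probability `mu_j dt` (aborting if any per-step event probability reaches
0.5), Euler size updates, Poisson egg production per female at rate
`x_f · max(0, 1 − N/K)` with the live head-count `N` (the finite-population
analogue of the equilibrium density feedback), sire sampling proportional to
the size-matching kernel (Gumbel-max), offspring sex male with probability
`c`, one allele transmitted per parent (mother-only for haplodiploid sons),
and per-component Gaussian mutation of transmitted alleles (default
probability `1e-2`, s.d. `1e-2` trait units), reflected at zero.
Initialisation is a monomorphic population at the resident equilibrium's
age/size structure. All randomness flows from one seed.

What the simulator emulates — demographic stochasticity, Mendelian
segregation, mutation-limited trait substitution, branching — and what it
does not: no spatial structure, no environmental stochasticity, no explicit
resource dynamics, no mate/sperm limitation, and a discretisation bias of
order `mu·dt` in the standing population size (~2–3% at the defaults).
Passing simulation tests therefore validate the analytic machinery's
predictions under the model's own assumptions, not the model against data.

Branching is detected as persistent bimodality of late-run male allelic
values: exact 1-D two-means splits per record, a record counting as "split"
when the between-cluster gap exceeds 4 pooled within-cluster standard
deviations, and a positive verdict when at least 80% of the final 20% of
records are split. This is deterministic given the seed.

**Scaled-down validation runs.** The analysis-vs-simulation agreement
checks run at reduced carrying capacity (`K = 1200` instead of `1e4`,
populations of ~1000–1600) over 1–2 × 10^4 time units, with the mutation
kernel widened to s.d. `0.04` so that mutational variance accrues on the
shortened horizon; the stabilising-selection control and the shared-trait
control use identical settings, so the contrast between branching and
non-branching outcomes is like-for-like. At these settings the disruptive
parameter set splits the male allele cloud with split fraction > 0.9 while
both controls stay below 0.05. Full-scale runs (`K = 1e4`, default mutation
kernel, ≥ 10^5 time units) show the same qualitative contrast but take
hours, not minutes.

## Known limitations

* Trait bounds are `[0, inf)`; only lower-boundary pinning is detected.
* The survivorship costate is ill-conditioned where survivorship is below
  ~`1e-6` (a ratio of vanishing quantities); all downstream uses are
  survivorship-weighted, so this is cosmetic, but exported deep-tail
  `lambda_l` values should not be over-interpreted.
* Uniqueness of singular strategies is never claimed — the root path
  polishes from a guess, and the grid scanner only brackets within the
  scanned box.
* With multiple co-evolving traits, a convergence-stable point with a
  non-negative-definite Hessian is reported as a *candidate* branching
  point; the exact multi-trait branching conditions are an open problem.
* Environments with fluctuating attractors are out of scope; a user model
  whose density dependence is inconsistent (resident `R0 != 1`) is reported
  as such, not auto-corrected.
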
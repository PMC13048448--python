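# ontosel

Selection analysis for quantitative traits that are **fixed for life but
shape ontogeny** — constant allocation rules, developmental thresholds,
growth investments — in populations structured by **discrete classes**
(sexes, ploidies, habitats) and by **age**. Written for evolutionary
ecologists and life-history theorists who want to go from a declarative
model (per-class fecundity, mortality and developmental rates plus a
genetic system) to convergence-stable trait values, their
stabilising/disruptive classification, and stochastic validation, without
re-deriving the machinery each time.

## What it computes

The fate of a rare mutant allele with allelic values `u` in a resident
population at `v` is read off its basic reproductive number — the Perron
root `R0(u, v)` of the allelic next-generation matrix
`gamma_ij R_ij(u_j, v)`, where
`R_ij = ∫ l_j(a) f_ij(z_j, x_j(a), v) da` is the expected lifetime number
of class-`i` offspring of a class-`j` carrier along its survivorship `l_j`
and state path `x_j`. The package evaluates, for any declared model:

* **Directional selection** `s_jl(v) = [∫ ŝ_jl(a, v) da] · dz/du` with the
  age-resolved kernel
  `ŝ_jl(a,v) = Σ_i ν_i γ_ij (∂H_ij/∂z_jl) q_j`, where
  `H_ij = l_j f_ij − λˡ_ij μ_j l_j + λˣ_ij·g_j` is the class-oriented
  Hamiltonian and the costates `λˡ, λˣ` price current survival and
  development in units of future class-oriented reproduction
  (`λˡ` generalises Fisher's age-specific reproductive value);
* **singular strategies** `v*` (zeros of the gradient, with
  boundary-pinning detection) and their **convergence stability** (sign of
  the leading symmetric-part eigenvalue of the gradient's Jacobian);
* **quadratic selection**: the Hessian of `R0` at `v*`, assembled from six
  age-resolved components (direct trait curvature and the indirect routes
  through states, survivorship and birth-class frequencies), classified as
  net stabilising or net disruptive (candidate evolutionary branching, with
  the divergence direction);
* **shared-trait (pleiotropic) constraints**: summed gradients and
  chain-rule-collapsed curvatures when several (class, trait) slots share
  one genetic value;
* a worked **two-sex sexual-niche model** (growth/survival trade-off with
  size-matching sexual selection, closed-form resident demography, diploid
  and haplodiploid variants) and an **individual-based simulator** that
  validates convergence and branching predictions.

## Worked example

Directional selection and the singular strategy of the two-sex model at its
default parameters (`examples/02_directional_selection.py`):

```
$ python examples/02_directional_selection.py
total directional coefficients at v = (0.5, 0.5):
  female: +0.02381   male: -0.37581
  (positive = selection for faster growth)

singular strategy: v* = (0.517, 0.428) (|gradient| = 3.9e-12)
fixed-point shortcut:      (0.517, 0.428) (independent route, same answer)

convergence stability: strongly_convergence_stable (leading symmetric eigenvalue -0.4584)
gradual evolution from nearby trait values is attracted to v*.

female kernel peaks at age 0.0 and changes sign near age 5.4:
selection favours growth early in life and opposes it later.
```

Reading it: at a resident where both sexes grow at 0.5, selection still
pushes female growth up slightly and male growth down strongly (males pay
the same survival cost but only gain through size-matching with females).
Joint evolution settles at `v* = (0.517, 0.428)` — females grow faster than
males — and the point is attracting. The age kernel shows the life-history
trade-off: growth is favoured early (future size gains) and disfavoured
late (survival costs dominate).

At a sex-asymmetric parameter set (cheap male growth, strong size
matching), `examples/03_quadratic_selection.py` finds the male diagonal of
the Hessian positive and the point net disruptive, and
`examples/04_branching_simulation.py` confirms with an individual-based run
in which the male allele cloud splits into fast-growing/short-lived and
slow-growing/long-lived clusters. `examples/05_shared_trait_constraint.py`
shows that forcing one shared growth gene drags the optimum below both
sex-specific optima and suppresses the branching;
`examples/06_custom_model.py` declares a fresh single-class model from
scratch.

A thin CLI mirrors the library:

```bash
ontosel singular --guess 0.5,0.5
ontosel hessian --vstar 0.517,0.428
ontosel example --mode sweep --sweep-param mu_e_f \
    --sweep-values 0.05,0.1,0.15 --out sweep.csv
ontosel run --config analysis.yaml     # staged gradient/singular/hessian/simulate
```

## Layout

| Module | Role |
| --- | --- |
| `ontosel.genetics` | transmission matrices, trait expression, constraints |
| `ontosel.model` | declarative `LifeHistoryModel`, validation, registry |
| `ontosel.resident` | trajectories, next-generation matrix, birth structure |
| `ontosel.costates` | Hamiltonians and costate solves |
| `ontosel.directional` | gradients, singular strategies, Jacobian |
| `ontosel.quadratic` | perturbations, six-component Hessian, classification |
| `ontosel.sexual_niche` | the worked two-sex model and its closed forms |
| `ontosel.simulate` | individual-based simulator and summaries |
| `ontosel.reporting` / `ontosel.cli` | staged runs, CSV/JSON artifacts, CLI |

`docs/methods.md` documents the model assumptions, every numerical choice
(tolerances, truncation, finite-difference steps, branching detection) and
the known limitations.
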
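"""Sexual antagonism under a shared (pleiotropic) growth trait.

When one genetic value controls growth in both sexes, the summed gradient
drives the shared trait to a compromise that sits *below* both sex-specific
optima (an antagonistic feedback: males are selected to be smaller than
females, the constraint drags females down, which selects males down
further).  The same constraint also suppresses the disruptive curvature
that drives male branching in the asymmetric parameter set.
"""

from ontosel import find_singular_strategy, hessian
from ontosel.sexual_niche import SexualNicheParams, build_model

for label, params in [
    ("baseline", SexualNicheParams()),
    ("asymmetric", SexualNicheParams(alpha=0.1, mu_e_m=0.05, beta_f=0.1,
                                     beta_m=0.01, kappa=2.0)),
]:
    independent = find_singular_strategy(build_model(params), [0.5, 0.5])
    shared_model = build_model(params, shared_trait=True)
    shared = find_singular_strategy(shared_model, [0.4, 0.4])
    vl = shared.v_star[0]
    print(f"\n=== {label} ===")
    print(f"independent optima: v_f* = {independent.v_star[0]:.3f}, "
          f"v_m* = {independent.v_star[1]:.3f}")
    print(f"shared optimum:     v_l* = {vl:.3f} "
          f"(below both: {vl < min(independent.v_star)})")
    rep = hessian(shared_model, shared.v_star)
    group = shared_model.genetics.constraint_groups[0]
    print(f"constrained curvature h_ll = {rep.constrained[group]:+.3f} "
          f"({'disruptive' if rep.constrained[group] > 0 else 'stabilising'}"
          " under the constraint)")
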
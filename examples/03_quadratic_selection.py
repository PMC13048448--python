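"""Stabilising vs disruptive selection at the singular strategy.

Assembles the Hessian of quadratic selection from its six age-resolved
components at two parameter sets: the symmetric baseline (net stabilising:
the population stays monomorphic) and a sex-asymmetric set with cheap male
growth and strong size matching (net disruptive: the male trait is a
candidate for evolutionary branching).  The assembly is cross-checked
against direct second differences of the mutant reproductive number.
"""

import numpy as np

from ontosel import classify_second_order, find_singular_strategy, hessian, \
    hessian_via_r0
from ontosel.sexual_niche import SexualNicheParams, build_model

for label, params in [
    ("baseline (symmetric demography)", SexualNicheParams()),
    ("asymmetric (cheap male growth, strong size matching)",
     SexualNicheParams(alpha=0.1, mu_e_m=0.05, beta_f=0.1, beta_m=0.01,
                       kappa=2.0)),
]:
    model = build_model(params)
    ss = find_singular_strategy(model, [0.6, 0.6])
    rep = hessian(model, ss.v_star)
    cls = classify_second_order(rep)
    print(f"\n=== {label} ===")
    print(f"v* = ({ss.v_star[0]:.3f}, {ss.v_star[1]:.3f})")
    print(f"H(v*) =\n{np.array2string(rep.H, precision=4)}")
    print(f"eigenvalues: {np.round(rep.eigenvalues, 4)} -> {cls['net']}")
    for (j, l), lab in cls["per_trait"].items():
        print(f"  trait ({model.class_names[j]}): {lab}")
    if cls["net"] == "net_disruptive":
        print(f"  divergence direction: {np.round(cls['branching_direction'], 3)}"
              " (the male axis)")
    Hfd = hessian_via_r0(model, ss.v_star)
    err = np.max(np.abs(rep.H - Hfd)) / np.max(np.abs(Hfd))
    print(f"cross-check vs direct R0 curvature: max relative "
          f"difference {err:.1e}")
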
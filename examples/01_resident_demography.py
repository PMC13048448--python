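"""Resident demography of the sexual-niche model.

Builds the two-sex model at its default parameters, solves the resident
age dynamics for a chosen pair of growth rates, and prints the equilibrium
demography: total density, secondary sex ratio, maximum and average sizes,
and the lifetime reproductive output per sex (which is two offspring —
one daughter and one son on average — whenever the population is at its
demographic equilibrium, so the resident basic reproductive number is one).
"""

import numpy as np

from ontosel import (build_model, resident_birth_structure,
                     resident_demography, solve_resident)
from ontosel.sexual_niche import SexualNicheParams

params = SexualNicheParams()  # c=0.5, alpha=0.2, mu_e=0.1, beta=0.2, kappa=1
v = np.array([0.5, 0.4])  # resident female and male basal growth rates

model = build_model(params)
demo = resident_demography(params, v)
print(f"resident growth rates      v = {v}")
print(f"equilibrium density        N_T = {demo.total_density:.1f} "
      f"(K = {params.K:.0f})")
print(f"secondary sex ratio        {demo.secondary_sex_ratio:.4f} "
      "(males accumulate: they grow slower, so die slower)")
print(f"maximum sizes (f, m)       {demo.max_sizes}")
print(f"average sizes (f, m)       {demo.average_sizes}")

traj = solve_resident(model, v)
print(f"\nage horizon (survivorship < {traj.tol:g}): a_max = "
      f"{traj.a_max:.1f} time units")
for j, name in enumerate(model.class_names):
    print(f"  sex {name}: l(10) = {float(traj.l(j, 10.0)):.4f}, "
          f"size(10) = {float(traj.x(j, 10.0)[0]):.4f}")

bs = resident_birth_structure(model, v, traj=traj)
print(f"\nbasic reproductive number  R0 = {bs.R0:.8f} (1 at equilibrium)")
print(f"birth-class frequencies    q = {bs.q} (primary sex ratio)")
print(f"lifetime offspring per sex {bs.R_individual.sum(axis=0)} "
      "(two each: replacement)")
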
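"""Directional selection: kernels, singular strategies, convergence stability."""

import numpy as np
import pytest

from ontosel import (LifeHistoryModel, build_model, make_genetic_system,
                     selection_gradient, solve_costates, solve_resident)
from ontosel.directional import classify_jacobian, convergence_stability
from ontosel.sexual_niche import (FEMALE, MALE, SexualNicheParams,
                                  solve_fixed_point)


@pytest.fixture(scope="module")
def baseline_gradient(baseline_model):
    return selection_gradient(baseline_model, [0.5, 0.4])


class TestAgeKernels:
    def test_female_kernel_closed_form(self, baseline_model, baseline_params,
                                       baseline_gradient):
        """s_hat_f(a) = (1-c)/2 (lam_x - lam_l l 2 beta_f v_f)."""
        p = baseline_params
        v = np.array([0.5, 0.4])
        traj = solve_resident(baseline_model, v)
        cs = solve_costates(baseline_model, v, traj=traj)
        lam_l = cs.lam_l[FEMALE]
        lam_x = cs.lam_x[FEMALE, :, 0]
        lf = traj.survivorship[FEMALE]
        exact = (1 - p.c) / 2 * (lam_x - lam_l * lf * 2 * p.beta_f * v[FEMALE])
        got = baseline_gradient.kernels[FEMALE, 0]
        assert np.max(np.abs(got - exact)) / np.max(np.abs(exact)) < 1e-6

    def test_kernel_integrates_to_zero_at_singular_strategy(
            self, baseline_model, baseline_vstar):
        from scipy.integrate import simpson

        grad = selection_gradient(baseline_model, baseline_vstar)
        for j in (FEMALE, MALE):
            total = simpson(grad.kernels[j, 0], x=grad.ages)
            assert abs(total) < 1e-5

    def test_male_kernel_nonpositive_without_size_matching(self):
        """With kappa=0 male siring is size-blind: growth is pure cost."""
        p = SexualNicheParams(kappa=0.0)
        grad = selection_gradient(build_model(p), [0.5, 0.3])
        assert np.all(grad.kernels[MALE, 0] <= 1e-12)
        assert grad.total(MALE) < 0

    def test_shared_kernel_is_sum_of_sex_kernels(self, baseline_params):
        model = build_model(baseline_params, shared_trait=True)
        v = [0.35, 0.35]
        grad = selection_gradient(model, v)
        group = model.genetics.constraint_groups[0]
        summed = grad.constrained_totals[group]
        assert summed == pytest.approx(
            grad.total(FEMALE) + grad.total(MALE), rel=1e-12)

    def test_doubling_female_growth_cost_weakens_selection_for_growth(
            self, baseline_params):
        v = [0.5, 0.4]
        g1 = selection_gradient(build_model(baseline_params), v)
        g2 = selection_gradient(
            build_model(baseline_params.replace(beta_f=0.4)), v)
        assert g2.total(FEMALE) < g1.total(FEMALE)


class TestHamiltonLimits:
    """Single-channel mutations recover the classic age-specific weights."""

    @staticmethod
    def _single_class_model(mortality, fecundity):
        return LifeHistoryModel(
            n_classes=1, n_traits=1, n_states=1,
            fecundity=fecundity, mortality=mortality,
            growth=lambda j, z, x, env: np.array([0.0]),
            initial_states=np.zeros((1, 1)),
            genetics=make_genetic_system("haploid_single_class"),
            class_proportions=np.ones((1, 1)),
        )

    def test_mortality_only_mutation_weights_by_remaining_reproduction(self):
        """Trait acting on mortality alone: kernel ~ l(a) lam_l(a)."""
        model = self._single_class_model(
            mortality=lambda j, z, x, env: 0.25 + 0.1 * z[0],
            fecundity=lambda i, j, z, x, env: 0.3)
        v = np.array([0.5])
        grad = selection_gradient(model, v)
        traj = solve_resident(model, v)
        cs = solve_costates(model, v, traj=traj)
        ref = traj.survivorship[0] * cs.lam_l[0]
        ratio = grad.kernels[0, 0] / np.where(ref > 1e-12, ref, np.nan)
        finite = np.isfinite(ratio)
        assert np.nanstd(ratio[finite]) / abs(np.nanmean(ratio[finite])) < 1e-6

    def test_fecundity_only_mutation_weights_by_survivorship(self):
        """Trait acting on fecundity alone: kernel ~ l(a)."""
        model = self._single_class_model(
            mortality=lambda j, z, x, env: 0.25,
            fecundity=lambda i, j, z, x, env: 0.3 * (1.0 + z[0]))
        v = np.array([0.5])
        grad = selection_gradient(model, v)
        traj = solve_resident(model, v)
        lvec = traj.survivorship[0]
        ratio = grad.kernels[0, 0] / np.where(lvec > 1e-12, lvec, np.nan)
        finite = np.isfinite(ratio)
        assert np.nanstd(ratio[finite]) / abs(np.nanmean(ratio[finite])) < 1e-6


class TestSingularStrategies:
    def test_agrees_with_fixed_point_oracle(self, baseline_params,
                                            baseline_vstar):
        """Generic root path and the model's fixed-point map coincide."""
        oracle = solve_fixed_point(baseline_params, v0=(0.5, 0.5))
        np.testing.assert_allclose(baseline_vstar, oracle, atol=1e-3)

    def test_shared_agrees_with_fixed_point_oracle(self, baseline_params,
                                                   baseline_shared_vstar):
        oracle = solve_fixed_point(baseline_params, shared=True)
        assert baseline_shared_vstar == pytest.approx(oracle, abs=1e-3)

    def test_female_optimum_independent_of_male_trait(self, baseline_vstar):
        """Female fecundity ignores males, so v_f* ignores the male trait."""
        oracle_f = solve_fixed_point(SexualNicheParams(), v0=(0.4, 0.9))
        assert oracle_f[FEMALE] == pytest.approx(baseline_vstar[FEMALE],
                                                 abs=1e-6)

    def test_gradient_signs_bracket_the_singular_value(self, baseline_model,
                                                       baseline_vstar):
        vf = baseline_vstar[FEMALE]
        below = selection_gradient(baseline_model,
                                   [vf - 0.05, baseline_vstar[MALE]])
        above = selection_gradient(baseline_model,
                                   [vf + 0.05, baseline_vstar[MALE]])
        assert below.total(FEMALE) > 0 > above.total(FEMALE)


class TestConvergenceStability:
    def test_baseline_singular_point_is_attracting(self, baseline_model,
                                                   baseline_vstar):
        rep = convergence_stability(baseline_model, baseline_vstar,
                                    n_grid=401)
        assert rep.label == "strongly_convergence_stable"
        assert rep.leading_eigenvalue < 0

    def test_scale_invariance_of_classification(self, baseline_model,
                                                baseline_vstar):
        """Reproductive-value rescaling multiplies the whole gradient:
        zeros and Jacobian signs are unaffected (normalisations agree)."""
        g_vq = selection_gradient(baseline_model, baseline_vstar)
        from ontosel import resident_birth_structure

        bs1 = resident_birth_structure(baseline_model, baseline_vstar)
        bs2 = resident_birth_structure(baseline_model, baseline_vstar,
                                       normalization="max1")
        scale = bs2.nu[0] / bs1.nu[0]
        np.testing.assert_allclose(bs2.nu, bs1.nu * scale, rtol=1e-10)
        assert abs(g_vq.total(FEMALE)) < 1e-5  # zero stays zero under scaling

    def test_negative_definite_matrix_labelled_stable(self):
        rep = classify_jacobian(np.diag([-1.0, -2.0]))
        assert rep.label == "strongly_convergence_stable"

    def test_indefinite_symmetric_part_detected(self):
        rep = classify_jacobian(np.array([[-1.0, 3.0], [3.0, -1.0]]))
        assert rep.label == "not_negative_semidefinite"
        assert rep.leading_eigenvalue == pytest.approx(2.0)

    def test_marginal_matrix_labelled(self):
        rep = classify_jacobian(np.zeros((2, 2)))
        assert rep.label == "marginal"
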
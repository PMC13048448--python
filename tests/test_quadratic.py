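"""Quadratic selection: perturbations, Hessian assembly, classification."""

import numpy as np
import pytest
from scipy.integrate import simpson

from ontosel import build_model, compute_perturbations, solve_resident
from ontosel.quadratic import classify_second_order, fundamental_matrix, hessian
from ontosel.sexual_niche import (FEMALE, MALE, SexualNicheParams,
                                  male_xx_kernel, resident_demography)


@pytest.fixture(scope="module")
def baseline_perturbations(baseline_model, baseline_vstar):
    traj = solve_resident(baseline_model, baseline_vstar)
    return traj, compute_perturbations(baseline_model, baseline_vstar,
                                       traj=traj)


class TestPerturbations:
    def test_fundamental_matrix_exponential_form(self, baseline_model,
                                                 baseline_params,
                                                 baseline_vstar):
        """Psi(a, tau) = exp(-alpha (a - tau)) for linear size loss."""
        traj = solve_resident(baseline_model, baseline_vstar, n_grid=201)
        for (a, tau) in ((5.0, 0.0), (9.0, 4.0), (3.0, 3.0)):
            psi = fundamental_matrix(baseline_model, traj, MALE, a, tau)
            assert psi[0, 0] == pytest.approx(
                np.exp(-baseline_params.alpha * (a - tau)), rel=1e-8)

    def test_state_sensitivity_closed_form(self, baseline_params,
                                           baseline_perturbations):
        """dx/dz = (1 - e^{-alpha a})/alpha, same for both sexes."""
        traj, perts = baseline_perturbations
        exact = (1 - np.exp(-baseline_params.alpha * traj.ages)) / \
            baseline_params.alpha
        for j in (FEMALE, MALE):
            err = np.max(np.abs(perts.dx_dz[j, 0, :, 0] - exact))
            assert err / exact.max() < 1e-6

    def test_survivorship_sensitivity_closed_form(self, baseline_params,
                                                  baseline_vstar,
                                                  baseline_perturbations):
        """dl/dz = -l 2 beta v a (mortality has no size dependence)."""
        traj, perts = baseline_perturbations
        demo = resident_demography(baseline_params, baseline_vstar)
        for j, beta in ((FEMALE, baseline_params.beta_f),
                        (MALE, baseline_params.beta_m)):
            lvec = np.exp(-demo.mortality[j] * traj.ages)
            exact = -lvec * 2 * beta * baseline_vstar[j] * traj.ages
            err = np.max(np.abs(perts.dl_dz[j, 0] - exact))
            assert err / np.max(np.abs(exact)) < 1e-6

    def test_sensitivities_vanish_at_birth(self, baseline_perturbations):
        _, perts = baseline_perturbations
        assert np.max(np.abs(perts.dx_dz[:, :, 0, :])) < 1e-12
        assert np.max(np.abs(perts.dl_dz[:, :, 0])) < 1e-12

    def test_birth_frequencies_fixed_by_sex_ratio(self,
                                                  baseline_perturbations):
        """Constant class proportions: traits cannot shift q at all."""
        _, perts = baseline_perturbations
        assert np.max(np.abs(perts.dq_dz)) < 1e-8
        assert np.max(np.abs(perts.dq_dz.sum(axis=-1))) < 1e-8


class TestHessianAssembly:
    def test_matches_direct_r0_curvature(self, baseline_model, baseline_vstar,
                                         baseline_hessian):
        """Primary gate: component assembly = second differences of R0."""
        from ontosel import hessian_via_r0

        Hfd = hessian_via_r0(baseline_model, baseline_vstar)
        scale = np.max(np.abs(Hfd))
        assert np.max(np.abs(baseline_hessian.H - Hfd)) / scale < 1e-3

    def test_asymmetric_case_matches_r0_curvature(self, asymmetric_model,
                                                  asymmetric_vstar,
                                                  asymmetric_hessian):
        from ontosel import hessian_via_r0

        Hfd = hessian_via_r0(asymmetric_model, asymmetric_vstar)
        scale = np.max(np.abs(Hfd))
        assert np.max(np.abs(asymmetric_hessian.H - Hfd)) / scale < 1e-3

    def test_symmetry(self, baseline_hessian):
        np.testing.assert_allclose(baseline_hessian.H,
                                   baseline_hessian.H.T, atol=1e-12)

    def test_cross_sex_kernel_is_zero(self, baseline_hessian):
        """Sexes are only coupled through birth frequencies, which are
        pinned by the fixed primary sex ratio: the mixed kernel vanishes."""
        mixed = baseline_hessian.kernel_total(FEMALE, 0, MALE, 0)
        assert np.max(np.abs(mixed)) < 1e-10
        assert abs(baseline_hessian.blocks[(FEMALE, MALE)][0, 0]) < 1e-10

    def test_male_size_component_matches_closed_form(self, asymmetric_model,
                                                     asymmetric_params,
                                                     asymmetric_vstar,
                                                     asymmetric_hessian):
        """Generic xx machinery = model-specific siring-curvature kernel."""
        kern = asymmetric_hessian.component_kernels[(MALE, 0, MALE, 0)]["xx"]
        closed = male_xx_kernel(asymmetric_params, asymmetric_vstar,
                                asymmetric_hessian.ages)
        scale = np.max(np.abs(closed))
        assert np.max(np.abs(kern - closed)) / scale < 1e-4

    def test_male_size_component_vanishes_without_size_matching(
            self, kappa0_singular):
        """kappa = 0 removes all curvature of siring rate in male size."""
        p = SexualNicheParams(kappa=0.0)
        ss = kappa0_singular
        assert ss.boundary_pinned  # male trait pinned at zero
        ages = np.linspace(0.0, 50.0, 101)
        np.testing.assert_allclose(
            male_xx_kernel(p, [ss.v_star[0], 0.0], ages), 0.0, atol=1e-15)

    def test_rejects_non_singular_input(self, baseline_model):
        with pytest.raises(ValueError, match="singular"):
            hessian(baseline_model, [0.8, 0.8], n_grid=301)


class TestClassification:
    def test_baseline_is_net_stabilising(self, baseline_hessian):
        cls = classify_second_order(baseline_hessian)
        assert cls["net"] == "net_stabilising"
        assert all(lab == "stabilising"
                   for lab in cls["per_trait"].values())

    def test_asymmetric_case_is_net_disruptive_via_male_trait(
            self, asymmetric_hessian):
        cls = classify_second_order(asymmetric_hessian)
        assert cls["net"] == "net_disruptive"
        assert cls["per_trait"][(MALE, 0)] == "disruptive"
        assert cls["per_trait"][(FEMALE, 0)] == "stabilising"
        # divergence direction is the male axis
        assert abs(cls["branching_direction"][1]) > 0.99

    def test_diagonal_matrices_classified_directly(self, baseline_hessian):
        import dataclasses

        rep = dataclasses.replace(
            baseline_hessian, H=np.diag([-1.0, 0.5]),
            eigenvalues=np.array([0.5, -1.0]),
            leading_eigenvector=np.array([0.0, 1.0]),
            trait_labels={(0, 0): "stabilising", (1, 0): "disruptive"})
        cls = classify_second_order(rep)
        assert cls["net"] == "net_disruptive"
        np.testing.assert_allclose(np.abs(cls["branching_direction"]),
                                   [0.0, 1.0])


class TestSharedTraitCurvature:
    def test_constrained_curvature_is_sum_of_sex_blocks(
            self, asymmetric_params, asymmetric_shared_vstar):
        """Chain rule: h_shared = h_ff + h_mm + 2 h_fm (here h_fm = 0)."""
        model = build_model(asymmetric_params, shared_trait=True)
        vl = asymmetric_shared_vstar
        rep = hessian(model, [vl, vl])
        group = model.genetics.constraint_groups[0]
        expected = (rep.H[0, 0] + rep.H[1, 1] + 2 * rep.H[0, 1])
        assert rep.constrained[group] == pytest.approx(expected, rel=1e-12)
        # the constraint suppresses the male-driven disruptive curvature
        assert rep.constrained[group] < 0
        # and the constrained kernel is the sum of the sex-specific kernels
        kern_sum = (rep.kernel_total(FEMALE, 0, FEMALE, 0)
                    + rep.kernel_total(MALE, 0, MALE, 0))
        combined = simpson(kern_sum, x=rep.ages) * 0.25
        assert combined == pytest.approx(rep.constrained[group], rel=1e-8)
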
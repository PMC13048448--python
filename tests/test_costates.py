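"""Costates, Hamiltonians and their defining identities."""

import numpy as np
import pytest

from ontosel import (evaluate_hamiltonian, remaining_reproduction,
                     resident_birth_structure, solve_costates)
from ontosel.costates import costate_residuals, hamiltonian_partial
from ontosel.sexual_niche import FEMALE, MALE, resident_demography


@pytest.fixture(scope="module")
def costates(baseline_model, baseline_trajectory):
    return solve_costates(baseline_model, baseline_trajectory.v,
                          traj=baseline_trajectory)


@pytest.fixture(scope="module")
def costates_oriented(baseline_model, baseline_trajectory):
    return solve_costates(baseline_model, baseline_trajectory.v,
                          traj=baseline_trajectory, mode="class_oriented")


class TestSurvivorshipCostate:
    def test_initial_value_is_lifetime_output_of_two(self, costates):
        """lam_l(0) = 2 for both sexes at the diploid resident equilibrium."""
        np.testing.assert_allclose(costates.lam_l[:, 0], [2.0, 2.0],
                                   atol=1e-6)

    def test_remaining_reproduction_at_birth_equals_lifetime_fecundity(
            self, baseline_model, baseline_trajectory, costates_oriented):
        traj = baseline_trajectory
        for i in range(2):
            for j in range(2):
                r0 = remaining_reproduction(traj, baseline_model, traj.v,
                                            i, j, 0.0)
                assert r0 == pytest.approx(
                    costates_oriented.R_total[i, j], rel=1e-8)
                tail = remaining_reproduction(traj, baseline_model, traj.v,
                                              i, j, traj.a_max)
                assert abs(tail) < 1e-8

    def test_female_remaining_reproduction_closed_form(
            self, baseline_model, baseline_trajectory, baseline_params):
        """Tail integral of l_f f_ff matches its analytic evaluation."""
        traj = baseline_trajectory
        p = baseline_params
        demo = resident_demography(p, traj.v)
        df = 1.0 - demo.total_density / p.K
        mu, al, vf, c = demo.mortality[FEMALE], p.alpha, traj.v[FEMALE], p.c
        for a in (0.0, 3.0, 11.0, 30.0):
            exact = (1 - c) * df * (vf / al) * (
                np.exp(-mu * a) / mu - np.exp(-(mu + al) * a) / (mu + al))
            got = remaining_reproduction(traj, baseline_model, traj.v,
                                         FEMALE, FEMALE, a)
            assert got == pytest.approx(exact, rel=1e-7)


class TestStateCostate:
    def test_terminal_condition(self, costates):
        assert np.max(np.abs(costates.lam_x[:, -1, :])) < 1e-8

    def test_female_closed_form(self, costates, baseline_params,
                                baseline_trajectory):
        """lam_x_f(a) = (1 - N_T/K) e^{-mu_f a} / (mu_f + alpha)."""
        p = baseline_params
        traj = baseline_trajectory
        demo = resident_demography(p, traj.v)
        df = 1.0 - demo.total_density / p.K
        mu = demo.mortality[FEMALE]
        a = np.linspace(0.0, 0.8 * traj.a_max, 40)
        exact = df * np.exp(-mu * a) / (mu + p.alpha)
        got = np.asarray(costates.lam_x_at(FEMALE, a))[0]
        assert np.max(np.abs(got - exact) / exact.max()) < 1e-8

    def test_ode_residuals_vanish(self, baseline_model, costates):
        res = costate_residuals(baseline_model, costates, n_check=25)
        assert res["lam_l"] < 1e-6
        assert res["lam_x"] < 1e-6


class TestReproductiveValueIdentity:
    def test_birth_value_identity(self, baseline_model, baseline_trajectory,
                                  costates_oriented):
        """nu_j = sum_i nu_i gamma_ij lam_l_ij(0) at the resident equilibrium."""
        bs = resident_birth_structure(baseline_model, baseline_trajectory.v,
                                      traj=baseline_trajectory)
        gamma = baseline_model.genetics.transmission
        lam0 = costates_oriented.lam_l[:, :, 0]  # (i, j)
        for j in range(2):
            rhs = sum(bs.nu[i] * gamma[i, j] * lam0[i, j] for i in range(2))
            assert rhs == pytest.approx(bs.nu[j], abs=1e-6)

    def test_class_oriented_costates_scale_with_class_proportions(
            self, baseline_model, baseline_trajectory, costates,
            costates_oriented):
        """With f_ij = c_ij f_j the oriented costates are c_ij-scaled copies.

        Compared where survivorship is at least 1e-6: the survivorship
        costate divides by l(a), so deep-tail values are ill-conditioned
        (and enter every downstream integral l-weighted anyway).
        """
        cij = baseline_model.class_proportions
        for i in range(2):
            for j in range(2):
                mask = baseline_trajectory.survivorship[j] >= 1e-6
                np.testing.assert_allclose(
                    costates_oriented.lam_l[i, j][mask],
                    cij[i, j] * costates.lam_l[j][mask],
                    rtol=1e-6, atol=1e-9)
                np.testing.assert_allclose(
                    costates_oriented.lam_x[i, j][mask],
                    cij[i, j] * costates.lam_x[j][mask],
                    rtol=1e-6, atol=1e-9)


class TestHamiltonian:
    def test_matches_explicit_three_term_sum(self, baseline_model, costates,
                                             baseline_params,
                                             baseline_trajectory):
        """H_f = l f_f - lam_l (mu_e + beta v^2) l + lam_x (v - alpha x)."""
        p = baseline_params
        traj = baseline_trajectory
        env = traj.env
        vf = traj.v[FEMALE]
        for a in (0.5, 4.0, 15.0):
            l = float(traj.l(FEMALE, a))
            x = float(traj.x(FEMALE, a)[0])
            lam_l = float(costates.lam_l_at(FEMALE, a))
            lam_x = float(costates.lam_x_at(FEMALE, a)[0])
            ff = x * env.density_factor
            expected = (l * ff
                        - lam_l * (p.mu_e_f + p.beta_f * vf**2) * l
                        + lam_x * (vf - p.alpha * x))
            got = evaluate_hamiltonian(baseline_model, costates, FEMALE, a)
            assert got == pytest.approx(expected, rel=1e-9)

    def test_trait_derivative_matches_selection_bracket(
            self, baseline_model, costates, baseline_params,
            baseline_trajectory):
        """dH_f/dz at resident = lam_x - lam_l l 2 beta_f v_f."""
        p = baseline_params
        traj = baseline_trajectory
        vf = traj.v[FEMALE]
        for a in (1.0, 6.0, 20.0):
            l = float(traj.l(FEMALE, a))
            lam_l = float(costates.lam_l_at(FEMALE, a))
            lam_x = float(costates.lam_x_at(FEMALE, a)[0])
            exact = lam_x - lam_l * l * 2 * p.beta_f * vf
            fd = hamiltonian_partial(baseline_model, costates, FEMALE, a,
                                     (("z", 0),))
            assert fd == pytest.approx(exact, rel=1e-6)

    def test_growth_term_only_when_rates_vanish(self, baseline_model,
                                                costates, baseline_trajectory):
        """With fecundity and mortality zeroed, H reduces to lam_x . g."""
        traj = baseline_trajectory
        a = 5.0
        x = np.array([1.3])
        lam_x = float(costates.lam_x_at(MALE, a)[0])
        # l = 0 kills the fecundity and mortality terms exactly
        got = evaluate_hamiltonian(baseline_model, costates, MALE, a,
                                   l=0.0, x=x)
        g = traj.v[MALE] - baseline_model.params.alpha * x[0]
        assert got == pytest.approx(lam_x * g, rel=1e-12)

    def test_class_specific_requires_constant_proportions(
            self, baseline_model, baseline_trajectory):
        model = baseline_model
        saved = model.class_proportions
        try:
            model.class_proportions = None
            with pytest.raises(ValueError):
                solve_costates(model, baseline_trajectory.v,
                               traj=baseline_trajectory,
                               mode="class_specific")
        finally:
            model.class_proportions = saved
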
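"""The worked sexual-niche model: demography, fecundities, shortcuts."""

import numpy as np
import pytest
from scipy.integrate import quad

from ontosel import male_fecundity
from ontosel.sexual_niche import (FEMALE, MALE, SexualNicheParams,
                                  _Environment, resident_demography,
                                  solve_fixed_point,
                                  total_reproduction_rates)


@pytest.fixture(scope="module")
def demo(baseline_params):
    return resident_demography(baseline_params, [0.5, 0.4])


class TestResidentDemography:
    def test_secondary_sex_ratio_symmetry(self):
        """Equal mortalities and c = 1/2 leave the living sex ratio even."""
        p = SexualNicheParams()
        d = resident_demography(p, [0.5, 0.5])
        assert d.secondary_sex_ratio == pytest.approx(0.5)

    def test_secondary_sex_ratio_favours_longer_lived_sex(self, demo):
        # v_m < v_f here, so males die less and accumulate
        assert demo.secondary_sex_ratio > 0.5

    def test_size_density_normalised(self, demo):
        for j in (FEMALE, MALE):
            total, _ = quad(lambda x: demo.size_density(j, x), 0.0,
                            demo.max_sizes[j], limit=200)
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_size_density_shape_follows_mortality_balance(self,
                                                          baseline_params):
        """Density rises with size iff size loss outpaces mortality."""
        p = baseline_params
        d = resident_demography(p, [0.5, 0.5])
        xs = np.linspace(0.05, 0.95, 20) * d.max_sizes[FEMALE]
        dens = d.size_density(FEMALE, xs)
        if p.alpha > d.mortality[FEMALE]:
            assert np.all(np.diff(dens) > 0)
        else:
            assert np.all(np.diff(dens) < 0)

    def test_average_size_closed_form(self, demo, baseline_params):
        """Mean of the standing size density is v/(mu + alpha)."""
        for j in (FEMALE, MALE):
            mean, _ = quad(lambda x: x * demo.size_density(j, x), 0.0,
                           demo.max_sizes[j], limit=200)
            assert mean == pytest.approx(demo.average_sizes[j], abs=1e-6)

    def test_equilibrium_density_from_lifetime_size_integral(
            self, baseline_params):
        """N_T = K (1 - 1/((1-c) * v_f/(mu_f (mu_f+alpha))))."""
        p = baseline_params
        v = [0.5, 0.4]
        d = resident_demography(p, v)
        mu = d.mortality[FEMALE]
        lifetime_size, _ = quad(
            lambda a: np.exp(-mu * a) * v[FEMALE]
            * (1 - np.exp(-p.alpha * a)) / p.alpha, 0.0, np.inf, limit=400)
        assert lifetime_size == pytest.approx(
            v[FEMALE] / (mu * (mu + p.alpha)), rel=1e-8)
        assert d.total_density == pytest.approx(
            p.K * (1 - 1 / ((1 - p.c) * lifetime_size)), rel=1e-10)

    def test_extinction_flagged_but_analysis_continues(self):
        p = SexualNicheParams(mu_e_f=2.0)  # lethal female environment
        d = resident_demography(p, [0.5, 0.4])
        assert d.extinct and d.total_density <= 0
        # downstream quantities still evaluate
        fm = male_fecundity(p, [0.5, 0.4], 1.0)
        assert np.isfinite(fm) and fm > 0


class TestMaleFecundity:
    def test_fisher_condition(self, baseline_params):
        """Total siring balances total egg production exactly."""
        for v in ([0.5, 0.4], [0.7, 0.7], [0.3, 0.8]):
            eggs, sires = total_reproduction_rates(baseline_params, v)
            assert abs(eggs - sires) / eggs < 1e-6

    def test_competition_normalises_over_resident_males(self,
                                                        baseline_params):
        """Resident males' relative abilities sum to one for any female."""
        env = _Environment(baseline_params, np.array([0.5, 0.4]))
        d = env.demography
        for xf in (0.3, 1.0, 2.0):
            comp = env.competition(env.sizes[MALE], xf)
            total = d.secondary_sex_ratio * d.total_density * \
                float(env.age_weights[MALE] @ comp)
            assert total == pytest.approx(1.0, rel=1e-8)

    def test_size_blind_competition_shares_eggs_evenly(self,
                                                       baseline_params):
        """kappa = 0: every male sires total eggs / male count."""
        p = baseline_params.replace(kappa=0.0)
        v = [0.5, 0.4]
        d = resident_demography(p, v)
        eggs, _ = total_reproduction_rates(p, v)
        per_male = eggs / (d.secondary_sex_ratio * d.total_density)
        for xm in (0.0, 0.7, 1.9):
            assert male_fecundity(p, v, xm) == pytest.approx(per_male,
                                                             rel=1e-8)

    def test_degenerate_nongrowing_males(self, baseline_params):
        """v_m = 0 collapses males to a point mass at size zero."""
        v = [0.5, 0.0]
        fm = male_fecundity(baseline_params, v, 0.0)
        assert np.isfinite(fm) and fm > 0
        eggs, sires = total_reproduction_rates(baseline_params, v)
        assert abs(eggs - sires) / eggs < 1e-6


class TestModelAssembly:
    def test_growth_rate_boundaries(self, baseline_model):
        env = baseline_model.env(np.array([0.5, 0.4]))
        z = np.array([0.5])
        assert baseline_model.growth(0, z, np.array([0.0]), env)[0] == \
            pytest.approx(0.5)
        alpha = baseline_model.params.alpha
        assert baseline_model.growth(0, z, np.array([0.5 / alpha]), env)[0] \
            == pytest.approx(0.0, abs=1e-14)

    def test_mortality_reduces_to_extrinsic_rate_without_growth(
            self, baseline_model, baseline_params):
        env = baseline_model.env(np.array([0.5, 0.4]))
        mu = baseline_model.mortality(0, np.array([0.0]), np.array([1.0]), env)
        assert mu == pytest.approx(baseline_params.mu_e_f)

    def test_female_fecundity_linear_in_size(self, baseline_model):
        env = baseline_model.env(np.array([0.5, 0.4]))
        z = np.array([0.5])
        f1 = baseline_model.total_fecundity(0, z, np.array([1.0]), env)
        f2 = baseline_model.total_fecundity(0, z, np.array([2.0]), env)
        assert f2 == pytest.approx(2 * f1, rel=1e-12)
        assert f1 == pytest.approx(env.density_factor, rel=1e-12)


class TestComparativeStatics:
    """Directional responses of the singular strategy to the parameters."""

    def test_parameter_response_signs(self, baseline_params, baseline_vstar):
        base = solve_fixed_point(baseline_params, v0=baseline_vstar)
        cases = [
            ("beta_f", 0.3, FEMALE, -1),  # costlier female growth: slower
            ("mu_e_f", 0.15, FEMALE, +1),  # female risk: live fast
            ("alpha", 0.25, FEMALE, +1),  # size loss: females compensate
            ("alpha", 0.25, MALE, -1),  # but males track smaller females
            ("beta_m", 0.3, MALE, -1),
            ("mu_e_m", 0.15, MALE, +1),
        ]
        for name, value, sex, sign in cases:
            p = baseline_params.replace(**{name: value})
            vstar = solve_fixed_point(p, v0=base)
            delta = vstar[sex] - base[sex]
            assert np.sign(delta) == sign, (name, value, sex, delta)

    def test_shared_optimum_sits_below_both_sex_optima(
            self, baseline_vstar, baseline_shared_vstar):
        """Sexually antagonistic feedback drags the shared trait below
        both sex-specific optima, not between them."""
        assert baseline_shared_vstar < min(baseline_vstar)

    def test_disruptive_kernel_requires_positive_weighted_mismatch(
            self, asymmetric_params, asymmetric_vstar):
        """Wherever the male xx kernel is positive, the fecundity-weighted
        average of (2 kappa (x_m - x_f)^2 - 1) must be positive."""
        from ontosel.sexual_niche import male_xx_kernel

        ages = np.linspace(0.0, 60.0, 121)
        kern = male_xx_kernel(asymmetric_params, asymmetric_vstar, ages)
        assert np.any(kern > 0)  # disruptive ages exist
        env = _Environment(asymmetric_params, np.asarray(asymmetric_vstar))
        xm = env.resident_size(MALE, ages)[:, None]
        xf = env.sizes[FEMALE][None, :]
        diff = xm - xf
        cmat = np.exp(-asymmetric_params.kappa * diff**2) / env.male_norms
        bracket = ((env.female_egg_rates * cmat
                    * (2 * asymmetric_params.kappa * diff**2 - 1))
                   @ env.age_weights[FEMALE])
        assert np.all(bracket[kern > 1e-12] > 0)
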
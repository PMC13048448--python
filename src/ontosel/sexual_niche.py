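"""Two-sex sexual-niche-partitioning model of growth under size matching.

The built-in worked example: a diploid (or haplodiploid), dioecious,
age-structured population in which each sex evolves a single non-plastic
trait, its basal growth rate ``v_j``.  Size (the single internal state)
follows ``dx/da = z_j - alpha * x`` from ``x(0) = 0``; mortality is
``mu_j = mu_e_j + beta_j * z_j**2`` (a survival cost of growth); female
fecundity rises linearly with size and is density dependent,
``f_f = x_f * (1 - N_T / K)``; and male fecundity (siring rate) comes from
competition among males for the eggs of each female, with competitive
ability declining in the male-female size mismatch,
``exp(-kappa * (x_m - x_f)**2)``.  Sex is determined at birth with a fixed
primary sex ratio ``c`` (proportion of males), so class proportions at birth
are constant and the class-specific (rather than class-oriented) costate
machinery applies.

The resident demography is available in closed form and is exposed both for
speed and as an independent oracle for the generic solvers:

* size and survivorship: ``x_j(a) = v_j * (1 - exp(-alpha*a)) / alpha``,
  ``l_j(a) = exp(-mu_j * a)`` with ``mu_j = mu_e_j + beta_j * v_j**2``;
* equilibrium density: ``N_T = K * (1 - 1 / ((1-c) * I_f))`` where
  ``I_f = v_f / (mu_f * (mu_f + alpha))`` is a female's lifetime
  density-discounted size integral, so that each female leaves exactly one
  daughter and the resident basic reproductive number is one;
* secondary sex ratio ``c_tilde = c*mu_f / ((1-c)*mu_m + c*mu_f)``;
* the standing size density of sex ``j``,
  ``chi_j(x) = (mu_j / v_j) * (1 - alpha*x/v_j)**((mu_j - alpha)/alpha)``
  on ``[0, v_j/alpha]``.

All integrals over standing size distributions are evaluated in the age
variable (sizes are a monotone function of age and the standing age density
is ``mu_j * exp(-mu_j * a)``), which avoids the integrable singularity of
``chi_j`` at the maximum size and converges at spectral rate under
Gauss-Legendre quadrature.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Any

import numpy as np
import yaml

from .genetics import GeneticSystem, make_genetic_system
from .model import LifeHistoryModel, register_model

__all__ = [
    "SexualNicheParams",
    "ResidentDemography",
    "resident_demography",
    "male_fecundity",
    "build_model",
    "closed_form_selection",
    "fixed_point_map",
    "solve_fixed_point",
    "male_xx_kernel",
    "total_reproduction_rates",
]

FEMALE, MALE = 0, 1

#: age-quadrature defaults: nodes per sex, survivorship cut for the horizon
_N_NODES = 200
_AGE_CUT = 1e-14


@dataclass(frozen=True)
class SexualNicheParams:
    """Parameters of the sexual-niche model (units: size, time arbitrary)."""

    c: float = 0.5  # primary sex ratio (proportion of males at birth)
    alpha: float = 0.2  # size-loss rate, per unit time
    mu_e_f: float = 0.1  # extrinsic female mortality, per unit time
    mu_e_m: float = 0.1  # extrinsic male mortality, per unit time
    beta_f: float = 0.2  # survival cost of female growth, per trait^2 * time
    beta_m: float = 0.2  # survival cost of male growth, per trait^2 * time
    kappa: float = 1.0  # strength of size-matching sexual selection, per size^2
    K: float = 1e4  # density-dependence scale, individuals

    def __post_init__(self):
        if not 0.0 < self.c < 1.0:
            raise ValueError(f"c must be in (0, 1), got {self.c}")
        if self.alpha <= 0 or self.K <= 0:
            raise ValueError("alpha and K must be positive")
        if min(self.mu_e_f, self.mu_e_m, self.beta_f, self.beta_m, self.kappa) < 0:
            raise ValueError("mu_e, beta and kappa must be nonnegative")

    def mortality_rate(self, sex: int, vj: float) -> float:
        mu_e = self.mu_e_f if sex == FEMALE else self.mu_e_m
        beta = self.beta_f if sex == FEMALE else self.beta_m
        return mu_e + beta * vj**2

    def beta(self, sex: int) -> float:
        return self.beta_f if sex == FEMALE else self.beta_m

    # -- flat key:value (YAML) round trip ---------------------------------
    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(
            {k: float(getattr(self, k)) for k in
             ("c", "alpha", "mu_e_f", "mu_e_m", "beta_f", "beta_m", "kappa", "K")},
            sort_keys=False,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SexualNicheParams":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        elif isinstance(source, str) and "\n" in source:
            data = yaml.safe_load(io.StringIO(source))
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        return cls(**{k: float(v) for k, v in data.items()})

    def replace(self, **kwargs) -> "SexualNicheParams":
        return replace(self, **kwargs)


@dataclass
class ResidentDemography:
    """Closed-form resident equilibrium demography at allelic values ``v``."""

    params: SexualNicheParams
    v: np.ndarray  # (v_f, v_m)
    mortality: np.ndarray  # resident mortality rate per sex
    total_density: float  # N_T (individuals; <= 0 flags extinction)
    secondary_sex_ratio: float  # proportion of males among living residents
    max_sizes: np.ndarray  # v_j / alpha per sex
    average_sizes: np.ndarray  # mean of the standing size density, v_j/(mu_j+alpha)
    extinct: bool

    def size_density(self, sex: int, x) -> np.ndarray:
        """Standing size density ``chi_j(x)`` on ``[0, v_j/alpha]``."""
        vj = self.v[sex]
        mu = self.mortality[sex]
        alpha = self.params.alpha
        x = np.asarray(x, dtype=float)
        if vj <= 0:
            raise ValueError("size density undefined for a non-growing sex (v_j = 0)")
        inside = (x >= 0) & (x < vj / alpha)
        out = np.zeros_like(x, dtype=float)
        base = np.where(inside, 1.0 - alpha * x / vj, 1.0)
        out = np.where(inside, (mu / vj) * base ** ((mu - alpha) / alpha), 0.0)
        return out


def resident_demography(params: SexualNicheParams, v) -> ResidentDemography:
    """Closed-form equilibrium demography of the resident population."""
    v = np.asarray(v, dtype=float).reshape(2)
    mu = np.array([params.mortality_rate(j, v[j]) for j in (FEMALE, MALE)])
    alpha, c, K = params.alpha, params.c, params.K
    # lifetime (undiscounted by density) size integral of a female
    if v[FEMALE] > 0:
        lifetime_size = v[FEMALE] / (mu[FEMALE] * (mu[FEMALE] + alpha))
        NT = K * (1.0 - 1.0 / ((1.0 - c) * lifetime_size))
    else:
        NT = -np.inf  # no female growth, no recruitment
    ctilde = c * mu[FEMALE] / ((1.0 - c) * mu[MALE] + c * mu[FEMALE])
    return ResidentDemography(
        params=params,
        v=v,
        mortality=mu,
        total_density=NT,
        secondary_sex_ratio=ctilde,
        max_sizes=v / alpha,
        average_sizes=v / (mu + alpha),
        extinct=bool(NT <= 0),
    )


class _Environment:
    """Resident environment: demography plus cached quadrature grids.

    Sizes are indexed by age; ``age_nodes[j]``/``age_weights[j]`` give a
    Gauss-Legendre rule for integrals against the standing age density
    ``mu_j * exp(-mu_j * a)`` of sex ``j`` (the weights already include the
    density factor, so they sum to ~1).
    """

    def __init__(self, params: SexualNicheParams, v, n_nodes: int | None = None):
        n_nodes = n_nodes or _N_NODES
        self.params = params
        self.v = np.asarray(v, dtype=float).reshape(2)
        self.demography = resident_demography(params, self.v)
        d = self.demography
        self.density_factor = 1.0 - d.total_density / params.K  # 1 - N_T/K
        self.age_nodes = []
        self.age_weights = []
        base_x, base_w = np.polynomial.legendre.leggauss(n_nodes)
        for j in (FEMALE, MALE):
            horizon = -np.log(_AGE_CUT) / d.mortality[j]
            a = 0.5 * horizon * (base_x + 1.0)
            w = 0.5 * horizon * base_w * d.mortality[j] * np.exp(-d.mortality[j] * a)
            self.age_nodes.append(a)
            self.age_weights.append(w)
        self.sizes = [self.resident_size(j, self.age_nodes[j]) for j in (FEMALE, MALE)]
        # collective egg production by females of each size node:
        # (1 - c~) N_T chi_f(x_f) f_f(x_f) dx_f, expressed on the age grid
        self.female_egg_rates = (
            (1.0 - d.secondary_sex_ratio)
            * d.total_density
            * self.sizes[FEMALE]
            * self.density_factor
        )
        # male normalisation per female size node:
        # integral of c~ N_T chi_m(x_m) Ctilde(x_m, x_f) over male sizes
        xm = self.sizes[MALE][:, None]
        xf = self.sizes[FEMALE][None, :]
        cmat = np.exp(-params.kappa * (xm - xf) ** 2)
        self.male_norms = (
            d.secondary_sex_ratio
            * d.total_density
            * (self.age_weights[MALE] @ cmat)
        )

    def resident_size(self, sex: int, a) -> np.ndarray:
        vj = self.v[sex]
        alpha = self.params.alpha
        return vj * (1.0 - np.exp(-alpha * np.asarray(a, dtype=float))) / alpha

    def competition(self, xm, xf) -> np.ndarray:
        """Relative competitive ability C(x_m, x_f) of a focal male.

        The raw size-matching kernel normalised by the total competitive
        ability of all resident males for a female of size ``xf``.
        """
        xm = np.asarray(xm, dtype=float)
        xf = np.asarray(xf, dtype=float)
        raw = np.exp(-self.params.kappa * (xm - xf) ** 2)
        d = self.demography
        resident_males = np.exp(
            -self.params.kappa * (self.sizes[MALE][..., None] - xf) ** 2
        )
        norm = d.secondary_sex_ratio * d.total_density * (
            self.age_weights[MALE] @ resident_males
        )
        return raw / norm

    def male_siring_rate(self, xm) -> np.ndarray:
        """Siring rate of a male of size ``xm`` (scalar or array)."""
        xm = np.asarray(xm, dtype=float)
        scalar = xm.ndim == 0
        xm2 = np.atleast_1d(xm)[:, None]
        xf = self.sizes[FEMALE][None, :]
        cmat = np.exp(-self.params.kappa * (xm2 - xf) ** 2)
        out = (cmat / self.male_norms[None, :] * self.female_egg_rates[None, :]) @ \
            self.age_weights[FEMALE]
        return float(out[0]) if scalar else out

    def male_siring_rate_dx(self, xm) -> np.ndarray:
        """Analytic derivative of the siring rate with respect to male size."""
        xm = np.asarray(xm, dtype=float)
        scalar = xm.ndim == 0
        xm2 = np.atleast_1d(xm)[:, None]
        xf = self.sizes[FEMALE][None, :]
        diff = xm2 - xf
        cmat = np.exp(-self.params.kappa * diff**2)
        integrand = -2.0 * self.params.kappa * diff * cmat / self.male_norms[None, :]
        out = (integrand * self.female_egg_rates[None, :]) @ self.age_weights[FEMALE]
        return float(out[0]) if scalar else out


def _fecundity_by_sex(sex: int, x, env: _Environment):
    """Total offspring-production rate of an individual of given sex/size."""
    if sex == FEMALE:
        return np.asarray(x, dtype=float) * env.density_factor
    return env.male_siring_rate(x)


def male_fecundity(params: SexualNicheParams, v, xm) -> float:
    """Siring rate of a male of size ``xm`` in a resident population at ``v``."""
    env = _Environment(params, v)
    return env.male_siring_rate(xm)


def total_reproduction_rates(params: SexualNicheParams, v) -> tuple[float, float]:
    """Population-level egg rate of females and siring rate of males.

    Equal by construction (every egg has one sire); returned separately so the
    balance can be checked numerically.
    """
    env = _Environment(params, v)
    d = env.demography
    eggs = float(env.age_weights[FEMALE] @ env.female_egg_rates)
    male_rates = env.male_siring_rate(env.sizes[MALE])
    sires = float(
        d.secondary_sex_ratio * d.total_density * (env.age_weights[MALE] @ male_rates)
    )
    return eggs, sires


def build_model(
    params: SexualNicheParams | None = None,
    genetics: GeneticSystem | None = None,
    shared_trait: bool = False,
    **param_kwargs,
) -> LifeHistoryModel:
    """Assemble the sexual-niche model as a :class:`LifeHistoryModel`.

    ``genetics`` defaults to the diploid two-sex system.  With
    ``shared_trait=True`` a pleiotropic constraint forces the female and male
    growth rates to share one allelic value.
    """
    params = params or SexualNicheParams(**param_kwargs)
    genetics = genetics or make_genetic_system("diploid_two_sex", params.c)
    if shared_trait:
        genetics = genetics.with_constraints(((FEMALE, 0), (MALE, 0)))
    c = params.c
    class_proportions = np.array([[1.0 - c, 1.0 - c], [c, c]])

    def fecundity(i, j, z, x, env):
        return class_proportions[i, j] * _fecundity_by_sex(j, x[0], env)

    def total_fecundity(j, z, x, env):
        return _fecundity_by_sex(j, x[0], env)

    def mortality(j, z, x, env):
        mu_e = params.mu_e_f if j == FEMALE else params.mu_e_m
        beta = params.beta_f if j == FEMALE else params.beta_m
        return mu_e + beta * z[0] ** 2

    def growth(j, z, x, env):
        return np.array([z[0] - params.alpha * x[0]])

    model = LifeHistoryModel(
        n_classes=2,
        n_traits=1,
        n_states=1,
        fecundity=fecundity,
        mortality=mortality,
        growth=growth,
        initial_states=np.zeros((2, 1)),
        genetics=genetics,
        class_proportions=class_proportions,
        total_fecundity=total_fecundity,
        environment=lambda m, v: _Environment(params, v),
        class_names=("f", "m"),
        name="sexual_niche",
    )
    model.params = params  # convenience back-reference
    return model


# ---------------------------------------------------------------------------
# model-specific closed-form shortcuts, used as independent oracles
# ---------------------------------------------------------------------------

def _costate_integrals(params: SexualNicheParams, v) -> dict[str, float]:
    """Lifetime integrals of the sex-specific costates, by direct quadrature.

    Uses only the closed-form resident demography and Fubini-collapsed
    double integrals (independent of the generic ODE machinery):

    * ``int lam_x_j da  = int l_j(t) f_j'(x_j(t)) (1 - exp(-alpha t))/alpha dt``
    * ``int lam_l_j l_j da = int t l_j(t) f_j(x_j(t)) dt``

    For females both have fully closed forms.
    """
    v = np.asarray(v, dtype=float).reshape(2)
    env = _Environment(params, v)
    d = env.demography
    alpha = params.alpha
    muf, mum = d.mortality
    df = env.density_factor
    out = {}
    # females, closed forms
    out["int_lam_x_f"] = df / (muf * (muf + alpha))
    out["int_lam_l_l_f"] = df * (v[FEMALE] / alpha) * (1.0 / muf**2 - 1.0 / (muf + alpha) ** 2)
    # males, quadrature on the male age grid (weights include mu_m e^{-mu_m t})
    t = env.age_nodes[MALE]
    w = env.age_weights[MALE] / mum  # plain l_m(t) dt weights
    xm = env.sizes[MALE]
    fm = env.male_siring_rate(xm)
    dfm = env.male_siring_rate_dx(xm)
    out["int_lam_x_m"] = float(w @ (dfm * (1.0 - np.exp(-alpha * t)) / alpha))
    out["int_lam_l_l_m"] = float(w @ (t * fm))
    return out


def fixed_point_map(params: SexualNicheParams, v) -> np.ndarray:
    """One step of the singular-strategy fixed-point map.

    ``v_j <- (1/(2 beta_j)) * int lam_x_j da / int lam_l_j l_j da`` for each
    sex, with the costates evaluated at the current ``v``.  Fixed points of
    this map are the zeros of the selection gradient.
    """
    ints = _costate_integrals(params, v)
    vf = ints["int_lam_x_f"] / (2.0 * params.beta_f * ints["int_lam_l_l_f"])
    vm = ints["int_lam_x_m"] / (2.0 * params.beta_m * ints["int_lam_l_l_m"])
    return np.array([vf, vm])


def shared_fixed_point_map(params: SexualNicheParams, vl: float) -> float:
    """Fixed-point map for the shared (pleiotropically constrained) trait."""
    c = params.c
    ints = _costate_integrals(params, [vl, vl])
    num = (1.0 - c) * ints["int_lam_x_f"] + c * ints["int_lam_x_m"]
    den = (1.0 - c) * params.beta_f * ints["int_lam_l_l_f"] + \
        c * params.beta_m * ints["int_lam_l_l_m"]
    return num / (2.0 * den)


def solve_fixed_point(
    params: SexualNicheParams,
    v0=(0.5, 0.5),
    shared: bool = False,
    tol: float = 1e-10,
) -> np.ndarray | float:
    """Solve the singular-strategy fixed-point condition ``map(v) = v``.

    The map can be strongly non-monotone in the male trait (its siring rate
    reacts steeply to the mismatch with the female size distribution), so
    the fixed point is located as a root of ``map(v) - v`` rather than by
    damped iteration.
    """
    from scipy.optimize import brentq, root

    if shared:
        def res(vl):
            return shared_fixed_point_map(params, float(vl)) - float(vl)

        lo, hi = 1e-3, 2.0
        flo = res(lo)
        while res(hi) * flo > 0 and hi < 64:
            hi *= 2
        return float(brentq(res, lo, hi, xtol=tol))

    sol = root(lambda v: fixed_point_map(params, v) - v,
               np.asarray(v0, dtype=float).reshape(2),
               method="hybr", options={"xtol": tol})
    if not sol.success:
        raise RuntimeError(f"fixed-point solve did not converge: {sol.message}")
    return sol.x


def male_xx_kernel(params: SexualNicheParams, v, ages) -> np.ndarray:
    """Size-mediated age kernel of quadratic selection on male growth.

    Closed-form route to the male ``xx`` component: the squared sensitivity
    of male size to the growth trait, ``((1 - e^{-alpha a})/alpha)**2``,
    times survivorship, times the curvature of the siring rate in male size,
    ``d2 f_m / d x_m**2 = 2 kappa * integral of (collective egg rate) * C *
    (2 kappa (x_m - x_f)^2 - 1) dx_f``, weighted by the class-specific
    reproductive value (1/2) and the male birth frequency ``q_m = c``.
    """
    v = np.asarray(v, dtype=float).reshape(2)
    env = _Environment(params, v)
    d = env.demography
    ages = np.asarray(ages, dtype=float)
    kappa, alpha, c = params.kappa, params.alpha, params.c
    if kappa == 0.0:
        return np.zeros_like(ages)
    xm = env.resident_size(MALE, ages)[:, None]
    xf = env.sizes[FEMALE][None, :]
    diff = xm - xf
    cmat = np.exp(-kappa * diff**2) / env.male_norms[None, :]
    bracket = (
        (env.female_egg_rates[None, :] * cmat * (2.0 * kappa * diff**2 - 1.0))
        @ env.age_weights[FEMALE]
    )
    lm = np.exp(-d.mortality[MALE] * ages)
    sens2 = ((1.0 - np.exp(-alpha * ages)) / alpha) ** 2
    return c * kappa * sens2 * lm * bracket


def closed_form_selection(params: SexualNicheParams, v) -> dict[str, Any]:
    """Model-specific shortcuts bundled for cross-checks.

    Returns the fixed-point map value per sex, the shared-trait map value,
    and a callable for the male size-mediated quadratic kernel.
    """
    v = np.asarray(v, dtype=float).reshape(2)
    return {
        "fixed_point": fixed_point_map(params, v),
        "shared_fixed_point": shared_fixed_point_map(params, float(np.mean(v))),
        "male_xx_kernel": lambda ages: male_xx_kernel(params, v, ages),
    }


register_model("sexual_niche", build_model)
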
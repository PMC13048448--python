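"""Resident (and mutant) trajectories, lifetime fecundities and birth structure.

Solves, for each class ``j``, the autonomous survivorship/state system

    dl_j/da = -mu_j(z_j, x_j(a), v) l_j(a),      l_j(0) = 1,
    dx_j/da =  g_j(z_j, x_j(a), v),              x_j(0) = x_{j,0},

truncating age at ``a_max`` chosen adaptively so that every class's
survivorship has fallen below a tolerance.  Lifetime class-oriented
fecundities ``R_ij = int l_j f_ij da`` are accumulated as extra quadrature
states of the same ODE solve, so their accuracy tracks the solver tolerance.
The allelic next-generation matrix is ``gamma_ij * R_ij``; its Perron root is
the basic reproductive number ``R0`` and its leading right/left eigenvectors
are the allelic class frequencies and reproductive values at birth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import LifeHistoryModel

__all__ = [
    "ResidentTrajectory",
    "BirthStructure",
    "solve_resident",
    "solve_trajectory",
    "next_generation_matrix",
    "birth_structure",
    "resident_birth_structure",
]

_RTOL = 1e-10
_ATOL = 1e-16


class TrajectorySolveError(RuntimeError):
    """ODE solve failed; carries the offending class index."""

    def __init__(self, message: str, class_index: int):
        super().__init__(message)
        self.class_index = class_index


class _UniformCubicHermite:
    """Fast C1 interpolant on a uniform grid with known derivatives.

    Cubic Hermite on each cell: O(h^4) accurate for smooth data, O(1)
    evaluation (no segment search), vectorised over query points.
    """

    def __init__(self, t0: float, h: float, y: np.ndarray, dy: np.ndarray):
        self.t0, self.h = float(t0), float(h)
        self.y = np.asarray(y, dtype=float)  # (n, k)
        self.dy = np.asarray(dy, dtype=float)

    def __call__(self, a):
        a = np.asarray(a, dtype=float)
        s = (a - self.t0) / self.h
        i = np.clip(np.floor(s).astype(np.intp), 0, self.y.shape[0] - 2)
        u = (s - i)[..., None]
        y0, y1 = self.y[i], self.y[i + 1]
        d0, d1 = self.dy[i] * self.h, self.dy[i + 1] * self.h
        u2, u3 = u * u, u * u * u
        out = ((2 * u3 - 3 * u2 + 1) * y0 + (u3 - 2 * u2 + u) * d0
               + (-2 * u3 + 3 * u2) * y1 + (u3 - u2) * d1)
        return out


@dataclass
class ResidentTrajectory:
    """Per-class survivorship and internal-state paths on ``[0, a_max]``.

    ``survivorship``/``states`` sample a uniform age grid; the dense ODE
    solutions back the callable accessors ``l(j, a)`` and ``x(j, a)``.
    """

    ages: np.ndarray  # (n_grid,)
    a_max: float
    survivorship: np.ndarray  # (nc, n_grid)
    states: np.ndarray  # (nc, n_grid, nx)
    v: np.ndarray  # resident allelic values this was solved at
    traits: np.ndarray  # expressed traits (nc, nz) along the trajectory
    env: Any
    tol: float
    _sols: list = field(default_factory=list, repr=False)

    @property
    def n_classes(self) -> int:
        return self.survivorship.shape[0]

    def l(self, j: int, a) -> np.ndarray:
        """Survivorship of class ``j`` at age(s) ``a``."""
        y = self._sols[j](np.clip(a, 0.0, self.a_max))
        return y[0]

    def x(self, j: int, a) -> np.ndarray:
        """Internal states of class ``j`` at age(s) ``a`` (state axis first)."""
        y = self._sols[j](np.clip(a, 0.0, self.a_max))
        return y[1:]

    def fast_states(self, model, j: int) -> "_UniformCubicHermite":
        """O(1) cubic-Hermite interpolant of class ``j``'s states.

        Built once per class from the grid values and their exact rates;
        used inside backward costate/perturbation solves where per-point
        dense-output interpolation would dominate the run time.
        """
        cache = getattr(self, "_fast_states", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_fast_states", cache)
        if j not in cache:
            z = self.traits[j]
            dy = np.array([
                np.asarray(model.growth(j, z, x, self.env), dtype=float)
                for x in self.states[j]
            ])
            cache[j] = _UniformCubicHermite(
                0.0, self.ages[1] - self.ages[0], self.states[j], dy)
        return cache[j]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: class, age, survivorship, state_1..state_nx."""
        frames = []
        for j in range(self.n_classes):
            df = pd.DataFrame({"class": j, "age": self.ages,
                               "survivorship": self.survivorship[j]})
            for m in range(self.states.shape[2]):
                df[f"state_{m + 1}"] = self.states[j, :, m]
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _class_rhs(model: LifeHistoryModel, j: int, z: np.ndarray, env,
               with_fecundity: bool):
    nc = model.n_classes

    def rhs(a, y):
        l = y[0]
        x = y[1 : 1 + model.n_states]
        mu = model.mortality(j, z, x, env)
        g = np.asarray(model.growth(j, z, x, env), dtype=float)
        out = np.empty_like(y)
        out[0] = -mu * l
        out[1 : 1 + model.n_states] = g
        if with_fecundity:
            for i in range(nc):
                out[1 + model.n_states + i] = l * model.fecundity(i, j, z, x, env)
        return out

    return rhs


def _find_a_max(model, z_mat, env, tol):
    """Smallest age at which every class's survivorship is below ``tol``."""
    a_max = 0.0
    for j in range(model.n_classes):
        rhs = _class_rhs(model, j, z_mat[j], env, with_fecundity=False)
        y0 = np.concatenate(([1.0], model.initial_states[j]))

        def below(a, y, _tol=tol):
            return y[0] - _tol

        below.terminal = True
        below.direction = -1
        horizon = 100.0
        for _ in range(20):
            sol = solve_ivp(rhs, (0.0, horizon), y0, events=below,
                            rtol=_RTOL, atol=_ATOL, method="RK45")
            if not sol.success:
                raise TrajectorySolveError(
                    f"resident solve failed for class {model.class_names[j]}: "
                    f"{sol.message}", j)
            if sol.t_events[0].size:
                a_max = max(a_max, float(sol.t_events[0][0]))
                break
            horizon *= 2.0
        else:
            raise TrajectorySolveError(
                f"survivorship of class {model.class_names[j]} did not fall "
                f"below {tol} within age {horizon}", j)
    return a_max


def solve_trajectory(
    model: LifeHistoryModel,
    z_mat: np.ndarray,
    v: np.ndarray,
    tol: float = 1e-9,
    n_grid: int = 801,
) -> ResidentTrajectory:
    """Solve survivorship/state dynamics for fixed expressed traits ``z_mat``.

    ``z_mat`` has shape ``(nc, nz)``; the environment is the resident one at
    ``v``.  Used both for residents (``z_mat = v``) and mutants.
    """
    v = np.asarray(v, dtype=float)
    z_mat = np.asarray(z_mat, dtype=float).reshape(model.n_classes, model.n_traits)
    env = model.env(v)
    a_max = _find_a_max(model, z_mat, env, tol)
    ages = np.linspace(0.0, a_max, n_grid)
    sols, surv, states = [], [], []
    for j in range(model.n_classes):
        rhs = _class_rhs(model, j, z_mat[j], env, with_fecundity=False)
        y0 = np.concatenate(([1.0], model.initial_states[j]))
        sol = solve_ivp(rhs, (0.0, a_max), y0, dense_output=True,
                        rtol=_RTOL, atol=_ATOL, method="RK45")
        if not sol.success:
            raise TrajectorySolveError(
                f"trajectory solve failed for class {model.class_names[j]}: "
                f"{sol.message}", j)
        sols.append(sol.sol)
        y = sol.sol(ages)
        surv.append(np.clip(y[0], 0.0, 1.0))
        states.append(y[1:].T)
    return ResidentTrajectory(
        ages=ages,
        a_max=a_max,
        survivorship=np.array(surv),
        states=np.array(states),
        v=v,
        traits=z_mat,
        env=env,
        tol=tol,
        _sols=sols,
    )


def solve_resident(
    model: LifeHistoryModel, v, tol: float = 1e-9, n_grid: int = 801
) -> ResidentTrajectory:
    """Resident trajectories at allelic values ``v`` (traits = ``v``)."""
    v = np.asarray(v, dtype=float)
    return solve_trajectory(model, model.resident_traits(v), v, tol=tol,
                            n_grid=n_grid)


def next_generation_matrix(
    model: LifeHistoryModel,
    u,
    v,
    traj: ResidentTrajectory | None = None,
    tol: float = 1e-9,
    return_individual: bool = False,
):
    """Allelic next-generation matrix ``R(u, v)`` (entries ``gamma_ij R_ij``).

    For ``u != v`` the mutant trajectories are re-solved internally with the
    mutant's expressed traits in the resident environment.  ``R_ij`` is
    accumulated as a quadrature state of the ODE solve over ``[0, a_max]``;
    the neglected tail is bounded by the survivorship truncation tolerance
    times the terminal fecundity.
    """
    from .genetics import express_traits

    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nc, nx = model.n_classes, model.n_states
    z_mat = express_traits(
        u.reshape(nc, model.n_traits), v.reshape(nc, model.n_traits),
        model.genetics)
    if traj is not None and np.array_equal(z_mat, traj.traits) and \
            np.array_equal(v, traj.v):
        a_max, env = traj.a_max, traj.env
    else:
        env = model.env(v)
        a_max = _find_a_max(model, z_mat, env, tol)
    R_ind = np.zeros((nc, nc))
    for j in range(nc):
        rhs = _class_rhs(model, j, z_mat[j], env, with_fecundity=True)
        y0 = np.concatenate(([1.0], model.initial_states[j], np.zeros(nc)))
        sol = solve_ivp(rhs, (0.0, a_max), y0, rtol=_RTOL, atol=_ATOL,
                        method="RK45")
        if not sol.success:
            raise TrajectorySolveError(
                f"fecundity integration failed for class "
                f"{model.class_names[j]}: {sol.message}", j)
        R_ind[:, j] = sol.y[1 + nx :, -1]
    R_allelic = model.genetics.transmission * R_ind
    if return_individual:
        return R_allelic, R_ind
    return R_allelic


@dataclass
class BirthStructure:
    """Eigen-structure of the resident next-generation matrix.

    ``R0`` is the Perron root; ``q`` the leading right eigenvector (allelic
    class frequencies at birth, summing to one); ``nu`` the leading left
    eigenvector (allelic reproductive values at birth).
    """

    R: np.ndarray  # allelic next-generation matrix
    R_individual: np.ndarray  # lifetime class-oriented fecundities R_ij
    R0: float
    q: np.ndarray
    nu: np.ndarray
    normalization: str
    warnings: tuple[str, ...] = ()


def birth_structure(
    R: np.ndarray,
    R_individual: np.ndarray | None = None,
    normalization: str = "vq",
) -> BirthStructure:
    """Perron root and eigenvectors of a nonnegative next-generation matrix.

    ``normalization``: ``"vq"`` scales the left eigenvector so that
    ``nu . q = 1`` (singular strategies and stability classifications are
    invariant to this scale); ``"max1"`` scales it so its largest entry is 1,
    which reproduces the conventional unit reproductive values of the diploid
    two-sex case (``nu = (1, 1)``).
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < -1e-12):
        raise ValueError("next-generation matrix must be nonnegative")
    warnings: list[str] = []
    eigvals, right = np.linalg.eig(R)
    order = np.argsort(-eigvals.real)
    lead = order[0]
    if len(order) > 1:
        gap = abs(abs(eigvals[lead]) - abs(eigvals[order[1]]))
        if gap <= 1e-10 * max(1.0, abs(eigvals[lead])):
            warnings.append(
                "leading eigenvalue nearly non-simple; eigenvectors may be "
                "ambiguous (non-primitive matrix?)")
    R0 = float(eigvals[lead].real)
    q = right[:, lead].real
    if q.sum() < 0:
        q = -q
    if np.any(q < -1e-8 * max(1.0, np.abs(q).max())):
        warnings.append("leading right eigenvector has mixed signs")
    q = np.clip(q, 0.0, None)
    q = q / q.sum()
    eigvals_t, left = np.linalg.eig(R.T)
    lead_t = int(np.argmin(np.abs(eigvals_t - eigvals[lead])))
    nu = left[:, lead_t].real
    if nu.sum() < 0:
        nu = -nu
    if normalization == "vq":
        nu = nu / float(nu @ q)
    elif normalization == "max1":
        nu = nu / nu.max()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return BirthStructure(
        R=R,
        R_individual=R_individual if R_individual is not None else
        np.full_like(R, np.nan),
        R0=R0,
        q=q,
        nu=nu,
        normalization=normalization,
        warnings=tuple(warnings),
    )


def resident_birth_structure(
    model: LifeHistoryModel, v, traj: ResidentTrajectory | None = None,
    normalization: str = "vq",
) -> BirthStructure:
    """Birth structure of the resident population at ``v``."""
    v = np.asarray(v, dtype=float)
    R, R_ind = next_generation_matrix(model, v, v, traj=traj,
                                      return_individual=True)
    return birth_structure(R, R_ind, normalization=normalization)
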
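"""Hamiltonians and costate trajectories.

The Hamiltonian of parent class ``j`` oriented to offspring class ``i``,

    H_ij(z_j, l_j(a), x_j(a), v) = l_j f_ij - lam_l_ij mu_j l_j
                                   + lam_x_ij . g_j,

prices the three routes by which age-``a`` physiology contributes to the
lifetime production of class-``i`` offspring: current fecundity, survival
(weighted by the survivorship costate ``lam_l``, the class-oriented analogue
of Fisher's age-specific reproductive value), and development (weighted by
the state costates ``lam_x``).

The survivorship costate is computed from its integral identity,

    lam_l_ij(a) = (1 / l_j(a)) * int_a^inf l_j f_ij dtau,

i.e. remaining class-oriented reproduction conditional on survival to ``a``,
which is numerically stabler than its forward ODE (the forward form divides
by survivorship and amplifies late-age error; it is kept as a residual
check).  The tail integral is accumulated by a backward quadrature ODE so no
catastrophic cancellation occurs.  The state costates solve their linear ODE
backwards from the terminal condition ``lam_x(a_max) = 0``.

Under constant class proportions at birth (``f_ij = c_ij f_j``), the
class-oriented system collapses to one class-specific Hamiltonian and
costate pair per parent class, with ``lam_l_j(0) = sum_i R_ij`` — the
expected total lifetime reproductive output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import LifeHistoryModel
from .resident import ResidentTrajectory

__all__ = [
    "CostateSet",
    "remaining_reproduction",
    "solve_costates",
    "evaluate_hamiltonian",
    "hamiltonian_partial",
    "costate_residuals",
]

_RTOL = 1e-10
_ATOL = 1e-13

#: relative finite-difference step for first derivatives of rate functions
_FD_STEP = 1e-6


def _step(val: float, rel: float = _FD_STEP) -> float:
    return rel * max(1.0, abs(val))


def _fec(model, i, j, z, x, env):
    """Class-oriented (i given) or class-specific (i is None) fecundity."""
    if i is None:
        return model.total_fecundity(j, z, x, env)
    return model.fecundity(i, j, z, x, env)


@dataclass
class CostateSet:
    """Survivorship and state costates on the resident age grid.

    In ``class_oriented`` mode ``lam_l`` has shape ``(nc, nc, n_grid)``
    (offspring class first) and ``lam_x`` shape ``(nc, nc, n_grid, nx)``; in
    ``class_specific`` mode the leading offspring axis is dropped.
    """

    mode: str
    ages: np.ndarray
    lam_l: np.ndarray
    lam_x: np.ndarray
    R_total: np.ndarray  # (nc, nc) lifetime individual fecundities R_ij
    traj: ResidentTrajectory
    _sols: dict = field(default_factory=dict, repr=False)

    def lam_l_at(self, key, a):
        """Interpolated survivorship costate; ``key`` is (i, j) or j.

        Evaluated as tail reproduction over survivorship from the same
        backward solution, so numerator and denominator stay consistent.
        """
        y = self._sols[key](np.clip(a, 0.0, self.traj.a_max))
        return y[1] / y[0]

    def lam_x_at(self, key, a):
        """Interpolated state costate vector (state axis first)."""
        y = self._sols[key](np.clip(a, 0.0, self.traj.a_max))
        return y[2:]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export (class_parent, class_offspring, age, lambda_l, lambda_x_*)."""
        rows = []
        nx = self.lam_x.shape[-1]
        if self.mode == "class_oriented":
            nc = self.lam_l.shape[0]
            for i in range(nc):
                for j in range(nc):
                    df = pd.DataFrame({
                        "class_parent": j, "class_offspring": i,
                        "age": self.ages, "lambda_l": self.lam_l[i, j]})
                    for m in range(nx):
                        df[f"lambda_x_{m + 1}"] = self.lam_x[i, j, :, m]
                    rows.append(df)
        else:
            nc = self.lam_l.shape[0]
            for j in range(nc):
                df = pd.DataFrame({
                    "class_parent": j, "class_offspring": -1,
                    "age": self.ages, "lambda_l": self.lam_l[j]})
                for m in range(nx):
                    df[f"lambda_x_{m + 1}"] = self.lam_x[j, :, m]
                rows.append(df)
        return pd.concat(rows, ignore_index=True)


def _backward_costate_sol(model, traj, i, j):
    """Joint backward solve of survivorship, tail reproduction and state
    costates for parent class ``j`` (offspring class ``i``, or the
    class-specific system when ``i`` is None).

    State vector ``[l, T, lam_x (nx)]`` integrated from ``a_max`` to 0:
    all three are stable in the backward direction, and the survivorship
    costate ``lam_l = T / l`` is self-consistent at every age.  States
    ``x(a)`` come from an O(1) cubic-Hermite interpolant of the forward
    solve (backward integration of ``x`` itself would be unstable whenever
    the forward state dynamics are contracting).
    """
    env = traj.env
    z = traj.traits[j]
    nx = model.n_states
    xfun = traj.fast_states(model, j)

    def rhs(a, y):
        l = y[0]
        lam_x = y[2:]
        lam_l = y[1] / l if l > 0 else 0.0
        x = xfun(a)
        mu = model.mortality(j, z, x, env)
        f = _fec(model, i, j, z, x, env)
        out = np.empty_like(y)
        out[0] = -mu * l
        out[1] = -l * f
        # dlam_x/da = -(l df/dx - lam_l l dmu/dx + (dg/dx)^T lam_x)
        for m in range(nx):
            h = _step(x[m])
            xp, xm_ = x.copy(), x.copy()
            xp[m] += h
            xm_[m] -= h
            df = (_fec(model, i, j, z, xp, env)
                  - _fec(model, i, j, z, xm_, env)) / (2 * h)
            dmu = (model.mortality(j, z, xp, env)
                   - model.mortality(j, z, xm_, env)) / (2 * h)
            dg = (np.asarray(model.growth(j, z, xp, env), dtype=float)
                  - np.asarray(model.growth(j, z, xm_, env), dtype=float)) / (2 * h)
            out[2 + m] = -(l * df - lam_l * l * dmu + float(dg @ lam_x))
        return out

    y_end = np.concatenate((
        [float(traj.l(j, traj.a_max))], [0.0], np.zeros(nx)))
    sol = solve_ivp(rhs, (traj.a_max, 0.0), y_end, dense_output=True,
                    rtol=1e-11, atol=1e-14, method="RK45")
    if not sol.success:
        raise RuntimeError(
            f"backward costate integration failed for classes ({i}, {j})")
    # The system is jointly linear in (l, T, lam_x): rescale so that the
    # recovered survivorship is exactly 1 at birth, cancelling the forward
    # solve's accumulated relative error in the deep-tail terminal value.
    scale = 1.0 / float(sol.sol(0.0)[0])
    return lambda a, _s=sol.sol, _c=scale: _c * _s(a)


def _tail_reproduction_sol(model, traj, i, j):
    """Dense T(a) = int_a^{a_max} l_j f_ij dtau via the backward system."""
    sol = _backward_costate_sol(model, traj, i, j)
    return lambda a, _s=sol: np.atleast_2d(_s(a)[1])


def remaining_reproduction(
    traj: ResidentTrajectory, model: LifeHistoryModel, v, i: int, j: int, a
) -> np.ndarray:
    """Expected remaining class-``i`` offspring of a class-``j`` resident.

    Tail quadrature of ``l_j f_ij`` from age ``a``; at ``a = 0`` this equals
    the lifetime fecundity ``R_ij``, and at ``a_max`` it is ~0.
    """
    sol = _tail_reproduction_sol(model, traj, i, j)
    return sol(np.clip(a, 0.0, traj.a_max))[0]


def solve_costates(
    model: LifeHistoryModel,
    v,
    traj: ResidentTrajectory | None = None,
    mode: str = "auto",
) -> CostateSet:
    """Solve the costate system along the resident trajectory.

    ``mode='class_specific'`` requires constant class proportions at birth
    (``f_ij = c_ij f_j``); ``'auto'`` picks it whenever the model declares
    them, else falls back to the full class-oriented system.
    """
    from .resident import solve_resident

    v = np.asarray(v, dtype=float)
    if traj is None:
        traj = solve_resident(model, v)
    if mode == "auto":
        mode = ("class_specific" if model.has_constant_class_proportions
                else "class_oriented")
    if mode == "class_specific" and not model.has_constant_class_proportions:
        raise ValueError(
            "class_specific costates require constant class proportions c_ij")

    nc, nx = model.n_classes, model.n_states
    ages = traj.ages
    n_grid = ages.size
    sols: dict = {}
    R_total = np.zeros((nc, nc))

    def unpack(sol):
        y = sol(ages)
        lam_l = y[1] / np.maximum(y[0], 1e-300)
        lam_x = y[2:].T
        return lam_l, lam_x

    if mode == "class_oriented":
        lam_l = np.zeros((nc, nc, n_grid))
        lam_x = np.zeros((nc, nc, n_grid, nx))
        for j in range(nc):
            for i in range(nc):
                sol = _backward_costate_sol(model, traj, i, j)
                sols[(i, j)] = sol
                R_total[i, j] = float(sol(0.0)[1])
                lam_l[i, j], lam_x[i, j] = unpack(sol)
    else:
        lam_l = np.zeros((nc, n_grid))
        lam_x = np.zeros((nc, n_grid, nx))
        for j in range(nc):
            sol = _backward_costate_sol(model, traj, None, j)
            sols[j] = sol
            lam_l[j], lam_x[j] = unpack(sol)
            total = float(sol(0.0)[1])
            for i in range(nc):
                R_total[i, j] = model.class_proportions[i, j] * total

    return CostateSet(
        mode=mode, ages=ages, lam_l=lam_l, lam_x=lam_x, R_total=R_total,
        traj=traj, _sols=sols)


# ---------------------------------------------------------------------------
# Hamiltonian evaluation and partial derivatives
# ---------------------------------------------------------------------------

def evaluate_hamiltonian(
    model: LifeHistoryModel,
    costates: CostateSet,
    key,
    a: float,
    z: np.ndarray | None = None,
    l: float | None = None,
    x: np.ndarray | None = None,
) -> float:
    """Hamiltonian value at age ``a``.

    ``key`` selects the costate pair: ``(i, j)`` in class-oriented mode or
    ``j`` in class-specific mode.  ``z``, ``l`` and ``x`` default to their
    resident values at that age and can be overridden independently (which
    is how the finite-difference partials are formed).
    """
    traj = costates.traj
    j = key[1] if isinstance(key, tuple) else key
    i = key[0] if isinstance(key, tuple) else None
    z = traj.traits[j] if z is None else np.asarray(z, dtype=float)
    l = float(traj.l(j, a)) if l is None else float(l)
    x = np.asarray(traj.x(j, a) if x is None else x, dtype=float)
    lam_l = float(costates.lam_l_at(key, a))
    lam_x = np.asarray(costates.lam_x_at(key, a), dtype=float)
    env = traj.env
    f = _fec(model, i, j, z, x, env)
    mu = model.mortality(j, z, x, env)
    g = np.asarray(model.growth(j, z, x, env), dtype=float)
    return l * f - lam_l * mu * l + float(lam_x @ g)


def hamiltonian_partial(
    model: LifeHistoryModel,
    costates: CostateSet,
    key,
    a: float,
    wrt: tuple,
    step: float = _FD_STEP,
) -> float:
    """First/second partials of the Hamiltonian by central differences.

    ``wrt`` is a tuple of one or two argument selectors among ``("z", k)``,
    ``("x", m)`` and ``("l",)``.  Mixed second derivatives use the standard
    four-point cross stencil.
    """
    traj = costates.traj
    j = key[1] if isinstance(key, tuple) else key
    z0 = np.array(traj.traits[j], dtype=float)
    x0 = np.asarray(traj.x(j, a), dtype=float)
    l0 = float(traj.l(j, a))

    def H(dz=(), dx=(), dl=0.0):
        z = z0.copy()
        for k, d in dz:
            z[k] += d
        x = x0.copy()
        for m, d in dx:
            x[m] += d
        return evaluate_hamiltonian(model, costates, key, a, z=z, x=x,
                                    l=l0 + dl)

    def pack(sel, d):
        if sel[0] == "z":
            return {"dz": [(sel[1], d)]}
        if sel[0] == "x":
            return {"dx": [(sel[1], d)]}
        return {"dl": d}

    def stepsize(sel):
        if sel[0] == "z":
            return step * max(1.0, abs(z0[sel[1]]))
        if sel[0] == "x":
            return step * max(1.0, abs(x0[sel[1]]))
        return step * max(1.0, abs(l0))

    if len(wrt) == 1:
        sel = wrt[0]
        h = stepsize(sel)
        return (H(**pack(sel, h)) - H(**pack(sel, -h))) / (2 * h)
    if len(wrt) == 2:
        s1, s2 = wrt
        h1, h2 = stepsize(s1), stepsize(s2)
        if s1 == s2:
            return (H(**pack(s1, h1)) - 2 * H() + H(**pack(s1, -h1))) / h1**2

        def merge(p1, p2):
            out = {"dz": [], "dx": [], "dl": 0.0}
            for p in (p1, p2):
                out["dz"] += p.get("dz", [])
                out["dx"] += p.get("dx", [])
                out["dl"] += p.get("dl", 0.0)
            return out

        return (
            H(**merge(pack(s1, h1), pack(s2, h2)))
            - H(**merge(pack(s1, h1), pack(s2, -h2)))
            - H(**merge(pack(s1, -h1), pack(s2, h2)))
            + H(**merge(pack(s1, -h1), pack(s2, -h2)))
        ) / (4 * h1 * h2)
    raise ValueError("wrt must contain one or two selectors")


def costate_residuals(
    model: LifeHistoryModel, costates: CostateSet, n_check: int = 50
) -> dict[str, float]:
    """Max-norm residuals of the forward/backward costate ODEs on the grid.

    Substitutes the computed costates into their defining ODEs
    (``d lam_l/da = mu lam_l - f`` and the state-costate equation) using
    centred differences of the interpolants; both should vanish to solver
    tolerance.
    """
    traj = costates.traj
    # check only where survivorship is well resolved (l >= ~1e-5): the
    # division by l amplifies interpolation noise in the deep tail, where
    # every downstream integral is survivorship-weighted anyway
    frac = min(0.9, -np.log(1e-5) / -np.log(traj.tol))
    ages = np.linspace(traj.a_max * 0.01, traj.a_max * frac, n_check)
    da = traj.a_max * 1e-4
    out = {}
    keys = list(costates._sols)
    res_l = 0.0
    res_x = 0.0
    for key in keys:
        j = key[1] if isinstance(key, tuple) else key
        i = key[0] if isinstance(key, tuple) else None
        env = traj.env
        z = traj.traits[j]
        for a in ages:
            lam_p = costates.lam_l_at(key, a + da)
            lam_m = costates.lam_l_at(key, a - da)
            dlam = (lam_p - lam_m) / (2 * da)
            x = traj.x(j, a)
            mu = model.mortality(j, z, x, env)
            f = _fec(model, i, j, z, x, env)
            lam = costates.lam_l_at(key, a)
            res_l = max(res_l, abs(dlam - (mu * lam - f)))
            # state costate residual
            lam_x_p = np.asarray(costates.lam_x_at(key, a + da))
            lam_x_m = np.asarray(costates.lam_x_at(key, a - da))
            dlam_x = (lam_x_p - lam_x_m) / (2 * da)
            grad = np.array([
                hamiltonian_partial(model, costates, key, a, (("x", m),))
                for m in range(model.n_states)
            ])
            res_x = max(res_x, float(np.max(np.abs(dlam_x + grad))))
    out["lam_l"] = res_l
    out["lam_x"] = res_x
    return out
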
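"""Directional selection: age kernels, gradients, singular strategies.

The age-specific coefficient of directional selection on trait ``(j, l)``,

    s_hat_jl(a, v) = sum_i nu_i gamma_ij dH_ij/dz_jl q_j,

weights the marginal effect of the trait on each class-oriented Hamiltonian
by the reproductive value of the offspring class, the allelic transmission
weight, and the birth-class frequency of the parent class.  Under constant
class proportions it collapses to ``nu_check_j dH_j/dz_jl q_j``.  The total
coefficient is the age integral times the genetic exposure ``dz/du``; zeros
of the total gradient are singular strategies, and the sign structure of its
Jacobian decides convergence stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.optimize import root

from .costates import CostateSet, solve_costates
from .model import LifeHistoryModel
from .resident import (ResidentTrajectory, resident_birth_structure,
                       solve_resident)

__all__ = [
    "SelectionGradient",
    "JacobianReport",
    "age_specific_gradient",
    "selection_gradient",
    "find_singular_strategy",
    "convergence_stability",
]


def class_specific_reproductive_values(bs, model: LifeHistoryModel) -> np.ndarray:
    """``nu_check_j = sum_i nu_i gamma_ij c_ij`` (average-offspring value)."""
    gamma = model.genetics.transmission
    cij = model.class_proportions
    return np.array([
        float(np.sum(bs.nu * gamma[:, j] * cij[:, j]))
        for j in range(model.n_classes)
    ])


@dataclass
class SelectionGradient:
    """Total and age-resolved directional selection coefficients.

    ``totals[j, l]`` is ``s_jl(v)`` (per-generation allelic fitness effect);
    ``kernels[j, l]`` the age kernel whose integral, times the exposure,
    gives the total.  ``constrained_totals`` holds the summed coefficient of
    each shared-trait constraint group.
    """

    v: np.ndarray
    ages: np.ndarray
    kernels: np.ndarray  # (nc, nz, n_grid), exposure NOT yet applied
    totals: np.ndarray  # (nc, nz), exposure applied
    exposure: np.ndarray  # (nc,)
    mode: str
    constrained_totals: dict | None = None

    def total(self, j: int, l: int = 0) -> float:
        return float(self.totals[j, l])

    def flat(self) -> np.ndarray:
        return self.totals.reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        nc, nz, _ = self.kernels.shape
        rows = []
        for j in range(nc):
            for l in range(nz):
                rows.append(pd.DataFrame({
                    "class": j, "trait": l, "age": self.ages,
                    "kernel": self.kernels[j, l]}))
        return pd.concat(rows, ignore_index=True)


@dataclass
class JacobianReport:
    """Jacobian of the selection gradient at a candidate singular point."""

    v_star: np.ndarray
    J: np.ndarray
    symmetric_eigenvalues: np.ndarray
    leading_eigenvalue: float
    label: str  # strongly_convergence_stable | not_negative_semidefinite | marginal
    step: float


def age_specific_gradient(
    model: LifeHistoryModel,
    v,
    costates: CostateSet,
    traj: ResidentTrajectory | None = None,
    birth=None,
) -> np.ndarray:
    """Age kernels ``s_hat_jl(a, v)`` for every (class, trait) pair.

    Returns an array ``(nc, nz, n_grid)`` on the trajectory's age grid; the
    genetic exposure is *not* applied here (it multiplies the age integral).
    """
    traj = traj or costates.traj
    v = np.asarray(v, dtype=float)
    if birth is None:
        birth = resident_birth_structure(model, v, traj=traj)
    nc, nz = model.n_classes, model.n_traits
    ages = traj.ages
    kernels = np.zeros((nc, nz, ages.size))
    gamma = model.genetics.transmission
    if costates.mode == "class_specific":
        nu_check = class_specific_reproductive_values(birth, model)
        for j in range(nc):
            for l in range(nz):
                dH = _dH_dz_on_grid(model, costates, j, None, l)
                kernels[j, l] = nu_check[j] * dH * birth.q[j]
    else:
        for j in range(nc):
            for l in range(nz):
                acc = np.zeros(ages.size)
                for i in range(nc):
                    acc += birth.nu[i] * gamma[i, j] * \
                        _dH_dz_on_grid(model, costates, j, i, l)
                kernels[j, l] = acc * birth.q[j]
    return kernels


def _dH_dz_on_grid(model, costates, j, i, l, step: float = 1e-6):
    """``dH_ij/dz_jl`` at resident values on the stored age grid.

    Central differences of the rate functions in the trait only;
    survivorship, states and costates stay at their resident grid values
    (``i=None`` selects the class-specific Hamiltonian).
    """
    from .costates import _fec

    traj = costates.traj
    env = traj.env
    z0 = np.array(traj.traits[j], dtype=float)
    h = step * max(1.0, abs(z0[l]))
    zp, zm = z0.copy(), z0.copy()
    zp[l] += h
    zm[l] -= h
    lvec = traj.survivorship[j]
    xmat = traj.states[j]
    if costates.mode == "class_specific":
        lam_l = costates.lam_l[j]
        lam_x = costates.lam_x[j]
    else:
        lam_l = costates.lam_l[i, j]
        lam_x = costates.lam_x[i, j]
    out = np.empty(lvec.size)
    for k in range(lvec.size):
        x = xmat[k]
        df = (_fec(model, i, j, zp, x, env) - _fec(model, i, j, zm, x, env)) / (2 * h)
        dmu = (model.mortality(j, zp, x, env)
               - model.mortality(j, zm, x, env)) / (2 * h)
        dg = (np.asarray(model.growth(j, zp, x, env), dtype=float)
              - np.asarray(model.growth(j, zm, x, env), dtype=float)) / (2 * h)
        out[k] = lvec[k] * df - lam_l[k] * lvec[k] * dmu + float(lam_x[k] @ dg)
    return out


def selection_gradient(
    model: LifeHistoryModel,
    v,
    mode: str = "auto",
    tol: float = 1e-9,
    n_grid: int = 801,
) -> SelectionGradient:
    """Full directional-selection computation at resident ``v``.

    Orchestrates resident solve -> costates -> age kernels -> age quadrature,
    applies the genetic exposures, and sums coefficients over any shared-trait
    constraint groups of the model's genetic system.
    """
    v = np.asarray(v, dtype=float)
    traj = solve_resident(model, v, tol=tol, n_grid=n_grid)
    costates = solve_costates(model, v, traj=traj, mode=mode)
    birth = resident_birth_structure(model, v, traj=traj)
    kernels = age_specific_gradient(model, v, costates, traj, birth)
    exposure = model.genetics.exposure
    totals = simpson(kernels, x=traj.ages, axis=-1) * exposure[:, None]
    constrained = None
    if model.genetics.constraint_groups:
        constrained = {
            group: float(sum(totals[j, l] for (j, l) in group))
            for group in model.genetics.constraint_groups
        }
    return SelectionGradient(
        v=v, ages=traj.ages, kernels=kernels, totals=totals,
        exposure=exposure, mode=costates.mode,
        constrained_totals=constrained)


def _free_indices(model: LifeHistoryModel, constraint) -> tuple[list, list]:
    """Split (class, trait) coordinates into constraint groups and free ones."""
    nc, nz = model.n_classes, model.n_traits
    groups = [tuple(g) for g in (constraint or ())]
    grouped = {idx for g in groups for idx in g}
    free = [(j, l) for j in range(nc) for l in range(nz)
            if (j, l) not in grouped]
    return groups, free


def _unpack(model, theta, groups, free):
    """Rebuild the full allelic vector from free + group coordinates."""
    v = np.zeros((model.n_classes, model.n_traits))
    for val, (j, l) in zip(theta[: len(free)], free):
        v[j, l] = val
    for val, g in zip(theta[len(free):], groups):
        for (j, l) in g:
            v[j, l] = val
    return v.reshape(-1)


@dataclass
class SingularStrategy:
    """Located singular strategy with solver diagnostics."""

    v_star: np.ndarray
    gradient_norm: float
    converged: bool
    boundary_pinned: tuple = ()
    n_evaluations: int = 0
    method: str = "root"


def find_singular_strategy(
    model: LifeHistoryModel,
    v0,
    constraint: Sequence | None = None,
    mode: str = "auto",
    tol: float = 1e-9,
    n_grid: int = 801,
    grad_tol: float = 1e-5,
    boundary_floor: float = 1e-3,
) -> SingularStrategy:
    """Locate a zero of the (possibly constrained) selection gradient.

    Runs quasi-Newton root-finding from ``v0`` on the stacked gradient (one
    component per free coordinate, one summed component per shared-trait
    group).  A coordinate that the solver drives to the lower trait bound
    while its gradient still points outward is pinned at the bound
    ("boundary-pinned") and the reduced system is re-solved.  ``constraint``
    defaults to the genetic system's shared-trait groups.
    """
    if constraint is None:
        constraint = model.genetics.constraint_groups
    groups, free = _free_indices(model, constraint)
    coords = free + groups
    n = len(coords)
    v0_mat = np.asarray(v0, dtype=float).reshape(
        model.n_classes, model.n_traits)
    theta = np.array(
        [v0_mat[j, l] for (j, l) in free]
        + [float(np.mean([v0_mat[j, l] for (j, l) in g])) for g in groups])
    lo = model.trait_bounds[0]
    pinned: set[int] = set()
    n_eval = 0

    def stacked_gradient(full_theta):
        nonlocal n_eval
        n_eval += 1
        grad = selection_gradient(
            model, _unpack(model, full_theta, groups, free),
            mode=mode, tol=tol, n_grid=n_grid)
        vals = [grad.total(j, l) for (j, l) in free]
        vals += [float(sum(grad.total(j, l) for (j, l) in g)) for g in groups]
        return np.array(vals)

    for _ in range(n + 1):
        active = [k for k in range(n) if k not in pinned]
        if not active:
            break

        def residual(th_active):
            full = theta.copy()
            full[active] = np.maximum(th_active, lo + boundary_floor * 1e-3)
            full[list(pinned)] = lo
            return stacked_gradient(full)[active]

        sol = root(residual, np.maximum(theta[active], lo + boundary_floor),
                   method="hybr", options={"xtol": 1e-12})
        theta[active] = np.maximum(sol.x, lo)
        theta[list(pinned)] = lo
        # pin coordinates pushed onto the bound with outward-pointing gradient
        probe = theta.copy()
        probe[active] = np.maximum(theta[active], lo + boundary_floor)
        at_bound = [k for k, th in zip(active, theta[active])
                    if th <= lo + boundary_floor]
        if not at_bound:
            break
        g_probe = stacked_gradient(probe)
        newly = [k for k in at_bound if g_probe[k] < 0]
        if not newly:
            break
        pinned.update(newly)

    theta[list(pinned)] = lo
    active = [k for k in range(n) if k not in pinned]
    gnorm = (float(np.max(np.abs(stacked_gradient(theta)[active])))
             if active else 0.0)
    return SingularStrategy(
        v_star=_unpack(model, theta, groups, free),
        gradient_norm=gnorm,
        converged=gnorm < grad_tol,
        boundary_pinned=tuple(coords[k] for k in sorted(pinned)),
        n_evaluations=n_eval,
        method="hybr",
    )


def gradient_on_grid(
    model: LifeHistoryModel,
    coord: tuple,
    grid: np.ndarray,
    v_base,
    constraint: Sequence | None = None,
    **kw,
):
    """Scan one coordinate of the gradient over a grid of resident values.

    Returns the gradient component of ``coord`` (a ``(j, l)`` pair or a
    constraint group) at each grid value, holding the other coordinates at
    ``v_base``.  Useful for bracketing/visualising zeros and for boundary
    diagnostics.
    """
    v_base = np.asarray(v_base, dtype=float).reshape(-1)
    out = np.empty(len(grid))
    is_group = isinstance(coord[0], tuple)
    for k, val in enumerate(grid):
        v = v_base.copy().reshape(model.n_classes, model.n_traits)
        targets = coord if is_group else (coord,)
        for (j, l) in targets:
            v[j, l] = val
        grad = selection_gradient(model, v.reshape(-1), **kw)
        if is_group:
            out[k] = sum(grad.total(j, l) for (j, l) in coord)
        else:
            out[k] = grad.total(*coord)
    return out


def convergence_stability(
    model: LifeHistoryModel,
    v_star,
    mode: str = "auto",
    step: float = 1e-3,
    marginal_tol: float = 1e-6,
    **kw,
) -> JacobianReport:
    """Jacobian of the gradient at ``v_star`` and its stability label.

    Central finite differences with relative step ``step``; every evaluation
    re-solves the full resident + costate system, since the resident values
    enter through the environment as well as the focal rates.  The label
    follows the sign of the leading eigenvalue of the symmetric part.
    """
    v_star = np.asarray(v_star, dtype=float).reshape(-1)
    n = v_star.size
    J = np.zeros((n, n))
    for col in range(n):
        h = step * max(1.0, abs(v_star[col]))
        vp, vm = v_star.copy(), v_star.copy()
        vp[col] += h
        vm[col] -= h
        gp = selection_gradient(model, vp, mode=mode, **kw).flat()
        gm = selection_gradient(model, vm, mode=mode, **kw).flat()
        J[:, col] = (gp - gm) / (2 * h)
    sym = 0.5 * (J + J.T)
    eigs = np.sort(np.linalg.eigvalsh(sym))[::-1]
    lead = float(eigs[0])
    scale = np.linalg.norm(J)
    if abs(lead) < marginal_tol * max(scale, 1e-30):
        label = "marginal"
    elif lead < 0:
        label = "strongly_convergence_stable"
    else:
        label = "not_negative_semidefinite"
    return JacobianReport(
        v_star=v_star, J=J, symmetric_eigenvalues=eigs,
        leading_eigenvalue=lead, label=label, step=step)


def classify_jacobian(J: np.ndarray, marginal_tol: float = 1e-6) -> JacobianReport:
    """Stability label for an externally supplied Jacobian matrix."""
    J = np.asarray(J, dtype=float)
    sym = 0.5 * (J + J.T)
    eigs = np.sort(np.linalg.eigvalsh(sym))[::-1]
    lead = float(eigs[0])
    scale = np.linalg.norm(J)
    if abs(lead) < marginal_tol * max(scale, 1e-30):
        label = "marginal"
    elif lead < 0:
        label = "strongly_convergence_stable"
    else:
        label = "not_negative_semidefinite"
    return JacobianReport(v_star=np.array([]), J=J, symmetric_eigenvalues=eigs,
                          leading_eigenvalue=lead, label=label, step=0.0)
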
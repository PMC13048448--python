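"""Quadratic selection at a singular strategy: perturbations and the Hessian.

At a singular trait value ``v*`` the fate of nearby mutants is governed by
the Hessian of the basic reproductive number in the mutant allelic values.
Each element decomposes into six age-resolved components routed through:
direct trait curvature of the Hamiltonian (``zz``), trait-induced state
changes (``xx``), trait-state interactions (``zx``), trait-survivorship
interactions (``zl``), joint survivorship-state effects (``lx``), and
trait effects on birth-class frequencies (``zq`` — the only component
coupling different parent classes).

The indirect components need the sensitivities of states, survivorship and
birth-class frequencies to the traits.  State sensitivities solve the
variational ODE

    d/da (dx/dz) = (dg/dx) (dx/dz) + dg/dz,     dx/dz(0) = 0,

whose propagator is the fundamental matrix ``Psi_j(a, tau)`` (exposed
separately, with the closed exponential form used when ``dg/dx`` is
age-constant).  Survivorship sensitivities integrate the direct plus
state-mediated mortality effects; birth-frequency sensitivities come from a
linear solve around the resident next-generation matrix, valid at ``v*``.

The assembled Hessian is cross-checked (in the test suite) against direct
second differences of ``R0(u, v*)`` in the mutant allelic values — a fully
independent route through mutant trajectory solves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import simpson, solve_ivp
from scipy.linalg import expm

from .costates import _fec, solve_costates
from .directional import (class_specific_reproductive_values,
                          selection_gradient)
from .model import LifeHistoryModel
from .resident import (ResidentTrajectory, next_generation_matrix,
                       resident_birth_structure, solve_resident)

__all__ = [
    "PerturbationSet",
    "HessianReport",
    "compute_perturbations",
    "fundamental_matrix",
    "hessian",
    "hessian_via_r0",
    "classify_second_order",
]

_RTOL = 1e-10
_ATOL = 1e-13

#: relative step for second derivatives of Hamiltonians (curvature scale)
_FD2_STEP = 1e-4


@dataclass
class PerturbationSet:
    """Sensitivities of states, survivorship and birth frequencies to traits.

    ``dx_dz[j, l]`` is an ``(n_grid, nx)`` array, ``dl_dz[j, l]`` a grid
    vector, ``dq_dz[j, l]`` the length-``nc`` birth-frequency response to
    trait ``(j, l)`` (rows sum to zero: the frequencies stay on the simplex).
    """

    ages: np.ndarray
    dx_dz: np.ndarray  # (nc, nz, n_grid, nx)
    dl_dz: np.ndarray  # (nc, nz, n_grid)
    dq_dz: np.ndarray  # (nc, nz, nc)
    v_star: np.ndarray
    traj: ResidentTrajectory


def fundamental_matrix(
    model: LifeHistoryModel,
    traj: ResidentTrajectory,
    j: int,
    a: float,
    tau: float,
    step: float = 1e-6,
) -> np.ndarray:
    """Propagator ``Psi_j(a, tau)`` of the linearised state dynamics.

    Solves ``dPsi/da = (dg_j/dx) Psi`` from ``Psi(tau, tau) = I``.  When
    ``dg/dx`` is age-constant along the trajectory the closed exponential
    form ``expm((a - tau) dg/dx)`` is returned directly.
    """
    nx = model.n_states
    env = traj.env
    z = traj.traits[j]

    xfun = traj.fast_states(model, j)

    def dg_dx(age):
        x = xfun(age)
        A = np.empty((nx, nx))
        for m in range(nx):
            h = step * max(1.0, abs(x[m]))
            xp, xm_ = x.copy(), x.copy()
            xp[m] += h
            xm_[m] -= h
            A[:, m] = (np.asarray(model.growth(j, z, xp, env), float)
                       - np.asarray(model.growth(j, z, xm_, env), float)) / (2 * h)
        return A

    A0 = dg_dx(tau)
    probes = [0.5 * (tau + a), a] if a != tau else []
    if all(np.allclose(dg_dx(t), A0, atol=1e-8) for t in probes):
        return expm((a - tau) * A0)

    def rhs(age, psi_flat):
        return (dg_dx(age) @ psi_flat.reshape(nx, nx)).reshape(-1)

    sol = solve_ivp(rhs, (tau, a), np.eye(nx).reshape(-1),
                    rtol=_RTOL, atol=_ATOL, method="RK45")
    if not sol.success:
        raise RuntimeError(f"fundamental-matrix solve failed for class {j}")
    return sol.y[:, -1].reshape(nx, nx)


def _dR_dz(model, v_star, j, l, step):
    """Central difference of the allelic next-generation matrix in z_{j,l}.

    Perturbing the *phenotype* of class ``j`` only changes column ``j``
    (mutant carriers of class ``j``); other columns stay resident.
    """
    from .resident import _class_rhs, _find_a_max

    v_star = np.asarray(v_star, dtype=float)
    z0 = model.resident_traits(v_star)
    env = model.env(v_star)
    h = step * max(1.0, abs(z0[j, l]))
    nc, nx = model.n_classes, model.n_states
    cols = []
    for sign in (+1, -1):
        z = z0.copy()
        z[j, l] += sign * h
        a_max = _find_a_max(model, z, env, 1e-9)
        rhs = _class_rhs(model, j, z[j], env, with_fecundity=True)
        y0 = np.concatenate(([1.0], model.initial_states[j], np.zeros(nc)))
        sol = solve_ivp(rhs, (0.0, a_max), y0, rtol=_RTOL, atol=_ATOL,
                        method="RK45")
        cols.append(sol.y[1 + nx :, -1])
    dR = np.zeros((nc, nc))
    dR[:, j] = model.genetics.transmission[:, j] * (cols[0] - cols[1]) / (2 * h)
    return dR


def compute_perturbations(
    model: LifeHistoryModel,
    v_star,
    traj: ResidentTrajectory | None = None,
    step: float = _FD2_STEP,
) -> PerturbationSet:
    """State, survivorship and birth-frequency sensitivities at ``v*``.

    The birth-frequency solve is the at-singularity form; away from a
    singular point the frequency response involves additional terms and is
    out of scope here.
    """
    v_star = np.asarray(v_star, dtype=float)
    if traj is None:
        traj = solve_resident(model, v_star)
    env = traj.env
    nc, nz, nx = model.n_classes, model.n_traits, model.n_states
    ages = traj.ages
    n_grid = ages.size
    dx_dz = np.zeros((nc, nz, n_grid, nx))
    dl_dz = np.zeros((nc, nz, n_grid))
    fd = 1e-6

    for j in range(nc):
        z0 = np.array(traj.traits[j], dtype=float)
        for l in range(nz):
            hz = fd * max(1.0, abs(z0[l]))
            zp, zm = z0.copy(), z0.copy()
            zp[l] += hz
            zm[l] -= hz

            xfun = traj.fast_states(model, j)

            def rhs(a, y):
                # y = [dx/dz (nx), integral for survivorship sensitivity]
                x = xfun(a)
                y_x = y[:nx]
                A = np.empty((nx, nx))
                for m in range(nx):
                    hx = fd * max(1.0, abs(x[m]))
                    xp, xm_ = x.copy(), x.copy()
                    xp[m] += hx
                    xm_[m] -= hx
                    A[:, m] = (np.asarray(model.growth(j, z0, xp, env), float)
                               - np.asarray(model.growth(j, z0, xm_, env),
                                            float)) / (2 * hx)
                dg_dz = (np.asarray(model.growth(j, zp, x, env), float)
                         - np.asarray(model.growth(j, zm, x, env), float)) / (2 * hz)
                dmu_dz = (model.mortality(j, zp, x, env)
                          - model.mortality(j, zm, x, env)) / (2 * hz)
                dmu_dx = np.empty(nx)
                for m in range(nx):
                    hx = fd * max(1.0, abs(x[m]))
                    xp, xm_ = x.copy(), x.copy()
                    xp[m] += hx
                    xm_[m] -= hx
                    dmu_dx[m] = (model.mortality(j, z0, xp, env)
                                 - model.mortality(j, z0, xm_, env)) / (2 * hx)
                out = np.empty(nx + 1)
                out[:nx] = A @ y_x + dg_dz
                out[nx] = float(dmu_dx @ y_x) + dmu_dz
                return out

            sol = solve_ivp(rhs, (0.0, traj.a_max), np.zeros(nx + 1),
                            dense_output=True, rtol=_RTOL, atol=_ATOL,
                            method="RK45")
            if not sol.success:
                raise RuntimeError(
                    f"perturbation solve failed for class {j}, trait {l}")
            y = sol.sol(ages)
            dx_dz[j, l] = y[:nx].T
            dl_dz[j, l] = -traj.survivorship[j] * y[nx]

    # birth-frequency sensitivities (at-singularity linear solve)
    birth = resident_birth_structure(model, v_star, traj=traj)
    R0mat = birth.R
    I = np.eye(nc)
    ones = np.ones((nc, nc))
    lhs = (R0mat.T - I) @ (R0mat - I) + ones
    dq_dz = np.zeros((nc, nz, nc))
    for j in range(nc):
        for l in range(nz):
            dR = _dR_dz(model, v_star, j, l, step)
            rhs_vec = (R0mat.T - I) @ (dR @ birth.q)
            try:
                dq = -np.linalg.solve(lhs, rhs_vec)
            except np.linalg.LinAlgError as exc:
                raise RuntimeError(
                    "singular linear system for birth-frequency "
                    f"sensitivities (trait ({j},{l}))") from exc
            dq_dz[j, l] = dq
    return PerturbationSet(ages=ages, dx_dz=dx_dz, dl_dz=dl_dz, dq_dz=dq_dz,
                           v_star=v_star, traj=traj)


# ---------------------------------------------------------------------------
# Hamiltonian second derivatives on the age grid
# ---------------------------------------------------------------------------

def _H_parts_on_grid(model, costates, j, i):
    """Closure evaluating H_ij(z, l, x) at grid index ``k`` with offsets."""
    traj = costates.traj
    env = traj.env
    z0 = np.array(traj.traits[j], dtype=float)
    lvec = traj.survivorship[j]
    xmat = traj.states[j]
    if costates.mode == "class_specific":
        lam_l = costates.lam_l[j]
        lam_x = costates.lam_x[j]
    else:
        lam_l = costates.lam_l[i, j]
        lam_x = costates.lam_x[i, j]

    def H(k, dz=None, dx=None, dl=0.0):
        z = z0 if dz is None else z0 + dz
        x = xmat[k] if dx is None else xmat[k] + dx
        l = lvec[k] + dl
        f = _fec(model, i, j, z, x, env)
        mu = model.mortality(j, z, x, env)
        g = np.asarray(model.growth(j, z, x, env), dtype=float)
        return l * f - lam_l[k] * mu * l + float(lam_x[k] @ g)

    return H, z0, lvec, xmat


def _second_derivative_grids(model, costates, j, i, step=_FD2_STEP):
    """All Hamiltonian second partials needed by the six components.

    Returns dict with grids: ``zz[k,l]``, ``xx[m,m']``, ``zx[k,m]``,
    ``zl[k]`` and ``lx[m]`` (each an array over grid ages), plus the first
    derivative ``dz[k]`` used by the zq component.
    """
    nz, nx = model.n_traits, model.n_states
    H, z0, lvec, xmat = _H_parts_on_grid(model, costates, j, i)
    n_grid = lvec.size
    hz = [step * max(1.0, abs(z0[k])) for k in range(nz)]

    def ev(idx):  # unit vector in trait space
        e = np.zeros(nz)
        e[idx] = 1.0
        return e

    out = {
        "zz": np.zeros((nz, nz, n_grid)),
        "xx": np.zeros((nx, nx, n_grid)),
        "zx": np.zeros((nz, nx, n_grid)),
        "zl": np.zeros((nz, n_grid)),
        "lx": np.zeros((nx, n_grid)),
        "dz": np.zeros((nz, n_grid)),
    }
    for k in range(n_grid):
        x = xmat[k]
        hx = [step * max(1.0, abs(x[m])) for m in range(nx)]
        hl = step * max(1.0, lvec[k])
        H0 = H(k)
        for kz in range(nz):
            out["dz"][kz, k] = (H(k, dz=hz[kz] * ev(kz))
                                - H(k, dz=-hz[kz] * ev(kz))) / (2 * hz[kz])
            out["zz"][kz, kz, k] = (H(k, dz=hz[kz] * ev(kz)) - 2 * H0
                                    + H(k, dz=-hz[kz] * ev(kz))) / hz[kz] ** 2
            for lz in range(kz + 1, nz):
                d = (H(k, dz=hz[kz] * ev(kz) + hz[lz] * ev(lz))
                     - H(k, dz=hz[kz] * ev(kz) - hz[lz] * ev(lz))
                     - H(k, dz=-hz[kz] * ev(kz) + hz[lz] * ev(lz))
                     + H(k, dz=-hz[kz] * ev(kz) - hz[lz] * ev(lz))) / \
                    (4 * hz[kz] * hz[lz])
                out["zz"][kz, lz, k] = out["zz"][lz, kz, k] = d
        for m in range(nx):
            em = np.zeros(nx)
            em[m] = 1.0
            out["xx"][m, m, k] = (H(k, dx=hx[m] * em) - 2 * H0
                                  + H(k, dx=-hx[m] * em)) / hx[m] ** 2
            for m2 in range(m + 1, nx):
                e2 = np.zeros(nx)
                e2[m2] = 1.0
                d = (H(k, dx=hx[m] * em + hx[m2] * e2)
                     - H(k, dx=hx[m] * em - hx[m2] * e2)
                     - H(k, dx=-hx[m] * em + hx[m2] * e2)
                     + H(k, dx=-hx[m] * em - hx[m2] * e2)) / \
                    (4 * hx[m] * hx[m2])
                out["xx"][m, m2, k] = out["xx"][m2, m, k] = d
            for kz in range(nz):
                d = (H(k, dz=hz[kz] * ev(kz), dx=hx[m] * em)
                     - H(k, dz=hz[kz] * ev(kz), dx=-hx[m] * em)
                     - H(k, dz=-hz[kz] * ev(kz), dx=hx[m] * em)
                     + H(k, dz=-hz[kz] * ev(kz), dx=-hx[m] * em)) / \
                    (4 * hz[kz] * hx[m])
                out["zx"][kz, m, k] = d
            # H is linear in l, so d2H/dl dx needs a single l offset
            out["lx"][m, k] = ((H(k, dx=hx[m] * em, dl=hl)
                                - H(k, dx=-hx[m] * em, dl=hl))
                               - (H(k, dx=hx[m] * em)
                                  - H(k, dx=-hx[m] * em))) / (2 * hx[m] * hl)
        for kz in range(nz):
            out["zl"][kz, k] = ((H(k, dz=hz[kz] * ev(kz), dl=hl)
                                 - H(k, dz=-hz[kz] * ev(kz), dl=hl))
                                - (H(k, dz=hz[kz] * ev(kz))
                                   - H(k, dz=-hz[kz] * ev(kz)))) / (2 * hz[kz] * hl)
    return out


@dataclass
class HessianReport:
    """Assembled Hessian with its age-resolved component kernels.

    ``H`` is the full symmetric matrix over flattened ``(class, trait)``
    coordinates.  ``component_kernels[(i, k, j, l)]`` maps component names
    (``zz``, ``xx``, ``zx``, ``zl``, ``lx``, ``zq``) to age kernels, prior to
    the exposure weighting.  ``constrained`` holds the chain-rule collapsed
    curvature of each shared-trait group.
    """

    v_star: np.ndarray
    ages: np.ndarray
    H: np.ndarray
    blocks: dict
    component_kernels: dict
    eigenvalues: np.ndarray
    leading_eigenvector: np.ndarray
    trait_labels: dict
    net_label: str
    constrained: dict | None
    gradient_norm: float

    def kernel_total(self, i, k, j, l) -> np.ndarray:
        return sum(self.component_kernels[(i, k, j, l)].values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (i, k, j, l), comps in self.component_kernels.items():
            df = pd.DataFrame({"pair": f"({i},{k})x({j},{l})", "age": self.ages})
            for name in ("zz", "xx", "zx", "zl", "lx", "zq"):
                df[name] = comps.get(name, np.zeros_like(self.ages))
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def hessian(
    model: LifeHistoryModel,
    v_star,
    mode: str = "auto",
    tol: float = 1e-9,
    n_grid: int = 801,
    step: float = _FD2_STEP,
    gradient_gate: float = 1e-4,
    disruptive_tol: float = 1e-10,
) -> HessianReport:
    """Six-component Hessian of quadratic selection at the singular ``v*``.

    Rejects inputs whose directional gradient exceeds ``gradient_gate``
    (the component formulas assume a vanishing gradient).  Off-diagonal
    class blocks only carry the birth-frequency (``zq``) component.
    """
    v_star = np.asarray(v_star, dtype=float)
    grad = selection_gradient(model, v_star, mode=mode, tol=tol, n_grid=n_grid)
    free = [(j, l) for j in range(model.n_classes)
            for l in range(model.n_traits)]
    groups = model.genetics.constraint_groups
    grouped = {idx for g in groups for idx in g}
    gnorm = max(
        [abs(grad.total(j, l)) for (j, l) in free if (j, l) not in grouped]
        + [abs(sum(grad.total(j, l) for (j, l) in g)) for g in groups]
        + [0.0])
    if gnorm > gradient_gate:
        raise ValueError(
            f"hessian requires a singular strategy: |gradient| = {gnorm:.3g} "
            f"exceeds {gradient_gate:.3g} at v = {v_star}")

    traj = solve_resident(model, v_star, tol=tol, n_grid=n_grid)
    costates = solve_costates(model, v_star, traj=traj, mode=mode)
    birth = resident_birth_structure(model, v_star, traj=traj)
    perts = compute_perturbations(model, v_star, traj=traj, step=step)
    nc, nz = model.n_classes, model.n_traits
    ages = traj.ages
    gamma = model.genetics.transmission
    exposure = model.genetics.exposure

    # weighted second-derivative grids per parent class
    if costates.mode == "class_specific":
        nu_check = class_specific_reproductive_values(birth, model)
        weighted = []
        for j in range(nc):
            grids = _second_derivative_grids(model, costates, j, None, step)
            weighted.append({key: nu_check[j] * val for key, val in grids.items()})
    else:
        weighted = []
        for j in range(nc):
            acc = None
            for i in range(nc):
                grids = _second_derivative_grids(model, costates, j, i, step)
                w = birth.nu[i] * gamma[i, j]
                if acc is None:
                    acc = {key: w * val for key, val in grids.items()}
                else:
                    for key, val in grids.items():
                        acc[key] += w * val
            weighted.append(acc)

    dim = nc * nz
    H = np.zeros((dim, dim))
    kernels: dict = {}

    def flat(j, l):
        return j * nz + l

    for j in range(nc):
        Wj = weighted[j]
        qj = birth.q[j]
        for k in range(nz):
            for l in range(nz):
                comp = {}
                comp["zz"] = Wj["zz"][k, l] * qj
                xx = np.zeros_like(ages)
                zx = np.zeros_like(ages)
                lx = np.zeros_like(ages)
                for m in range(model.n_states):
                    for m2 in range(model.n_states):
                        xx += (Wj["xx"][m, m2]
                               * perts.dx_dz[j, k, :, m]
                               * perts.dx_dz[j, l, :, m2])
                    zx += (Wj["zx"][k, m] * perts.dx_dz[j, l, :, m]
                           + Wj["zx"][l, m] * perts.dx_dz[j, k, :, m])
                    lx += ((perts.dl_dz[j, k] * perts.dx_dz[j, l, :, m]
                            + perts.dl_dz[j, l] * perts.dx_dz[j, k, :, m])
                           * Wj["lx"][m])
                comp["xx"] = xx * qj
                comp["zx"] = zx * qj
                comp["lx"] = lx * qj
                comp["zl"] = (Wj["zl"][k] * perts.dl_dz[j, l]
                              + Wj["zl"][l] * perts.dl_dz[j, k]) * qj
                comp["zq"] = (weighted[j]["dz"][k] * perts.dq_dz[j, l, j]
                              + weighted[j]["dz"][l] * perts.dq_dz[j, k, j])
                kernels[(j, k, j, l)] = comp
                val = simpson(sum(comp.values()), x=ages)
                H[flat(j, k), flat(j, l)] = val * exposure[j] * exposure[j]
        for i in range(nc):
            if i == j:
                continue
            for k in range(nz):
                for l in range(nz):
                    zq = (weighted[i]["dz"][k] * perts.dq_dz[j, l, i]
                          + weighted[j]["dz"][l] * perts.dq_dz[i, k, j])
                    kernels[(i, k, j, l)] = {"zq": zq}
                    H[flat(i, k), flat(j, l)] = simpson(zq, x=ages) * \
                        exposure[i] * exposure[j]

    H = 0.5 * (H + H.T)  # symmetrise away quadrature-level asymmetry
    eigvals, eigvecs = np.linalg.eigh(H)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    blocks = {(i, j): H[i * nz:(i + 1) * nz, j * nz:(j + 1) * nz]
              for i in range(nc) for j in range(nc)}
    trait_labels = {}
    for j in range(nc):
        for l in range(nz):
            d = H[flat(j, l), flat(j, l)]
            trait_labels[(j, l)] = ("disruptive" if d > disruptive_tol
                                    else "stabilising")
    net = "net_disruptive" if eigvals[0] > disruptive_tol else "net_stabilising"

    constrained = None
    if groups:
        constrained = {}
        for g in groups:
            val = float(sum(H[flat(j1, l1), flat(j2, l2)]
                            for (j1, l1) in g for (j2, l2) in g))
            constrained[tuple(g)] = val
    return HessianReport(
        v_star=v_star, ages=ages, H=H, blocks=blocks,
        component_kernels=kernels, eigenvalues=eigvals,
        leading_eigenvector=eigvecs[:, 0], trait_labels=trait_labels,
        net_label=net, constrained=constrained, gradient_norm=gnorm)


def hessian_via_r0(
    model: LifeHistoryModel,
    v_star,
    step: float = 1e-2,
    tol: float = 1e-10,
    richardson: bool = True,
) -> np.ndarray:
    """Hessian by direct second differences of ``R0(u, v*)`` in ``u``.

    A fully independent route: each evaluation expresses the mutant traits,
    re-solves the mutant trajectories in the resident environment, builds
    the mutant next-generation matrix and takes its Perron root.  Used as
    the primary correctness gate for the component assembly.  With
    ``richardson=True`` the O(h^2) truncation error is cancelled by a second
    pass at half the step.
    """
    if richardson:
        coarse = hessian_via_r0(model, v_star, step=step, tol=tol,
                                richardson=False)
        fine = hessian_via_r0(model, v_star, step=step / 2, tol=tol,
                              richardson=False)
        return (4.0 * fine - coarse) / 3.0
    from .resident import birth_structure

    v_star = np.asarray(v_star, dtype=float).reshape(-1)
    n = v_star.size

    def r0(u):
        R = next_generation_matrix(model, u, v_star, tol=tol)
        return birth_structure(R).R0

    H = np.zeros((n, n))
    base = r0(v_star)
    hs = [step * max(1.0, abs(v_star[k])) for k in range(n)]
    for k in range(n):
        up, um = v_star.copy(), v_star.copy()
        up[k] += hs[k]
        um[k] -= hs[k]
        H[k, k] = (r0(up) - 2 * base + r0(um)) / hs[k] ** 2
    for k in range(n):
        for l in range(k + 1, n):
            upp, upm, ump, umm = (v_star.copy() for _ in range(4))
            upp[[k, l]] += [hs[k], hs[l]]
            upm[k] += hs[k]
            upm[l] -= hs[l]
            ump[k] -= hs[k]
            ump[l] += hs[l]
            umm[[k, l]] -= [hs[k], hs[l]]
            H[k, l] = H[l, k] = (r0(upp) - r0(upm) - r0(ump) + r0(umm)) / \
                (4 * hs[k] * hs[l])
    return H


def classify_second_order(report: HessianReport,
                          disruptive_tol: float = 1e-10) -> dict:
    """Labels per trait and overall, with the divergence direction.

    A positive diagonal element marks disruptive selection on that trait in
    isolation; a positive leading eigenvalue makes the singular point a
    candidate branching point (divergence along the leading eigenvector).
    """
    out = {
        "per_trait": dict(report.trait_labels),
        "net": ("net_disruptive"
                if report.eigenvalues[0] > disruptive_tol
                else "net_stabilising"),
        "leading_eigenvalue": float(report.eigenvalues[0]),
    }
    if out["net"] == "net_disruptive":
        out["branching_direction"] = report.leading_eigenvector
        out["note"] = ("candidate branching point: curvature favours "
                       "divergence along the leading eigenvector")
    return out
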
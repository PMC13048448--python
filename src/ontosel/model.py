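"""Declarative life-history models for class- and age-structured populations.

A :class:`LifeHistoryModel` collects everything the invasion analysis needs:
per-class rate functions (class-oriented fecundity, mortality, developmental
rates), initial internal states, a genetic system (transmission and
trait-expression weights) and, optionally, constant class proportions at
birth which unlock the class-specific (rather than class-oriented) costate
shortcut.

Rate functions are plain Python callables; there is no on-disk model format.
They receive the expressed trait vector of the focal class, the current
internal-state vector, and an *environment* object.  The environment is
computed once per resident allelic vector ``v`` by the model's
``environment`` factory and carries ``v`` plus any equilibrium quantities the
rates need (e.g. the resident density).  This matches the assumption that the
environment is fully determined by the resident population at its fixed
attractor, while letting concrete models cache expensive equilibrium
computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Any, Callable

import numpy as np

from .genetics import GeneticSystem

__all__ = ["LifeHistoryModel", "validate_model", "register_model", "get_model", "MODEL_REGISTRY"]


def _default_environment(model: "LifeHistoryModel", v: np.ndarray) -> Any:
    return SimpleNamespace(v=np.asarray(v, dtype=float))


@dataclass
class LifeHistoryModel:
    """A class-structured life-history model with evolving non-plastic traits.

    Rate-function signatures (``j`` = focal/parent class, ``i`` = offspring
    class, ``z`` = expressed trait vector ``(nz,)`` of class ``j``, ``x`` =
    internal states ``(nx,)``, ``env`` = environment object):

    * ``fecundity(i, j, z, x, env) -> float`` — rate of production of
      class-``i`` offspring (per unit time, nonnegative);
    * ``mortality(j, z, x, env) -> float`` — per-capita death rate;
    * ``growth(j, z, x, env) -> ndarray (nx,)`` — rates of change of states.
    """

    n_classes: int
    n_traits: int
    n_states: int
    fecundity: Callable[[int, int, np.ndarray, np.ndarray, Any], float]
    mortality: Callable[[int, np.ndarray, np.ndarray, Any], float]
    growth: Callable[[int, np.ndarray, np.ndarray, Any], np.ndarray]
    initial_states: np.ndarray  # (nc, nx)
    genetics: GeneticSystem
    class_proportions: np.ndarray | None = None  # (nc, nc), unit column sums
    total_fecundity: Callable[[int, np.ndarray, np.ndarray, Any], float] | None = None
    environment: Callable[["LifeHistoryModel", np.ndarray], Any] | None = None
    class_names: tuple[str, ...] = ()
    name: str = ""
    trait_bounds: tuple[float, float] = (0.0, np.inf)
    _env_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.initial_states = np.atleast_2d(np.asarray(self.initial_states, float))
        if not self.class_names:
            self.class_names = tuple(str(j) for j in range(self.n_classes))
        if self.class_proportions is not None:
            self.class_proportions = np.asarray(self.class_proportions, float)
        if self.total_fecundity is None and self.class_proportions is not None:
            # under constant class proportions f_ij = c_ij * f_j
            def _total(j, z, x, env, _m=self):
                return sum(
                    _m.fecundity(i, j, z, x, env) for i in range(_m.n_classes)
                )

            self.total_fecundity = _total

    # -- environment ------------------------------------------------------
    def env(self, v: np.ndarray) -> Any:
        """Environment at resident ``v`` (memoised per model instance)."""
        v = np.asarray(v, dtype=float)
        key = v.tobytes()
        if key not in self._env_cache:
            factory = self.environment or _default_environment
            if len(self._env_cache) > 256:
                self._env_cache.clear()
            self._env_cache[key] = factory(self, v)
        return self._env_cache[key]

    @property
    def has_constant_class_proportions(self) -> bool:
        return self.class_proportions is not None

    def resident_traits(self, v: np.ndarray) -> np.ndarray:
        """Resident trait matrix ``(nc, nz)`` (identity: z(v, v) = v)."""
        return np.asarray(v, dtype=float).reshape(self.n_classes, self.n_traits)


def validate_model(
    model: LifeHistoryModel,
    v_samples: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Check a model's structural invariants; returns a list of violations.

    Checks shapes, unit column sums of the class proportions, nonnegativity
    of fecundity and mortality at sampled trait/state points, finiteness of
    growth rates, and the resident identity ``z(v, v) = v``.  An empty list
    means the model passed every check.
    """
    rng = rng or np.random.default_rng(0)
    problems: list[str] = []
    nc, nz, nx = model.n_classes, model.n_traits, model.n_states

    if model.genetics.transmission.shape != (nc, nc):
        problems.append(
            f"transmission matrix has shape {model.genetics.transmission.shape}, "
            f"expected {(nc, nc)}"
        )
    if model.initial_states.shape != (nc, nx):
        problems.append(
            f"initial_states has shape {model.initial_states.shape}, expected {(nc, nx)}"
        )
    if model.class_proportions is not None:
        cp = model.class_proportions
        if cp.shape != (nc, nc):
            problems.append(f"class proportions have shape {cp.shape}, expected {(nc, nc)}")
        else:
            if np.any(cp < -1e-12) or np.any(cp > 1 + 1e-12):
                problems.append("class proportions outside [0, 1]")
            colsums = cp.sum(axis=0)
            if not np.allclose(colsums, 1.0, atol=1e-8):
                problems.append(
                    f"class proportions not normalized (column sums {colsums})"
                )

    if v_samples is None:
        lo, hi = model.trait_bounds
        hi = min(hi, 1.0) if np.isfinite(hi) else 1.0
        v_samples = lo + (hi - lo) * rng.random((3, nc * nz)) * 0.9 + 0.05 * (hi - lo)

    from .genetics import express_traits

    for v in np.atleast_2d(v_samples):
        vmat = v.reshape(nc, nz)
        z_res = express_traits(vmat, vmat, model.genetics)
        if not np.allclose(z_res, vmat, atol=1e-12):
            problems.append(f"resident identity z(v, v) != v at v={v}")
        try:
            env = model.env(v)
        except Exception as exc:  # environment construction is model code
            problems.append(f"environment factory failed at v={v}: {exc!r}")
            continue
        for j in range(nc):
            zj = vmat[j]
            for x in (model.initial_states[j], model.initial_states[j] + 0.5):
                try:
                    mu = model.mortality(j, zj, x, env)
                    if not np.isfinite(mu) or mu < 0:
                        problems.append(
                            f"negative rate: mortality for class {model.class_names[j]} "
                            f"is {mu} at v={v}"
                        )
                    g = np.asarray(model.growth(j, zj, x, env), float)
                    if g.shape != (nx,) or not np.all(np.isfinite(g)):
                        problems.append(
                            f"growth rate of class {model.class_names[j]} is not a "
                            f"finite length-{nx} vector at v={v}"
                        )
                    for i in range(nc):
                        f = model.fecundity(i, j, zj, x, env)
                        if not np.isfinite(f) or f < -1e-12:
                            problems.append(
                                f"negative rate: fecundity f[{i},{j}]={f} at v={v}"
                            )
                except Exception as exc:
                    problems.append(
                        f"rate function raised for class {model.class_names[j]} "
                        f"at v={v}: {exc!r}"
                    )
                    break
    return problems


#: registry of named built-in model constructors
MODEL_REGISTRY: dict[str, Callable[..., LifeHistoryModel]] = {}


def register_model(name: str, factory: Callable[..., LifeHistoryModel]) -> None:
    MODEL_REGISTRY[name] = factory


def get_model(name: str, **kwargs) -> LifeHistoryModel:
    try:
        factory = MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered: {sorted(MODEL_REGISTRY)}"
        ) from None
    return factory(**kwargs)
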
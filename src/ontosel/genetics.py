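"""Genetic systems: transmission, trait expression and shared-trait constraints.

A *genetic system* describes how allelic values map onto expressed traits and
how allele copies flow from parents to offspring classes.  Two ingredients
matter for invasion analysis:

* the transmission matrix ``gamma``, whose entry ``gamma[i, j]`` is the
  expected number of mutant allele copies carried by one class-``i`` offspring
  of a class-``j`` mutant parent (1/2 per offspring for a diploid heterozygote
  under fair meiosis, 1 for a haploid parent, 0 for a haploid father to sons);

* the *genetic exposure* ``dz/du``, the marginal effect of the mutant allelic
  value on the trait expressed by a mutant carrier (1/2 for a diploid
  heterozygote under additive gene action and dosage compensation, 1 for a
  haploid carrier).

Mutant trait expression is additive: ``z(u, v) = v + exposure * (u - v)``,
which covers haploidy (``z = u``), diploidy (``z = (u + v) / 2``) and any
per-class mixture of the two, and satisfies the resident identity
``z(v, v) = v`` exactly.

Shared-trait (pleiotropic) constraints are represented as groups of
``(class, trait)`` index pairs forced to carry one common allelic value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeneticSystem", "make_genetic_system", "express_traits", "apply_constraints"]

#: (class, trait) index pair
TraitIndex = tuple[int, int]


@dataclass(frozen=True)
class GeneticSystem:
    """Ploidy, transmission and trait-expression weights for each class."""

    kind: str
    ploidy: tuple[str, ...]
    transmission: np.ndarray  # (nc, nc) expected mutant copies per offspring
    exposure: np.ndarray  # (nc,) dz/du per carrier class
    constraint_groups: tuple[tuple[TraitIndex, ...], ...] = field(default=())

    @property
    def n_classes(self) -> int:
        return self.transmission.shape[0]

    def with_constraints(self, *groups: tuple[TraitIndex, ...]) -> "GeneticSystem":
        """Return a copy with shared-trait constraint groups attached."""
        return GeneticSystem(
            kind=self.kind,
            ploidy=self.ploidy,
            transmission=self.transmission,
            exposure=self.exposure,
            constraint_groups=tuple(tuple(g) for g in groups),
        )


def make_genetic_system(kind: str, primary_sex_ratio: float = 0.5) -> GeneticSystem:
    """Build one of the built-in genetic systems.

    Parameters
    ----------
    kind
        ``"diploid_two_sex"`` — two classes (female, male), both diploid,
        full genetic mixing: every transmission weight is 1/2 and every
        exposure is 1/2.
        ``"haplodiploid_two_sex"`` — diploid females, haploid males
        (arrhenotoky): mothers transmit 1/2 to daughters and sons, fathers
        transmit 1 to daughters and 0 to sons; male exposure is 1 under
        complete dosage compensation.
        ``"haploid_single_class"`` — one haploid class, identity
        transmission and exposure 1.
    primary_sex_ratio
        Proportion of males at birth; only checked for the two-sex kinds.
    """
    if kind in ("diploid_two_sex", "haplodiploid_two_sex"):
        if not 0.0 < primary_sex_ratio < 1.0:
            raise ValueError(
                f"primary_sex_ratio must lie in (0, 1), got {primary_sex_ratio}"
            )
    if kind == "diploid_two_sex":
        return GeneticSystem(
            kind=kind,
            ploidy=("diploid", "diploid"),
            transmission=np.full((2, 2), 0.5),
            exposure=np.array([0.5, 0.5]),
        )
    if kind == "haplodiploid_two_sex":
        # class order (female, male); entry [i, j]: offspring class i, parent j
        gamma = np.array(
            [
                [0.5, 1.0],  # daughters: 1/2 from mother, 1 from father
                [0.5, 0.0],  # sons: 1/2 from mother, nothing from father
            ]
        )
        return GeneticSystem(
            kind=kind,
            ploidy=("diploid", "haploid"),
            transmission=gamma,
            exposure=np.array([0.5, 1.0]),
        )
    if kind == "haploid_single_class":
        return GeneticSystem(
            kind=kind,
            ploidy=("haploid",),
            transmission=np.ones((1, 1)),
            exposure=np.array([1.0]),
        )
    raise ValueError(f"unknown genetic system kind: {kind!r}")


def express_traits(
    u: np.ndarray, v: np.ndarray, system: GeneticSystem
) -> np.ndarray:
    """Mutant trait values ``z(u, v)`` under additive gene action.

    ``u`` and ``v`` are arrays of allelic values with the class axis first
    (shape ``(nc,)`` or ``(nc, nz)``).  Returns an array of the same shape.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch: u {u.shape} vs v {v.shape}")
    if u.shape[0] != system.n_classes:
        raise ValueError(
            f"first axis ({u.shape[0]}) must index the {system.n_classes} classes"
        )
    w = system.exposure.reshape((-1,) + (1,) * (u.ndim - 1))
    return v + w * (u - v)


def apply_constraints(values: np.ndarray, system: GeneticSystem) -> np.ndarray:
    """Force each shared-trait constraint group to a single common value.

    ``values`` has shape ``(nc, nz)``; members of each group are replaced by
    the group mean, so the output is invariant under any within-group
    permutation of the input and already-constrained inputs pass through
    unchanged.
    """
    out = np.array(values, dtype=float)
    if out.ndim == 1:
        out = out[:, None]
    for group in system.constraint_groups:
        shared = float(np.mean([out[j, l] for (j, l) in group]))
        for j, l in group:
            out[j, l] = shared
    return out.reshape(np.shape(values))
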
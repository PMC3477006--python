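"""Entity-class kinds and their lattice algebra.

The OBO Relation Ontology distinguishes two non-overlapping types of
biological entity classes: *continuants* (things, objects, structures) and
*processes* (activities and events).  Continuants subdivide further into
*material* (cell, DNA, hemoglobin) and *immaterial* (cavities, lumina,
channel interiors) continuants.  These four declarable kinds, together with
two bookkeeping values, form a meet-semilattice::

                UNKNOWN            (no commitment yet)
                /     \\
          PROCESS   CONTINUANT
                    /        \\
              MATERIAL    IMMATERIAL
                \\   |     /    /
                 \\  |    /    /
                   BOTTOM          (contradiction / unsatisfiable)

``UNKNOWN`` is the top element (an unstereotyped class could still be
anything); ``BOTTOM`` is the bottom element encoding an impossible
combination, e.g. a class required to be both a process and a continuant.
The meet (greatest lower bound) of two kinds is the most general kind
compatible with both; disjointness of the branches is exactly the statement
that their meet is ``BOTTOM``.
"""

from __future__ import annotations

import enum

__all__ = [
    "EntityKind",
    "DECLARABLE_KINDS",
    "kind_meet",
    "kind_satisfies",
    "branch_of",
]


class EntityKind(enum.Enum):
    """A node of the entity-class kind lattice."""

    PROCESS = "process"
    CONTINUANT = "continuant"
    MATERIAL = "material"
    IMMATERIAL = "immaterial"
    UNKNOWN = "unknown"
    BOTTOM = "bottom"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"EntityKind.{self.name}"

    @property
    def declarable(self) -> bool:
        """True for the four kinds a user may declare on a class."""
        return self in DECLARABLE_KINDS

    def __le__(self, other: "EntityKind") -> bool:
        return kind_satisfies(self, other)


#: The four user-declarable kinds (the profile's entity-class stereotypes).
DECLARABLE_KINDS: tuple[EntityKind, ...] = (
    EntityKind.PROCESS,
    EntityKind.CONTINUANT,
    EntityKind.MATERIAL,
    EntityKind.IMMATERIAL,
)

# Strict ancestors (excluding self) of each kind; BOTTOM is below everything
# and UNKNOWN above everything, handled explicitly in the helpers.
_UP: dict[EntityKind, frozenset[EntityKind]] = {
    EntityKind.UNKNOWN: frozenset(),
    EntityKind.PROCESS: frozenset({EntityKind.UNKNOWN}),
    EntityKind.CONTINUANT: frozenset({EntityKind.UNKNOWN}),
    EntityKind.MATERIAL: frozenset({EntityKind.CONTINUANT, EntityKind.UNKNOWN}),
    EntityKind.IMMATERIAL: frozenset({EntityKind.CONTINUANT, EntityKind.UNKNOWN}),
    EntityKind.BOTTOM: frozenset(
        {
            EntityKind.PROCESS,
            EntityKind.CONTINUANT,
            EntityKind.MATERIAL,
            EntityKind.IMMATERIAL,
            EntityKind.UNKNOWN,
        }
    ),
}


def kind_satisfies(declared: EntityKind, bound: EntityKind) -> bool:
    """True iff ``declared`` lies at or below ``bound`` in the lattice.

    This is the strict-mode endpoint test: a class declared ``MATERIAL``
    satisfies a ``CONTINUANT`` bound, but a bare ``CONTINUANT`` does not
    satisfy a ``MATERIAL`` bound.
    """
    return declared is bound or bound in _UP[declared]


def kind_meet(a: EntityKind, b: EntityKind) -> EntityKind:
    """Greatest lower bound of two kinds.

    Commutative, associative and idempotent; ``UNKNOWN`` is the identity and
    ``BOTTOM`` is absorbing.  Incomparable pairs (process vs continuant,
    material vs immaterial) meet at ``BOTTOM``, realising the profile's
    mutual-exclusivity of those stereotypes.
    """
    if kind_satisfies(a, b):
        return a
    if kind_satisfies(b, a):
        return b
    return EntityKind.BOTTOM


def branch_of(kind: EntityKind) -> EntityKind | None:
    """The top-level branch (PROCESS or CONTINUANT) a kind commits to.

    ``UNKNOWN`` commits to neither branch and returns ``None``; ``BOTTOM``
    vacuously belongs to both and also returns ``None`` (callers treat it as
    already-failed rather than branch-resolved).
    """
    if kind is EntityKind.PROCESS:
        return EntityKind.PROCESS
    if kind in (EntityKind.CONTINUANT, EntityKind.MATERIAL, EntityKind.IMMATERIAL):
        return EntityKind.CONTINUANT
    return None
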
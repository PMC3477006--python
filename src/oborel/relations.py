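"""The relation inventory of the OBO Relation Ontology.

Twenty-two relations in four categories: foundational (is_a, part_of and
friends), spatial (located_in, contained_in, ...), temporal (derives_from,
preceded_by, ...) and participation (has_participant, has_agent, ...).
All are class-level relations except ``instance_of``, which links a
particular to the class it instantiates.

Relation names appear in the literature both hyphenated (``part-of``) and
underscored (``part_of``); :func:`normalize_relation_name` folds both to the
canonical underscored lowercase form.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "RelationCategory",
    "RelationLevel",
    "RelationKind",
    "normalize_relation_name",
    "relation_registry",
    "get_relation",
    "extension_relation",
    "UnknownRelationError",
    "EXTENSION_RELATIONS",
]


class RelationCategory(enum.Enum):
    FOUNDATIONAL = "foundational"
    SPATIAL = "spatial"
    TEMPORAL = "temporal"
    PARTICIPATION = "participation"
    #: Relations outside the canonical inventory (e.g. contributes_to,
    #: involved_in, or arbitrary relationship names met in OBO files).
    EXTENSION = "extension"


class RelationLevel(enum.Enum):
    CLASS_CLASS = "class-class"
    INSTANCE_CLASS = "instance-class"


@dataclass(frozen=True, slots=True)
class RelationKind:
    """One relation of the inventory (or a registered extension).

    ``inverse`` names the registry relation reading the same fact in the
    opposite direction (``part_of`` ↔ ``has_part``); involutive when defined.
    """

    name: str
    category: RelationCategory
    level: RelationLevel = RelationLevel.CLASS_CLASS
    inverse: str | None = None

    def __str__(self) -> str:
        return self.name

    @property
    def is_extension(self) -> bool:
        return self.category is RelationCategory.EXTENSION

    @property
    def is_association(self) -> bool:
        """True for relations realised as instance-to-instance links.

        Every class-level relation except ``is_a`` (a generalization, not an
        association) carries the all/some instance semantics.
        """
        return (
            self.level is RelationLevel.CLASS_CLASS and self.name != "is_a"
        )


class UnknownRelationError(KeyError):
    """Raised when a name does not resolve to a registry relation."""


def normalize_relation_name(name: str) -> str:
    """Canonicalize a relation name to lowercase underscored form.

    Idempotent: hyphens and runs of whitespace become single underscores,
    case is folded.
    """
    parts = name.strip().lower().replace("-", " ").replace("_", " ").split()
    return "_".join(parts)


def _build_registry() -> dict[str, RelationKind]:
    F = RelationCategory.FOUNDATIONAL
    S = RelationCategory.SPATIAL
    T = RelationCategory.TEMPORAL
    P = RelationCategory.PARTICIPATION
    rows: list[tuple[str, RelationCategory, str | None]] = [
        # foundational (8)
        ("instance_of", F, None),
        ("is_a", F, None),
        ("part_of", F, "has_part"),
        ("has_part", F, "part_of"),
        ("integral_part_of", F, "has_integral_part"),
        ("has_integral_part", F, "integral_part_of"),
        ("proper_part_of", F, "has_proper_part"),
        ("has_proper_part", F, "proper_part_of"),
        # spatial (5)
        ("located_in", S, "location_of"),
        ("location_of", S, "located_in"),
        ("contained_in", S, "contains"),
        ("contains", S, "contained_in"),
        ("adjacent_to", S, None),
        # temporal (5)
        ("transformation_of", T, None),
        ("derives_from", T, "derived_into"),
        ("derived_into", T, "derives_from"),
        ("preceded_by", T, "precedes"),
        ("precedes", T, "preceded_by"),
        # participation (4)
        ("has_participant", P, "participates_in"),
        ("participates_in", P, "has_participant"),
        ("has_agent", P, "agent_in"),
        ("agent_in", P, "has_agent"),
    ]
    registry = {}
    for name, cat, inv in rows:
        level = (
            RelationLevel.INSTANCE_CLASS
            if name == "instance_of"
            else RelationLevel.CLASS_CLASS
        )
        registry[name] = RelationKind(name=name, category=cat, level=level, inverse=inv)
    return registry


_REGISTRY: dict[str, RelationKind] = _build_registry()

#: Extension relations the lint advisor may suggest; not part of the
#: canonical 22-relation inventory and carrying no endpoint constraints.
EXTENSION_RELATIONS: dict[str, RelationKind] = {
    name: RelationKind(name=name, category=RelationCategory.EXTENSION)
    for name in ("contributes_to", "involved_in")
}


def relation_registry() -> tuple[RelationKind, ...]:
    """The canonical 22 relation kinds, in inventory order."""
    return tuple(_REGISTRY.values())


def get_relation(name: str) -> RelationKind:
    """Resolve a (possibly hyphenated) name to its registry relation.

    Raises :class:`UnknownRelationError` for names outside the inventory;
    use :func:`extension_relation` to obtain an unconstrained extension kind
    instead.
    """
    key = normalize_relation_name(name)
    try:
        return _REGISTRY[key]
    except KeyError:
        raise UnknownRelationError(key) from None


def extension_relation(name: str) -> RelationKind:
    """An unconstrained extension RelationKind for a non-inventory name.

    Returns the registry kind if the name does resolve, so callers can use
    this as a total lookup when loading arbitrary OBO relationship lines.
    """
    key = normalize_relation_name(name)
    if key in _REGISTRY:
        return _REGISTRY[key]
    if key in EXTENSION_RELATIONS:
        return EXTENSION_RELATIONS[key]
    return RelationKind(name=key, category=RelationCategory.EXTENSION)
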
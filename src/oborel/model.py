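"""The ontology container: entity classes, relation assertions, instances.

An :class:`OntologyModel` is a directed multigraph whose nodes are entity
classes and whose edges are class-level relation assertions, plus an
optional instance layer (instances and instance-to-instance links) used by
the all/some checker.  Assertions are kept with set semantics: at most one
edge per (relation, source, target) triple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .kinds import EntityKind
from .relations import RelationKind, RelationLevel

__all__ = [
    "EntityClass",
    "RelationAssertion",
    "InstanceSpec",
    "InstanceLink",
    "OntologyModel",
    "ModelError",
    "DuplicateError",
    "ResolutionError",
]


class ModelError(ValueError):
    """Base class for model construction errors."""


class DuplicateError(ModelError):
    """An id or assertion triple is already present."""


class ResolutionError(ModelError):
    """An id does not resolve to an element of the model."""


@dataclass(frozen=True, slots=True)
class EntityClass:
    """An entity class (a term): an id, a label and a declared kind.

    ``declared_kind`` may be ``UNKNOWN`` — plain OBO terms carry no
    continuant/process classification; the validator flags such classes
    (rule UNTYPED_CLASS) rather than refusing to load them.  It is never
    ``BOTTOM``: contradiction is a result of inference, not a declaration.
    """

    id: str
    name: str = ""
    declared_kind: EntityKind = EntityKind.UNKNOWN
    obsolete: bool = False

    def __post_init__(self) -> None:
        if self.declared_kind is EntityKind.BOTTOM:
            raise ModelError(f"class {self.id!r}: declared_kind may not be BOTTOM")


@dataclass(frozen=True, slots=True)
class RelationAssertion:
    """A directed class-level assertion ``kind(source, target)``.

    Reading direction follows the relation inventory: ``part_of(A, B)``
    states that instances of A are parts of instances of B.
    """

    kind: RelationKind
    source_id: str
    target_id: str

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.kind.name, self.source_id, self.target_id)

    def __str__(self) -> str:
        return f"{self.kind.name}({self.source_id} -> {self.target_id})"


@dataclass(frozen=True, slots=True)
class InstanceSpec:
    """A particular ``id`` instantiating the class ``class_id``."""

    id: str
    class_id: str


@dataclass(frozen=True, slots=True)
class InstanceLink:
    """An instance-level link ``kind(source, target)`` between particulars."""

    kind: RelationKind
    source_id: str
    target_id: str

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.kind.name, self.source_id, self.target_id)

    def __str__(self) -> str:
        return f"{self.kind.name}[{self.source_id} -> {self.target_id}]"


@dataclass
class OntologyModel:
    """Mutable container for an ontology fragment.

    Classes are id-indexed; assertions, instances and links keep insertion
    order but compare as sets (see :meth:`structurally_equal`).
    """

    metadata: dict[str, object] = field(default_factory=dict)
    _classes: dict[str, EntityClass] = field(default_factory=dict)
    _relations: list[RelationAssertion] = field(default_factory=list)
    _triples: set[tuple[str, str, str]] = field(default_factory=set)
    _instances: dict[str, InstanceSpec] = field(default_factory=dict)
    _links: list[InstanceLink] = field(default_factory=list)
    _link_triples: set[tuple[str, str, str]] = field(default_factory=set)

    # -- classes ---------------------------------------------------------

    @property
    def classes(self) -> tuple[EntityClass, ...]:
        return tuple(self._classes.values())

    def class_ids(self) -> tuple[str, ...]:
        return tuple(self._classes)

    def has_class(self, class_id: str) -> bool:
        return class_id in self._classes

    def get_class(self, class_id: str) -> EntityClass:
        try:
            return self._classes[class_id]
        except KeyError:
            raise ResolutionError(f"unknown class id {class_id!r}") from None

    def add_class(self, cls: EntityClass) -> "OntologyModel":
        if cls.id in self._classes:
            raise DuplicateError(f"duplicate class id {cls.id!r}")
        self._classes[cls.id] = cls
        return self

    def replace_class(self, cls: EntityClass) -> "OntologyModel":
        """Replace an existing class (e.g. to apply an inferred kind)."""
        if cls.id not in self._classes:
            raise ResolutionError(f"unknown class id {cls.id!r}")
        self._classes[cls.id] = cls
        return self

    # -- relations -------------------------------------------------------

    @property
    def relations(self) -> tuple[RelationAssertion, ...]:
        return tuple(self._relations)

    def add_relation(self, assertion: RelationAssertion) -> "OntologyModel":
        if assertion.kind.level is not RelationLevel.CLASS_CLASS:
            raise ModelError(
                f"{assertion.kind.name} is not a class-level relation"
            )
        for end in (assertion.source_id, assertion.target_id):
            if end not in self._classes:
                raise ResolutionError(f"unknown class id {end!r} in {assertion}")
        if assertion.triple in self._triples:
            raise DuplicateError(f"duplicate assertion {assertion}")
        self._relations.append(assertion)
        self._triples.add(assertion.triple)
        return self

    def has_relation(self, kind_name: str, source_id: str, target_id: str) -> bool:
        return (kind_name, source_id, target_id) in self._triples

    def relations_from(self, source_id: str) -> tuple[RelationAssertion, ...]:
        return tuple(r for r in self._relations if r.source_id == source_id)

    # -- instances -------------------------------------------------------

    @property
    def instances(self) -> tuple[InstanceSpec, ...]:
        return tuple(self._instances.values())

    def get_instance(self, instance_id: str) -> InstanceSpec:
        try:
            return self._instances[instance_id]
        except KeyError:
            raise ResolutionError(f"unknown instance id {instance_id!r}") from None

    def add_instance(self, spec: InstanceSpec) -> "OntologyModel":
        if spec.id in self._instances:
            raise DuplicateError(f"duplicate instance id {spec.id!r}")
        if spec.class_id not in self._classes:
            raise ResolutionError(
                f"instance {spec.id!r} instantiates unknown class {spec.class_id!r}"
            )
        self._instances[spec.id] = spec
        return self

    def instances_of(self, class_id: str) -> tuple[InstanceSpec, ...]:
        return tuple(i for i in self._instances.values() if i.class_id == class_id)

    # -- links -----------------------------------------------------------

    @property
    def links(self) -> tuple[InstanceLink, ...]:
        return tuple(self._links)

    def add_link(self, link: InstanceLink) -> "OntologyModel":
        if not link.kind.is_association:
            raise ModelError(
                f"{link.kind.name} cannot be used as an instance-level link"
            )
        for end in (link.source_id, link.target_id):
            if end not in self._instances:
                raise ResolutionError(f"unknown instance id {end!r} in {link}")
        if link.triple in self._link_triples:
            raise DuplicateError(f"duplicate link {link}")
        self._links.append(link)
        self._link_triples.add(link.triple)
        return self

    # -- whole-model helpers ---------------------------------------------

    def __len__(self) -> int:
        return len(self._classes)

    def __iter__(self) -> Iterator[EntityClass]:
        return iter(self._classes.values())

    def structurally_equal(self, other: "OntologyModel") -> bool:
        """Equality on classes (with kinds), assertions, instances, links.

        Insertion order and metadata are not compared.
        """
        return (
            self._classes == other._classes
            and self._triples == other._triples
            and self._instances == other._instances
            and self._link_triples == other._link_triples
        )


def build_model(
    classes: Iterable[EntityClass],
    relations: Iterable[RelationAssertion] = (),
) -> OntologyModel:
    """Convenience constructor for a model from class/assertion iterables."""
    model = OntologyModel()
    for cls in classes:
        model.add_class(cls)
    for rel in relations:
        model.add_relation(rel)
    return model
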
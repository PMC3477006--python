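"""Endpoint constraints per relation and model validation.

Each relation of the inventory constrains the kinds of the entity classes
it may connect.  Some constraints are simple bounds (``has_agent`` links a
process to a material continuant), some couple the two endpoints
(``is_a``/``part_of`` must stay within one branch of the kind lattice), and
the part-whole family adds conditional material/immaterial rules: a
material part implies a material whole, an immaterial whole implies
immaterial parts — while an immaterial part may sit in either a material or
an immaterial whole.

Two checking modes are provided.  STRICT is the profile's intended regime,
where every class is already stereotyped and a declared kind must *satisfy*
each bound.  LENIENT accepts a kind whenever it is still *refinable* to the
bound (its meet with the bound is not BOTTOM), which is the right reading
for plain OBO files whose terms are untyped.  STRICT issues are always a
superset of LENIENT issues.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .kinds import EntityKind, branch_of, kind_meet, kind_satisfies
from .model import OntologyModel, RelationAssertion, InstanceLink
from .relations import (
    RelationKind,
    RelationLevel,
    get_relation,
    relation_registry,
)

__all__ = [
    "Mode",
    "Severity",
    "ConditionalRule",
    "KindConstraint",
    "ValidationIssue",
    "ValidationReport",
    "endpoint_rule",
    "check_relation",
    "check_kind_pair",
    "validate_model",
    "valid_kind_pairs",
    "check_all_some",
    "RULE_IDS",
]


class Mode(enum.Enum):
    STRICT = "strict"
    LENIENT = "lenient"


class Severity(enum.Enum):
    ERROR = "error"
    WARNING = "warning"


#: Closed set of rule identifiers a ValidationIssue may carry.
RULE_IDS: tuple[str, ...] = (
    "ENDPOINT_KIND",
    "SAME_BRANCH",
    "CONDITIONAL_KIND",
    "IRREFLEXIVE",
    "UNTYPED_CLASS",
    "RECIPROCITY",
    "ALL_SOME",
    "UNSATISFIABLE_KIND",
)


@dataclass(frozen=True, slots=True)
class ConditionalRule:
    """If the ``antecedent_end`` endpoint is (at or below) ``antecedent``,
    the other endpoint must satisfy ``consequent``.

    Only MATERIAL/IMMATERIAL ever appear here (the part-whole coupling)."""

    antecedent_end: str  # "source" | "target"
    antecedent: EntityKind
    consequent: EntityKind

    @property
    def consequent_end(self) -> str:
        return "target" if self.antecedent_end == "source" else "source"


@dataclass(frozen=True, slots=True)
class KindConstraint:
    """The full endpoint rule for one relation kind.

    ``source_bound``/``target_bound`` of UNKNOWN mean "no bound".
    ``same_branch`` requires both endpoints jointly in the process branch or
    jointly in the continuant branch.  ``specification_parity`` (is_a only)
    additionally requires continuant endpoints to carry the same level of
    material/immaterial specification.
    """

    relation: RelationKind
    source_bound: EntityKind = EntityKind.UNKNOWN
    target_bound: EntityKind = EntityKind.UNKNOWN
    same_branch: bool = False
    conditional_rules: tuple[ConditionalRule, ...] = ()
    specification_parity: bool = False
    irreflexive: bool = False
    reciprocal_expected: bool = False


@dataclass(frozen=True, slots=True)
class ValidationIssue:
    """One detected violation or advisory finding."""

    rule_id: str
    severity: Severity
    subject: tuple[str, ...]
    message: str

    def sort_key(self) -> tuple:
        return (self.rule_id, self.subject, self.message)

    def to_dict(self) -> dict:
        return {
            "rule": self.rule_id,
            "severity": self.severity.value,
            "subject": list(self.subject),
            "message": self.message,
        }


@dataclass
class ValidationReport:
    """Aggregated validation outcome for a model."""

    mode: Mode
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for issue in self.issues:
            out[issue.rule_id] = out.get(issue.rule_id, 0) + 1
        return out

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity is Severity.ERROR]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity is Severity.WARNING]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode.value,
            "issues": [i.to_dict() for i in self.issues],
            "counts": self.counts,
        }


_PART_CONDITIONALS = (
    ConditionalRule("source", EntityKind.MATERIAL, EntityKind.MATERIAL),
    ConditionalRule("target", EntityKind.IMMATERIAL, EntityKind.IMMATERIAL),
)
# has_part reads the same fact whole-first, so the coupling mirrors.
_HAS_PART_CONDITIONALS = (
    ConditionalRule("target", EntityKind.MATERIAL, EntityKind.MATERIAL),
    ConditionalRule("source", EntityKind.IMMATERIAL, EntityKind.IMMATERIAL),
)

P = EntityKind.PROCESS
C = EntityKind.CONTINUANT
M = EntityKind.MATERIAL
I = EntityKind.IMMATERIAL
U = EntityKind.UNKNOWN


def _build_constraints() -> dict[str, KindConstraint]:
    table: dict[str, KindConstraint] = {}

    def row(name: str, **kwargs) -> None:
        table[name] = KindConstraint(relation=get_relation(name), **kwargs)

    row("is_a", same_branch=True, specification_parity=True)
    row("instance_of")  # instance->class resolution handled structurally

    for name in ("part_of", "proper_part_of", "integral_part_of"):
        row(
            name,
            same_branch=True,
            conditional_rules=_PART_CONDITIONALS,
            irreflexive=(name == "proper_part_of"),
            reciprocal_expected=(name == "integral_part_of"),
        )
    for name in ("has_part", "has_proper_part", "has_integral_part"):
        row(
            name,
            same_branch=True,
            conditional_rules=_HAS_PART_CONDITIONALS,
            irreflexive=(name == "has_proper_part"),
            reciprocal_expected=(name == "has_integral_part"),
        )

    for name in ("located_in", "location_of", "adjacent_to"):
        row(name, source_bound=C, target_bound=C)
    row("contained_in", source_bound=M, target_bound=I)
    row("contains", source_bound=I, target_bound=M)

    for name in ("derives_from", "derived_into", "transformation_of"):
        row(name, source_bound=M, target_bound=M)
    for name in ("preceded_by", "precedes"):
        row(name, source_bound=P, target_bound=P)

    row("has_participant", source_bound=P, target_bound=C)
    row("participates_in", source_bound=C, target_bound=P)
    row("has_agent", source_bound=P, target_bound=M)
    row("agent_in", source_bound=M, target_bound=P)
    return table


_CONSTRAINTS = _build_constraints()


def endpoint_rule(kind: RelationKind | str) -> KindConstraint:
    """The constraint-table row for a registry relation.

    Extension relations carry no constraints; asking for one raises
    :class:`KeyError` (callers treat missing rows as unconstrained).
    """
    name = kind.name if isinstance(kind, RelationKind) else get_relation(kind).name
    return _CONSTRAINTS[name]


def _bound_ok(declared: EntityKind, bound: EntityKind, mode: Mode) -> bool:
    if bound is EntityKind.UNKNOWN:
        return True
    if mode is Mode.STRICT:
        return kind_satisfies(declared, bound)
    return kind_meet(declared, bound) is not EntityKind.BOTTOM


def check_kind_pair(
    kind: RelationKind,
    source_kind: EntityKind,
    target_kind: EntityKind,
    mode: Mode = Mode.STRICT,
    subject: tuple[str, ...] = (),
    distinct_endpoints: bool = True,
) -> list[ValidationIssue]:
    """Evaluate a relation's kind constraints on a pair of endpoint kinds.

    This is the kernel shared by assertion checking, instance-link checking
    and the brute-force validity matrix.  ``subject`` is attached verbatim to
    any produced issue.
    """
    try:
        rule = _CONSTRAINTS[kind.name]
    except KeyError:
        return []  # extension relation: unconstrained
    issues: list[ValidationIssue] = []

    for end, declared, bound in (
        ("source", source_kind, rule.source_bound),
        ("target", target_kind, rule.target_bound),
    ):
        if not _bound_ok(declared, bound, mode):
            issues.append(
                ValidationIssue(
                    "ENDPOINT_KIND",
                    Severity.ERROR,
                    subject,
                    f"{kind.name}: {end} must be {bound.value}, "
                    f"found {declared.value}",
                )
            )

    branch_violated = False
    if rule.same_branch:
        bs, bt = branch_of(source_kind), branch_of(target_kind)
        if mode is Mode.STRICT:
            branch_violated = bs is None or bt is None or bs is not bt
        else:
            branch_violated = bs is not None and bt is not None and bs is not bt
        if branch_violated:
            issues.append(
                ValidationIssue(
                    "SAME_BRANCH",
                    Severity.ERROR,
                    subject,
                    f"{kind.name}: endpoints must both be processes or both "
                    f"continuants, found {source_kind.value}/{target_kind.value}",
                )
            )

    # is_a specification parity within the continuant branch: the two
    # endpoints must carry the same material/immaterial specification.
    # Skipped when the branch rule already failed (one root cause, one issue).
    if rule.specification_parity and not branch_violated:
        if branch_of(source_kind) is C and branch_of(target_kind) is C:
            if mode is Mode.STRICT:
                parity_ok = source_kind is target_kind
            else:
                parity_ok = (
                    kind_meet(source_kind, target_kind) is not EntityKind.BOTTOM
                )
            if not parity_ok:
                issues.append(
                    ValidationIssue(
                        "CONDITIONAL_KIND",
                        Severity.ERROR,
                        subject,
                        f"{kind.name}: continuant endpoints must carry the same "
                        f"material/immaterial specification, found "
                        f"{source_kind.value}/{target_kind.value}",
                    )
                )

    for cond in rule.conditional_rules:
        ante = source_kind if cond.antecedent_end == "source" else target_kind
        if not kind_satisfies(ante, cond.antecedent) or ante is EntityKind.BOTTOM:
            continue  # antecedent not established
        other = target_kind if cond.antecedent_end == "source" else source_kind
        if not _bound_ok(other, cond.consequent, mode):
            issues.append(
                ValidationIssue(
                    "CONDITIONAL_KIND",
                    Severity.ERROR,
                    subject,
                    f"{kind.name}: {cond.antecedent_end} is "
                    f"{cond.antecedent.value}, so {cond.consequent_end} must be "
                    f"{cond.consequent.value}, found {other.value}",
                )
            )

    if rule.irreflexive and not distinct_endpoints:
        issues.append(
            ValidationIssue(
                "IRREFLEXIVE",
                Severity.ERROR,
                subject,
                f"{kind.name}: source and target must be different classes",
            )
        )
    return issues


def check_relation(
    assertion: RelationAssertion,
    model: OntologyModel,
    mode: Mode = Mode.STRICT,
) -> list[ValidationIssue]:
    """All constraint issues raised by one class-level assertion.

    Endpoints must resolve (a :class:`ResolutionError` is raised otherwise —
    a malformed model, not a validation finding).  Assertions touching an
    obsolete class are skipped.
    """
    src = model.get_class(assertion.source_id)
    tgt = model.get_class(assertion.target_id)
    if src.obsolete or tgt.obsolete:
        return []
    return check_kind_pair(
        assertion.kind,
        src.declared_kind,
        tgt.declared_kind,
        mode=mode,
        subject=assertion.triple,
        distinct_endpoints=assertion.source_id != assertion.target_id,
    )


_RECIPROCAL_FAMILY = {
    # whole-side assertions that satisfy integral_part_of(A, B) as has_part(B, A)
    "integral_part_of": ("has_part", "has_proper_part", "has_integral_part"),
    "has_integral_part": ("part_of", "proper_part_of", "integral_part_of"),
}


def validate_model(model: OntologyModel, mode: Mode = Mode.STRICT) -> ValidationReport:
    """Validate every assertion of a model and aggregate a report.

    Beyond per-assertion constraint checks this adds UNTYPED_CLASS warnings
    for unstereotyped non-obsolete classes and RECIPROCITY warnings for
    integral part relations whose reciprocal whole-side assertion is absent.
    Issue order is deterministic (rule id, then subject).
    """
    issues: list[ValidationIssue] = []
    for assertion in model.relations:
        issues.extend(check_relation(assertion, model, mode))

    for cls in model.classes:
        if not cls.obsolete and cls.declared_kind is EntityKind.UNKNOWN:
            issues.append(
                ValidationIssue(
                    "UNTYPED_CLASS",
                    Severity.WARNING,
                    (cls.id,),
                    f"class {cls.name or cls.id!r} carries no "
                    "continuant/process stereotype",
                )
            )

    for assertion in model.relations:
        expected = _RECIPROCAL_FAMILY.get(assertion.kind.name)
        if expected is None:
            continue
        if model.get_class(assertion.source_id).obsolete:
            continue
        if model.get_class(assertion.target_id).obsolete:
            continue
        if not any(
            model.has_relation(k, assertion.target_id, assertion.source_id)
            for k in expected
        ):
            issues.append(
                ValidationIssue(
                    "RECIPROCITY",
                    Severity.WARNING,
                    assertion.triple,
                    f"{assertion.kind.name} expects a reciprocal part assertion "
                    f"from {assertion.target_id} back to {assertion.source_id}",
                )
            )

    issues.sort(key=ValidationIssue.sort_key)
    return ValidationReport(mode=mode, issues=issues)


def valid_kind_pairs(
    kind: RelationKind | str, mode: Mode = Mode.STRICT
) -> set[tuple[EntityKind, EntityKind]]:
    """Enumerate declarable kind pairs a relation accepts issue-free.

    Brute-forces the 16 (source, target) combinations over the four
    declarable kinds, on notionally distinct endpoint classes (so
    irreflexivity never excludes a *kind* pair).
    """
    rel = kind if isinstance(kind, RelationKind) else get_relation(kind)
    if rel.level is not RelationLevel.CLASS_CLASS:
        raise ValueError(f"{rel.name} is not a class-level relation")
    from .kinds import DECLARABLE_KINDS

    return {
        (s, t)
        for s in DECLARABLE_KINDS
        for t in DECLARABLE_KINDS
        if not check_kind_pair(rel, s, t, mode=mode, distinct_endpoints=True)
    }


def check_all_some(
    model: OntologyModel, mode: Mode = Mode.STRICT
) -> list[ValidationIssue]:
    """Instance-level evaluation of the all/some rule.

    A class-level association ``R(C, C1)`` promises that *every* instance of
    C bears an R-link to *some* instance of C1; each uncovered instance
    yields one ALL_SOME issue.  Instance links themselves are additionally
    endpoint-checked against the kinds of the classes their particulars
    instantiate.  With no instances the forAll is vacuous.
    """
    issues: list[ValidationIssue] = []

    for link in model.links:
        src_cls = model.get_class(model.get_instance(link.source_id).class_id)
        tgt_cls = model.get_class(model.get_instance(link.target_id).class_id)
        issues.extend(
            check_kind_pair(
                link.kind,
                src_cls.declared_kind,
                tgt_cls.declared_kind,
                mode=mode,
                subject=link.triple,
                distinct_endpoints=link.source_id != link.target_id,
            )
        )

    if model.instances:
        for assertion in model.relations:
            if not assertion.kind.is_association:
                continue
            targets = {
                i.id for i in model.instances_of(assertion.target_id)
            }
            for inst in model.instances_of(assertion.source_id):
                covered = any(
                    link.kind.name == assertion.kind.name
                    and link.source_id == inst.id
                    and link.target_id in targets
                    for link in model.links
                )
                if not covered:
                    issues.append(
                        ValidationIssue(
                            "ALL_SOME",
                            Severity.ERROR,
                            (inst.id,) + assertion.triple,
                            f"instance {inst.id!r} of {assertion.source_id!r} has "
                            f"no {assertion.kind.name} link to any instance of "
                            f"{assertion.target_id!r}",
                        )
                    )

    issues.sort(key=ValidationIssue.sort_key)
    return issues
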
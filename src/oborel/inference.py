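"""Fixpoint kind inference over the ontology graph.

Starting from the declared kinds (UNKNOWN for unstereotyped classes), the
endpoint constraints of every assertion are applied as meet operations
until nothing changes: endpoint bounds narrow an endpoint toward the bound,
the same-branch coupling of is_a/part-whole relations pushes a resolved
branch across the edge, and the material/immaterial conditionals fire once
their antecedent is established.  For is_a the two endpoint kinds are met
with each other directly — a subtype and its supertype must carry the same
branch and the same material specification.

Kinds only descend a finite lattice, so the iteration terminates; because
meet is commutative/associative the fixpoint does not depend on the order
in which assertions are processed.  A class driven to BOTTOM is
*unsatisfiable*: no entity-class stereotype is compatible with all the
relations it participates in (the classic example being an ontology-root
term that both processes and continuants specialise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constraints import endpoint_rule
from .kinds import EntityKind, branch_of, kind_meet, kind_satisfies
from .model import EntityClass, OntologyModel, RelationAssertion

__all__ = ["NarrowingStep", "KindAssignment", "infer_kinds", "unsatisfiable_classes"]


@dataclass(frozen=True, slots=True)
class NarrowingStep:
    """One lattice descent of one class, with its cause."""

    class_id: str
    before: EntityKind
    after: EntityKind
    cause: str

    def __str__(self) -> str:
        return (
            f"{self.class_id}: {self.before.value} -> {self.after.value} "
            f"({self.cause})"
        )


@dataclass
class KindAssignment:
    """Result of inference: per-class kind plus narrowing provenance.

    For every class the inferred kind is at or below its declared kind;
    a declaration contradicted by the graph surfaces as BOTTOM, never as a
    silent reassignment.
    """

    kinds: dict[str, EntityKind] = field(default_factory=dict)
    provenance: dict[str, list[NarrowingStep]] = field(default_factory=dict)

    def kind_of(self, class_id: str) -> EntityKind:
        return self.kinds[class_id]

    def chain(self, class_id: str) -> list[NarrowingStep]:
        """The narrowing steps that led to the class's inferred kind."""
        return self.provenance.get(class_id, [])

    def unsatisfiable(self) -> set[str]:
        return {cid for cid, k in self.kinds.items() if k is EntityKind.BOTTOM}

    def to_dict(self) -> dict:
        return {
            "kinds": {cid: k.value for cid, k in sorted(self.kinds.items())},
            "unsatisfiable": sorted(self.unsatisfiable()),
            "provenance": {
                cid: [str(s) for s in steps]
                for cid, steps in sorted(self.provenance.items())
                if steps
            },
        }


def _narrow(
    assignment: KindAssignment,
    class_id: str,
    bound: EntityKind,
    cause: str,
) -> bool:
    """Meet a class's kind with ``bound``; record provenance on descent."""
    before = assignment.kinds[class_id]
    after = kind_meet(before, bound)
    if after is before:
        return False
    assignment.kinds[class_id] = after
    assignment.provenance.setdefault(class_id, []).append(
        NarrowingStep(class_id, before, after, cause)
    )
    return True


def _contributions(
    snapshot: dict[str, EntityKind], assertion: RelationAssertion
) -> list[tuple[str, EntityKind, str]]:
    """Narrowing facts one assertion derives from a kind snapshot.

    A class already at BOTTOM emits nothing: its constraints are violated
    at that class and carry no usable information for its neighbours — this
    keeps a contradiction localized to the class where it surfaces instead
    of flooding the connected component.
    """
    try:
        rule = endpoint_rule(assertion.kind)
    except KeyError:
        return []  # extension relation: no constraints to propagate
    sid, tid = assertion.source_id, assertion.target_id
    if sid not in snapshot or tid not in snapshot:
        return []  # endpoint obsolete (excluded from inference)
    out: list[tuple[str, EntityKind, str]] = []
    label = str(assertion)

    if rule.source_bound is not EntityKind.UNKNOWN:
        out.append((sid, rule.source_bound, f"source bound of {label}"))
    if rule.target_bound is not EntityKind.UNKNOWN:
        out.append((tid, rule.target_bound, f"target bound of {label}"))

    if rule.specification_parity:
        # is_a: subtype and supertype share branch and specification; meet
        # each side with the other's kind.
        if snapshot[tid] is not EntityKind.BOTTOM:
            out.append((sid, snapshot[tid], f"supertype kind via {label}"))
        if snapshot[sid] is not EntityKind.BOTTOM:
            out.append((tid, snapshot[sid], f"subtype kind via {label}"))
    elif rule.same_branch:
        # Lazy disjunction: propagate only once one side resolves a branch.
        for a, b, end in ((sid, tid, "source"), (tid, sid, "target")):
            br = branch_of(snapshot[a])
            if br is not None:
                out.append((b, br, f"{end} branch of {label}"))

    for cond in rule.conditional_rules:
        ante_id = sid if cond.antecedent_end == "source" else tid
        other_id = tid if cond.antecedent_end == "source" else sid
        ante = snapshot[ante_id]
        if ante is EntityKind.BOTTOM:
            continue
        if kind_satisfies(ante, cond.antecedent):
            out.append(
                (
                    other_id,
                    cond.consequent,
                    f"{cond.antecedent_end} is {cond.antecedent.value} in {label}",
                )
            )
    return out


def infer_kinds(model: OntologyModel) -> KindAssignment:
    """Propagate kind constraints to a fixpoint.

    Returns the inferred per-class kinds with the narrowing steps that
    produced them.  Obsolete classes are excluded.  Propagation proceeds in
    synchronous rounds: every assertion derives its narrowing facts from
    the kinds of the *previous* round, and all facts of a round are folded
    in by meets.  Meets commute, so the inferred kinds do not depend on the
    order assertions are stored or processed; kinds only descend a finite
    lattice, so at most (number of classes x lattice height) rounds run.
    """
    assignment = KindAssignment()
    for cls in model.classes:
        if not cls.obsolete:
            assignment.kinds[cls.id] = cls.declared_kind

    changed = True
    while changed:
        changed = False
        snapshot = dict(assignment.kinds)
        for assertion in model.relations:
            for class_id, bound, cause in _contributions(snapshot, assertion):
                changed |= _narrow(assignment, class_id, bound, cause)
    return assignment


def unsatisfiable_classes(model: OntologyModel) -> set[str]:
    """Ids of classes whose inferred kind collapses to BOTTOM."""
    return infer_kinds(model).unsatisfiable()


def apply_assignment(model: OntologyModel, assignment: KindAssignment) -> OntologyModel:
    """A copy of the model re-declared with the inferred kinds.

    BOTTOM-inferred classes keep their original declaration (BOTTOM is not
    declarable); callers detect them via :meth:`KindAssignment.unsatisfiable`.
    """
    out = OntologyModel(metadata=dict(model.metadata))
    for cls in model.classes:
        inferred = assignment.kinds.get(cls.id, cls.declared_kind)
        if inferred is EntityKind.BOTTOM:
            inferred = cls.declared_kind
        out.add_class(
            EntityClass(cls.id, cls.name, inferred, cls.obsolete)
        )
    for rel in model.relations:
        out.add_relation(rel)
    for inst in model.instances:
        out.add_instance(inst)
    for link in model.links:
        out.add_link(link)
    return out
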
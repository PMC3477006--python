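"""Fixpoint kind inference: propagation, unsatisfiability, confluence."""

import random

import pytest

from oborel import (
    EntityClass,
    EntityKind,
    Mode,
    RelationAssertion,
    build_model,
    get_relation,
    infer_kinds,
    unsatisfiable_classes,
    validate_model,
)
from oborel.inference import apply_assignment
from oborel.fixtures import random_model

P = EntityKind.PROCESS
C = EntityKind.CONTINUANT
M = EntityKind.MATERIAL
U = EntityKind.UNKNOWN


def test_untypeable_root_is_unsatisfiable(go_root):
    assignment = infer_kinds(go_root)
    root = "GO:FIX01"
    assert assignment.kind_of(root) is EntityKind.BOTTOM
    # contradiction stays at the root; the branches keep their declarations
    assert assignment.unsatisfiable() == {root}
    assert unsatisfiable_classes(go_root) == {root}
    assert assignment.chain(root)  # provenance explains the collapse


def test_root_becomes_process_without_the_continuant_branch(go_root):
    reduced = build_model(
        go_root.classes,
        [r for r in go_root.relations if r.source_id != "GO:FIX03"],
    )
    assignment = infer_kinds(reduced)
    assert assignment.kind_of("GO:FIX01") is P
    assert assignment.unsatisfiable() == set()


def test_agent_bound_infers_material_participant():
    model = build_model([EntityClass("X:P1", "p1", P), EntityClass("X:X", "x", U)])
    model.add_relation(RelationAssertion(get_relation("has_agent"), "X:P1", "X:X"))
    assert infer_kinds(model).kind_of("X:X") is M


def test_declarations_pass_through_without_relations(pro):
    bare = build_model(pro.classes)
    assignment = infer_kinds(bare)
    assert assignment.kinds == {c.id: c.declared_kind for c in pro.classes}
    assert all(not assignment.chain(c.id) for c in pro.classes)


def test_satisfied_bound_does_not_collapse():
    # MATERIAL already satisfies the continuant source bound of participates_in
    model = build_model([EntityClass("X:M", "m", M), EntityClass("X:P", "p", P)])
    model.add_relation(
        RelationAssertion(get_relation("participates_in"), "X:M", "X:P")
    )
    assert unsatisfiable_classes(model) == set()


def test_clean_fixtures_have_no_unsatisfiable_classes(pro, xao, go_mi):
    for model in (pro, xao, go_mi):
        assert unsatisfiable_classes(model) == set()


def test_inference_refines_never_contradicts_silently():
    # inferred kind is at or below the declaration for every class
    for seed in range(5):
        planted = random_model(20, 60, 0.3, seed)
        assignment = infer_kinds(planted.model)
        for cls in planted.model.classes:
            inferred = assignment.kind_of(cls.id)
            from oborel import kind_satisfies

            assert kind_satisfies(inferred, cls.declared_kind) or (
                inferred is EntityKind.BOTTOM
            )


@pytest.mark.parametrize("seed", range(5))
def test_idempotence_on_bottom_free_models(seed):
    planted = random_model(25, 60, 0.0, seed)
    assignment = infer_kinds(planted.model)
    assert not assignment.unsatisfiable()
    again = infer_kinds(apply_assignment(planted.model, assignment))
    assert again.kinds == assignment.kinds


@pytest.mark.parametrize("seed", range(5))
def test_inferred_kinds_validate_cleanly(seed):
    # strip declarations, infer from structure alone, re-declare: no
    # endpoint or conditional errors remain in strict validation
    planted = random_model(25, 60, 0.0, seed)
    stripped = build_model(
        [EntityClass(c.id, c.name, U) for c in planted.model.classes],
        planted.model.relations,
    )
    assignment = infer_kinds(stripped)
    assert not assignment.unsatisfiable()
    redeclared = apply_assignment(stripped, assignment)
    report = validate_model(redeclared, Mode.STRICT)
    assert not [
        i for i in report.errors if i.rule_id in ("ENDPOINT_KIND", "CONDITIONAL_KIND")
    ]


@pytest.mark.parametrize("seed", range(5))
def test_result_is_processing_order_independent(seed):
    planted = random_model(20, 60, 0.4, seed)
    baseline = infer_kinds(planted.model).kinds
    rng = random.Random(seed)
    relations = list(planted.model.relations)
    rng.shuffle(relations)
    shuffled = build_model(planted.model.classes, relations)
    assert infer_kinds(shuffled).kinds == baseline
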
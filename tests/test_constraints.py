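"""Endpoint constraints, the two checking modes, and model validation."""

import random

import pytest

from oborel import (
    EntityClass,
    EntityKind,
    Mode,
    RelationAssertion,
    Severity,
    build_model,
    check_relation,
    endpoint_rule,
    get_relation,
    validate_model,
)
from oborel.fixtures import random_model

P = EntityKind.PROCESS
C = EntityKind.CONTINUANT
M = EntityKind.MATERIAL
I = EntityKind.IMMATERIAL
U = EntityKind.UNKNOWN


def pair_model(kind_name, src_kind, tgt_kind, same_class=False):
    a = EntityClass("T:A", "a", src_kind)
    if same_class:
        model = build_model([a])
        model.add_relation(RelationAssertion(get_relation(kind_name), "T:A", "T:A"))
        return model
    b = EntityClass("T:B", "b", tgt_kind)
    model = build_model([a, b])
    model.add_relation(RelationAssertion(get_relation(kind_name), "T:A", "T:B"))
    return model


def issues_for(kind_name, src_kind, tgt_kind, mode=Mode.STRICT, same_class=False):
    model = pair_model(kind_name, src_kind, tgt_kind, same_class)
    return check_relation(model.relations[0], model, mode)


class TestEndpointRuleTable:
    def test_has_agent_connects_process_to_material(self):
        rule = endpoint_rule("has_agent")
        assert rule.source_bound is P
        assert rule.target_bound is M

    def test_containment_is_material_in_immaterial(self):
        assert (endpoint_rule("contained_in").source_bound,
                endpoint_rule("contained_in").target_bound) == (M, I)
        assert (endpoint_rule("contains").source_bound,
                endpoint_rule("contains").target_bound) == (I, M)

    def test_proper_variants_are_irreflexive(self):
        assert endpoint_rule("proper_part_of").irreflexive
        assert endpoint_rule("has_proper_part").irreflexive
        assert not endpoint_rule("part_of").irreflexive

    def test_integral_variants_expect_reciprocals(self):
        assert endpoint_rule("integral_part_of").reciprocal_expected
        assert endpoint_rule("has_integral_part").reciprocal_expected
        assert not endpoint_rule("has_part").reciprocal_expected

    def test_location_family_has_no_material_constraint(self):
        for name in ("located_in", "location_of", "adjacent_to"):
            rule = endpoint_rule(name)
            assert rule.source_bound is C and rule.target_bound is C
            assert not rule.conditional_rules


class TestCheckRelation:
    def test_agent_must_be_material(self):
        issues = issues_for("has_agent", P, I)
        assert [i.rule_id for i in issues] == ["ENDPOINT_KIND"]

    def test_material_part_requires_material_whole(self):
        issues = issues_for("part_of", M, C)
        assert [i.rule_id for i in issues] == ["CONDITIONAL_KIND"]
        assert all(i.rule_id == "CONDITIONAL_KIND"
                   for i in issues_for("part_of", M, I))

    def test_immaterial_part_may_sit_in_material_whole(self):
        assert issues_for("part_of", I, M) == []

    def test_proper_part_of_self_is_irreflexive(self):
        issues = issues_for("proper_part_of", M, M, same_class=True)
        assert [i.rule_id for i in issues] == ["IRREFLEXIVE"]

    def test_part_of_across_branches_fails(self):
        assert [i.rule_id for i in issues_for("part_of", P, C)] == ["SAME_BRANCH"]

    def test_is_a_specification_parity(self):
        assert issues_for("is_a", M, M) == []
        assert issues_for("is_a", C, C) == []
        assert [i.rule_id for i in issues_for("is_a", M, C)] == ["CONDITIONAL_KIND"]
        assert [i.rule_id for i in issues_for("is_a", M, I)] == ["CONDITIONAL_KIND"]

    def test_lenient_accepts_refinable_kinds(self):
        # a bare continuant can still be refined to material
        assert issues_for("has_agent", P, C, Mode.LENIENT) == []
        assert [i.rule_id for i in issues_for("has_agent", P, C)] == [
            "ENDPOINT_KIND"
        ]
        # untyped endpoints pass lenient branch checks but fail strict
        assert issues_for("part_of", U, U, Mode.LENIENT) == []
        assert [i.rule_id for i in issues_for("part_of", U, U)] == ["SAME_BRANCH"]

    def test_lenient_still_rejects_contradictions(self):
        assert [i.rule_id for i in issues_for("has_agent", P, I, Mode.LENIENT)] == [
            "ENDPOINT_KIND"
        ]
        assert [i.rule_id for i in issues_for("part_of", P, C, Mode.LENIENT)] == [
            "SAME_BRANCH"
        ]


class TestValidateModel:
    def test_clean_fixtures_have_no_errors(self, pro, xao):
        for model in (pro, xao):
            report = validate_model(model, Mode.STRICT)
            assert report.errors == []

    def test_empty_model_gives_empty_report(self):
        report = validate_model(build_model([]))
        assert report.issues == []
        assert report.counts == {}

    def test_untyped_class_warning(self):
        model = build_model([EntityClass("X:1", "x", U)])
        report = validate_model(model)
        assert [i.rule_id for i in report.issues] == ["UNTYPED_CLASS"]
        assert report.issues[0].severity is Severity.WARNING

    def test_obsolete_classes_are_excluded(self):
        model = build_model(
            [
                EntityClass("X:1", "x", P, obsolete=True),
                EntityClass("X:2", "y", C),
            ]
        )
        model.add_relation(RelationAssertion(get_relation("is_a"), "X:1", "X:2"))
        report = validate_model(model)
        # no SAME_BRANCH error, no UNTYPED warning for the obsolete class
        assert report.issues == []

    def test_reciprocity_warning_for_integral_part(self):
        model = build_model([EntityClass("X:1", "x", M), EntityClass("X:2", "y", M)])
        model.add_relation(
            RelationAssertion(get_relation("integral_part_of"), "X:1", "X:2")
        )
        report = validate_model(model)
        assert [i.rule_id for i in report.issues] == ["RECIPROCITY"]
        assert report.issues[0].severity is Severity.WARNING
        # the reciprocal whole-side assertion silences the warning
        model.add_relation(RelationAssertion(get_relation("has_part"), "X:2", "X:1"))
        assert validate_model(model).issues == []

    def test_counts_match_issue_list(self, pro):
        report = validate_model(pro)
        assert sum(report.counts.values()) == len(report.issues)


class TestModeAndOrderProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_strict_issues_superset_of_lenient(self, seed):
        planted = random_model(20, 60, 0.4, seed)
        strict = validate_model(planted.model, Mode.STRICT)
        lenient = validate_model(planted.model, Mode.LENIENT)
        strict_keys = {(i.rule_id, i.subject) for i in strict.issues}
        lenient_keys = {(i.rule_id, i.subject) for i in lenient.issues}
        assert lenient_keys <= strict_keys

    @pytest.mark.parametrize("seed", range(3))
    def test_validation_is_insertion_order_independent(self, seed):
        planted = random_model(15, 40, 0.5, seed)
        baseline = validate_model(planted.model)
        rng = random.Random(seed)
        classes = list(planted.model.classes)
        relations = list(planted.model.relations)
        rng.shuffle(classes)
        rng.shuffle(relations)
        shuffled = build_model(classes, relations)
        assert validate_model(shuffled).issues == baseline.issues
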
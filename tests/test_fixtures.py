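"""Packaged fragments match their documented structure; generator contract."""

import pytest

from oborel import EntityKind, Mode, validate_model
from oborel.fixtures import GenerationError, random_model

M = EntityKind.MATERIAL
P = EntityKind.PROCESS


class TestProFragment:
    def test_shape(self, pro):
        assert len(pro) == 6
        assert len(pro.relations) == 6
        assert all(c.declared_kind is M for c in pro.classes)
        kinds = sorted(r.kind.name for r in pro.relations)
        assert kinds == ["derives_from", "derives_from", "is_a", "is_a", "is_a", "is_a"]

    def test_cleavage_product_derives_from_protein(self, pro):
        by_name = {c.name: c.id for c in pro.classes}
        assert pro.has_relation(
            "derives_from",
            by_name["TGF-Beta 1 Proteolytic Cleavage Product"],
            by_name["TGF-Beta 1"],
        )

    def test_validates_cleanly(self, pro):
        assert validate_model(pro, Mode.STRICT).errors == []


class TestXaoFragment:
    def test_shape(self, xao):
        assert len(xao) == 10
        assert len(xao.relations) == 11
        assert all(c.declared_kind is P for c in xao.classes)

    def test_stage_succession(self, xao):
        by_name = {c.name: c.id for c in xao.classes}
        assert xao.has_relation(
            "preceded_by", by_name["NF Stage 8"], by_name["NF Stage 7"]
        )
        assert xao.has_relation(
            "part_of", by_name["NF Stage 8"], by_name["Blastula"]
        )

    def test_validates_cleanly(self, xao):
        assert validate_model(xao, Mode.STRICT).errors == []


class TestGoRootFragment:
    def test_shape(self, go_root):
        assert len(go_root) == 4
        assert len(go_root.relations) == 3
        root = go_root.get_class("GO:FIX01")
        assert root.name == "Gene Ontology"
        assert root.declared_kind is EntityKind.UNKNOWN


class TestGenerator:
    def test_same_seed_reproduces_the_model(self):
        a = random_model(20, 50, 0.5, 42)
        b = random_model(20, 50, 0.5, 42)
        assert a.model.structurally_equal(b.model)
        assert a.planted_issues == b.planted_issues

    def test_zero_violation_rate_is_constructively_sound(self):
        for seed in range(5):
            planted = random_model(30, 80, 0.0, seed)
            assert planted.planted_issues == []
            assert validate_model(planted.model, Mode.STRICT).errors == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_full_violation_rate_recovered_exactly(self, seed):
        planted = random_model(50, 50, 1.0, seed)
        assert len(planted.planted_issues) == 50
        report = validate_model(planted.model, Mode.STRICT)
        found = {(i.rule_id, i.subject) for i in report.errors}
        assert found == set(planted.planted_issues)

    def test_at_most_one_violation_per_assertion(self):
        planted = random_model(40, 120, 0.6, 3)
        report = validate_model(planted.model, Mode.STRICT)
        per_assertion = {}
        for issue in report.errors:
            per_assertion[issue.subject] = per_assertion.get(issue.subject, 0) + 1
        assert all(v == 1 for v in per_assertion.values())

    def test_infeasible_requests_rejected(self):
        with pytest.raises(GenerationError):
            random_model(1, 5, 0.0, 0)
        with pytest.raises(GenerationError):
            random_model(10, 5, 1.5, 0)
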
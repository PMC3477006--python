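"""OBO flat-file subset: parsing, model mapping, round trips."""

import pytest
from hypothesis import given, strategies as st

from oborel import EntityClass, EntityKind, build_model, get_relation
from oborel.model import RelationAssertion
from oborel.obo import (
    OboFormatError,
    apply_instance_data,
    parse_obo,
    to_model,
    write_obo,
)
from oborel.fixtures import (
    FIXTURE_NAMES,
    fixture_path,
    go_mi_fragment,
    pro_fragment,
    random_model,
    xao_fragment,
)

SIMPLE = """\
format-version: 1.2

[Term]
id: XAO:1
name: Blastula

[Term]
id: XAO:2
name: NF stage 7
relationship: part_of XAO:1 ! part of blastula
"""


def test_relationship_line_parsed():
    doc = parse_obo(SIMPLE)
    assert [t.id for t in doc.terms] == ["XAO:1", "XAO:2"]
    assert doc.terms[1].relationships == [("part_of", "XAO:1")]
    model = to_model(doc)
    assert model.has_relation("part_of", "XAO:2", "XAO:1")


def test_hyphenated_table_spelling_is_normalized():
    doc = parse_obo(
        "[Term]\nid: A\n\n[Term]\nid: B\nrelationship: derives-from A\n"
    )
    assert doc.terms[1].relationships == [("derives_from", "A")]


def test_obsolete_flag_passthrough():
    doc = parse_obo("[Term]\nid: A\nis_obsolete: true\n")
    assert doc.terms[0].is_obsolete
    assert to_model(doc).get_class("A").obsolete


def test_crlf_and_unknown_tags_preserved():
    text = "[Term]\r\nid: A\r\nname: a\r\nxref: EXT:1\r\nsubset: goslim\r\n"
    doc = parse_obo(text)
    assert doc.terms[0].other_lines == ["xref: EXT:1", "subset: goslim"]
    # verbatim lines survive a model round trip
    model = to_model(doc)
    assert "xref: EXT:1" in write_obo(model)


def test_duplicate_term_id_is_a_format_error():
    with pytest.raises(OboFormatError):
        parse_obo("[Term]\nid: A\n\n[Term]\nid: A\n")


def test_relationship_without_target_is_a_format_error():
    with pytest.raises(OboFormatError):
        parse_obo("[Term]\nid: A\nrelationship: part_of\n")


def test_dangling_targets_become_warnings_not_errors():
    model = to_model(parse_obo("[Term]\nid: A\nis_a: GHOST\n"))
    assert model.has_class("A")
    assert not model.relations
    assert any("GHOST" in w for w in model.metadata["parse_warnings"])


def test_non_inventory_relationship_loads_as_extension_with_warning():
    model = to_model(
        parse_obo("[Term]\nid: A\n\n[Term]\nid: B\nrelationship: regulates A\n")
    )
    (rel,) = model.relations
    assert rel.kind.is_extension and rel.kind.name == "regulates"
    assert any("regulates" in w for w in model.metadata["parse_warnings"])


def test_empty_document_gives_empty_model():
    model = to_model(parse_obo("format-version: 1.2\n"))
    assert len(model) == 0 and not model.relations


def test_kind_annotations_round_trip():
    text = write_obo(pro_fragment())
    assert "property_value: oborel:kind material" in text
    model = to_model(parse_obo(text))
    assert all(
        c.declared_kind is EntityKind.MATERIAL for c in model.classes
    )


def test_kind_annotation_argument_overrides():
    doc = parse_obo("[Term]\nid: A\nname: a\n")
    model = to_model(doc, kind_annotations={"A": EntityKind.PROCESS})
    assert model.get_class("A").declared_kind is EntityKind.PROCESS


@pytest.mark.parametrize("name", FIXTURE_NAMES)
def test_shipped_fixture_files_round_trip(name):
    import oborel.fixtures as fx

    reference = getattr(fx, name)()
    with open(fixture_path(name), encoding="utf-8") as fh:
        model = to_model(parse_obo(fh))
    assert model.structurally_equal(reference)
    assert to_model(parse_obo(write_obo(model))).structurally_equal(reference)


@pytest.mark.parametrize("seed", range(10))
def test_random_models_round_trip(seed):
    model = random_model(15, 40, 0.3, seed).model
    assert to_model(parse_obo(write_obo(model))).structurally_equal(model)


@given(
    st.lists(
        st.sampled_from(["alpha", "beta", "gamma", "delta"]),
        min_size=1,
        max_size=4,
        unique=True,
    ),
    st.sampled_from(list(EntityKind)[:4]),
    st.sampled_from(["is_a", "part_of", "derives_from", "has_agent"]),
)
def test_roundtrip_property(ids, kind, rel_name):
    classes = [EntityClass(f"T:{i}", i.title(), kind) for i in ids]
    model = build_model(classes)
    if len(ids) >= 2:
        model.add_relation(
            RelationAssertion(get_relation(rel_name), f"T:{ids[0]}", f"T:{ids[1]}")
        )
    assert to_model(parse_obo(write_obo(model))).structurally_equal(model)


def test_parser_agrees_with_obonet_on_fixture_file():
    obonet = pytest.importorskip("obonet")
    path = str(fixture_path("xao_fragment"))
    graph = obonet.read_obo(path)
    ours = to_model(parse_obo(open(path, encoding="utf-8").read()))
    assert set(graph.nodes) == set(ours.class_ids())
    theirs = {
        (key, src, tgt) for src, tgt, key in graph.edges(keys=True)
    }
    assert theirs == {r.triple for r in ours.relations}


def test_instance_sidecar_loads_instances_and_links():
    model = xao_fragment()
    apply_instance_data(
        model,
        """
version: 1
instances:
  - {id: nf8_embryo, instance_of: "XAO:FIX09"}
  - {id: blastula_1, instance_of: "XAO:FIX06"}
links:
  - {relation: part-of, source: nf8_embryo, target: blastula_1}
""",
    )
    assert {i.id for i in model.instances} == {"nf8_embryo", "blastula_1"}
    (link,) = model.links
    assert link.kind.name == "part_of"
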
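"""Reader/writer for a subset of the OBO flat file format, plus the
instance-data sidecar.

The supported dialect is the line-oriented OBO 1.2 style: an optional
header, then ``[Term]`` stanzas with ``id``, ``name``, ``is_a``,
``relationship`` and ``is_obsolete`` tags.  All other tags are preserved
verbatim (in order) so that read-modify-write round-trips do not destroy
information the tool does not interpret.  Trailing ``! ...`` comments and
``{...}`` qualifier blocks on is_a/relationship lines are stripped;
relation names are normalized (``derives-from`` -> ``derives_from``).

OBO has no slot for the continuant/process classification, so declared
kinds are serialized as ``property_value: oborel:kind <KIND>`` annotation
lines in a reserved namespace; the parser recovers them, making
parse -> write -> parse the identity on the model.

Instance-level data (instance declarations plus instance links) lives in a
small YAML sidecar::

    version: 1
    instances:
      - {id: a1, instance_of: "XAO:FIX06"}
    links:
      - {relation: part_of, source: a1, target: b1}
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import yaml

from .kinds import EntityKind
from .model import (
    EntityClass,
    InstanceLink,
    InstanceSpec,
    OntologyModel,
    RelationAssertion,
)
from .relations import extension_relation, normalize_relation_name

__all__ = [
    "OboTerm",
    "OboDocument",
    "OboFormatError",
    "parse_obo",
    "to_model",
    "model_to_document",
    "write_obo",
    "load_model",
    "parse_instance_data",
    "apply_instance_data",
    "SidecarError",
]

KIND_PROPERTY = "oborel:kind"


class OboFormatError(ValueError):
    """The input is not well-formed in the supported OBO subset."""


class SidecarError(ValueError):
    """The instance sidecar is malformed."""


@dataclass
class OboTerm:
    id: str
    name: str = ""
    is_a: list[str] = field(default_factory=list)
    relationships: list[tuple[str, str]] = field(default_factory=list)
    is_obsolete: bool = False
    kind: EntityKind = EntityKind.UNKNOWN
    #: Uninterpreted tag lines, preserved verbatim in input order.
    other_lines: list[str] = field(default_factory=list)


@dataclass
class OboDocument:
    header: list[str] = field(default_factory=list)
    terms: list[OboTerm] = field(default_factory=list)


_COMMENT_RE = re.compile(r"\s*!.*$")
_QUALIFIER_RE = re.compile(r"\s*\{[^}]*\}\s*$")

_KNOWN_TAGS = {"id", "name", "is_a", "relationship", "is_obsolete", "property_value"}


def _strip_trailers(value: str) -> str:
    value = _COMMENT_RE.sub("", value)
    value = _QUALIFIER_RE.sub("", value)
    return value.strip()


def parse_obo(source: str | TextIO) -> OboDocument:
    """Parse an OBO character stream into a document.

    Accepts LF or CRLF line endings.  Raises :class:`OboFormatError` on
    duplicate term ids, terms without an id, or relationship lines missing
    a target.  Non-``[Term]`` stanzas are ignored.
    """
    text = source if isinstance(source, str) else source.read()
    doc = OboDocument()
    term: OboTerm | None = None
    in_term_stanza = False
    in_header = True
    seen_ids: set[str] = set()
    pending: list[str] = []  # lines of the current stanza before its id

    def finish() -> None:
        nonlocal term, pending
        if in_term_stanza:
            if term is None:
                if any(line for line in pending):
                    raise OboFormatError("[Term] stanza without an id tag")
            else:
                doc.terms.append(term)
        term = None
        pending = []

    for raw in text.splitlines():
        line = raw.rstrip("\r").rstrip("\n")
        stripped = line.strip()
        if stripped.startswith("[") and stripped.endswith("]"):
            finish()
            in_header = False
            in_term_stanza = stripped == "[Term]"
            continue
        if not stripped or stripped.startswith("!"):
            continue
        if in_header:
            doc.header.append(stripped)
            continue
        if not in_term_stanza:
            continue
        if ":" not in stripped:
            raise OboFormatError(f"malformed tag line: {line!r}")
        tag, _, value = stripped.partition(":")
        tag = tag.strip()
        value = value.strip()
        if tag == "id":
            tid = _strip_trailers(value)
            if tid in seen_ids:
                raise OboFormatError(f"duplicate term id {tid!r}")
            seen_ids.add(tid)
            term = OboTerm(id=tid)
            term.other_lines.extend(pending)
            pending = []
            continue
        target = term if term is not None else None

        def keep(line_text: str) -> None:
            if target is None:
                pending.append(line_text)
            else:
                target.other_lines.append(line_text)

        if term is None and tag in _KNOWN_TAGS and tag != "id":
            # tags appearing before id: preserve order, interpret after id
            pending.append(stripped)
            continue
        if tag == "name":
            term.name = _strip_trailers(value)
        elif tag == "is_a":
            tgt = _strip_trailers(value)
            if not tgt:
                raise OboFormatError(f"is_a line without a target: {line!r}")
            term.is_a.append(tgt)
        elif tag == "relationship":
            body = _strip_trailers(value)
            parts = body.split(None, 1)
            if len(parts) != 2 or not parts[1].strip():
                raise OboFormatError(
                    f"relationship line without a target: {line!r}"
                )
            term.relationships.append(
                (normalize_relation_name(parts[0]), parts[1].strip())
            )
        elif tag == "is_obsolete":
            term.is_obsolete = _strip_trailers(value).lower() == "true"
        elif tag == "property_value":
            body = _strip_trailers(value)
            parts = body.split()
            if len(parts) >= 2 and parts[0] == KIND_PROPERTY:
                kind_name = parts[1].strip().strip('"').lower()
                try:
                    kind = EntityKind(kind_name)
                except ValueError:
                    raise OboFormatError(
                        f"unknown {KIND_PROPERTY} value {parts[1]!r}"
                    ) from None
                if not kind.declarable:
                    raise OboFormatError(
                        f"{KIND_PROPERTY} must be a declarable kind, "
                        f"got {kind_name!r}"
                    )
                term.kind = kind
            else:
                keep(stripped)
        else:
            keep(stripped)
    finish()
    return doc


def to_model(
    doc: OboDocument,
    kind_annotations: dict[str, EntityKind] | None = None,
) -> OntologyModel:
    """Build an :class:`OntologyModel` from a parsed document.

    ``kind_annotations`` overrides/augments in-file kind annotations per
    term id.  Relationship names outside the canonical inventory become
    unconstrained extension assertions; dangling targets are skipped.  Both
    situations are recorded as strings in ``model.metadata['parse_warnings']``
    rather than raised — loading a real OBO fragment must be total.
    """
    warnings: list[str] = []
    model = OntologyModel()
    model.metadata["header"] = list(doc.header)
    for term in doc.terms:
        kind = term.kind
        if kind_annotations and term.id in kind_annotations:
            kind = kind_annotations[term.id]
        model.add_class(
            EntityClass(term.id, term.name, kind, term.is_obsolete)
        )
        if term.other_lines:
            model.metadata.setdefault("term_extras", {})[term.id] = list(
                term.other_lines
            )
    for term in doc.terms:
        for target in term.is_a:
            if not model.has_class(target):
                warnings.append(
                    f"{term.id}: is_a target {target!r} not in document; skipped"
                )
                continue
            _add_unique(model, "is_a", term.id, target, warnings)
        for rel_name, target in term.relationships:
            if not model.has_class(target):
                warnings.append(
                    f"{term.id}: relationship {rel_name} target {target!r} "
                    "not in document; skipped"
                )
                continue
            kind_obj = extension_relation(rel_name)
            if kind_obj.is_extension:
                warnings.append(
                    f"{term.id}: relationship {rel_name!r} is not in the "
                    "relation inventory; loaded as unconstrained extension"
                )
            _add_unique(model, rel_name, term.id, target, warnings)
    model.metadata["parse_warnings"] = warnings
    return model


def _add_unique(
    model: OntologyModel,
    rel_name: str,
    source: str,
    target: str,
    warnings: list[str],
) -> None:
    if model.has_relation(normalize_relation_name(rel_name), source, target):
        warnings.append(
            f"duplicate assertion {rel_name}({source} -> {target}); kept once"
        )
        return
    model.add_relation(
        RelationAssertion(extension_relation(rel_name), source, target)
    )


def model_to_document(model: OntologyModel) -> OboDocument:
    """Serialize a model back into a document (stanzas sorted by id)."""
    header = model.metadata.get("header")
    if not header:
        header = ["format-version: 1.2"]
    extras = model.metadata.get("term_extras", {})
    doc = OboDocument(header=list(header))
    for cls in sorted(model.classes, key=lambda c: c.id):
        term = OboTerm(
            id=cls.id,
            name=cls.name,
            is_obsolete=cls.obsolete,
            kind=cls.declared_kind if cls.declared_kind.declarable else EntityKind.UNKNOWN,
            other_lines=list(extras.get(cls.id, [])),
        )
        for rel in sorted(
            model.relations_from(cls.id), key=lambda r: (r.kind.name, r.target_id)
        ):
            if rel.kind.name == "is_a":
                term.is_a.append(rel.target_id)
            else:
                term.relationships.append((rel.kind.name, rel.target_id))
        doc.terms.append(term)
    return doc


def write_obo(model: OntologyModel, stream: TextIO | None = None) -> str:
    """Write a model as OBO text (deterministic order, LF endings).

    Declared kinds are emitted as ``property_value: oborel:kind <kind>``
    lines so that ``to_model(parse_obo(write_obo(m)))`` reproduces ``m``.
    """
    doc = model_to_document(model)
    out = io.StringIO()
    for line in doc.header:
        out.write(line + "\n")
    for term in doc.terms:
        out.write("\n[Term]\n")
        out.write(f"id: {term.id}\n")
        if term.name:
            out.write(f"name: {term.name}\n")
        if term.kind.declarable:
            out.write(f"property_value: {KIND_PROPERTY} {term.kind.value}\n")
        for target in term.is_a:
            out.write(f"is_a: {target}\n")
        for rel_name, target in term.relationships:
            out.write(f"relationship: {rel_name} {target}\n")
        if term.is_obsolete:
            out.write("is_obsolete: true\n")
        for line in term.other_lines:
            out.write(line + "\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def load_model(path: str) -> OntologyModel:
    """Parse an OBO file from disk into a model."""
    with open(path, "r", encoding="utf-8") as fh:
        return to_model(parse_obo(fh))


# -- instance sidecar ----------------------------------------------------

SIDECAR_VERSION = 1


def parse_instance_data(
    source: str | TextIO,
) -> tuple[list[InstanceSpec], list[tuple[str, str, str]]]:
    """Parse the YAML instance sidecar.

    Returns instance specs and raw (relation, source, target) link triples;
    resolution against a model happens in :func:`apply_instance_data`.
    """
    data = yaml.safe_load(source if isinstance(source, str) else source.read())
    if not isinstance(data, dict):
        raise SidecarError("instance sidecar must be a mapping")
    version = data.get("version", SIDECAR_VERSION)
    if version != SIDECAR_VERSION:
        raise SidecarError(f"unsupported sidecar version {version!r}")
    instances = []
    for row in data.get("instances", []) or []:
        try:
            instances.append(InstanceSpec(str(row["id"]), str(row["instance_of"])))
        except (TypeError, KeyError) as exc:
            raise SidecarError(f"malformed instance entry {row!r}") from exc
    links = []
    for row in data.get("links", []) or []:
        try:
            links.append(
                (
                    normalize_relation_name(str(row["relation"])),
                    str(row["source"]),
                    str(row["target"]),
                )
            )
        except (TypeError, KeyError) as exc:
            raise SidecarError(f"malformed link entry {row!r}") from exc
    return instances, links


def apply_instance_data(model: OntologyModel, source: str | TextIO) -> OntologyModel:
    """Load a sidecar's instances and links into a model (in place)."""
    instances, links = parse_instance_data(source)
    for spec in instances:
        model.add_instance(spec)
    for rel_name, src, tgt in links:
        model.add_link(InstanceLink(extension_relation(rel_name), src, tgt))
    return model
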
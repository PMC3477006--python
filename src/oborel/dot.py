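"""Deterministic DOT export with the profile's notational conventions.

Nodes are entity classes labeled with their name and stereotype
(``<<material>>`` etc.).  Following the profile's UML-flavoured notation:
is_a edges render as generalizations (hollow-triangle arrowhead), the
part_of family as shared aggregation (open diamond at the whole end), and
every other relation as a labeled directed edge.
"""

from __future__ import annotations

from .model import OntologyModel

__all__ = ["to_dot"]

_PART_OF_FAMILY = {"part_of", "proper_part_of", "integral_part_of"}
_HAS_PART_FAMILY = {"has_part", "has_proper_part", "has_integral_part"}


def _quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def to_dot(model: OntologyModel) -> str:
    """Render a model as DOT text; byte-identical across runs.

    Nodes are sorted by id and edges by (relation, source, target).
    """
    lines = [
        "digraph ontology {",
        "  rankdir=BT;",
        '  node [shape=box, fontname="Helvetica"];',
    ]
    for cls in sorted(model.classes, key=lambda c: c.id):
        label = cls.name or cls.id
        if cls.declared_kind.declarable:
            label += f"\\n<<{cls.declared_kind.value}>>"
        attrs = [f"label={_quote(label)}"]
        if cls.obsolete:
            attrs.append("style=dashed")
        lines.append(f"  {_quote(cls.id)} [{', '.join(attrs)}];")
    for rel in sorted(model.relations, key=lambda r: r.triple):
        name = rel.kind.name
        edge = f"  {_quote(rel.source_id)} -> {_quote(rel.target_id)}"
        if name == "is_a":
            lines.append(f"{edge} [arrowhead=onormal];")
        elif name in _PART_OF_FAMILY:
            # the whole (target) end carries the open diamond
            lines.append(
                f'{edge} [arrowhead=odiamond, label={_quote("<<" + name + ">>")}];'
            )
        elif name in _HAS_PART_FAMILY:
            # whole is the source: diamond at the tail
            lines.append(
                f"{edge} [dir=both, arrowtail=odiamond, arrowhead=vee, "
                f'label={_quote("<<" + name + ">>")}];'
            )
        else:
            lines.append(f'{edge} [label={_quote("<<" + name + ">>")}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
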
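"""Packaged worked-example fragments and a random model generator.

Four small ontology fragments ship with the package so every engine is
exercisable without downloads:

* ``pro_fragment`` — a PRotein Ontology excerpt around TGF-Beta 1: six
  material continuants linked by is_a and derives_from (proteolytic
  cleavage products derive from the proteins they are cleaved from).
* ``xao_fragment`` — a Xenopus developmental-stage excerpt: ten processes
  linked by is_a, part_of (NF stages 7-9 are parts of the Blastula range)
  and preceded_by (stage succession).
* ``go_root_fragment`` — the historical "Gene Ontology" root term with its
  three branches attached by is_a; the root is typeable neither as a
  continuant nor as a process and is the canonical unsatisfiable concept.
* ``go_mi_fragment`` — a Gene Ontology process fragment exhibiting
  multiple inheritance and a relation-embedded term name
  ("Cell-Cell Signaling Involved in Cell Fate Commitment").

Term ids are synthetic stable strings (``PRO:FIX01`` ...): the sources the
fragments are drawn from print labels, not accessions.  The same fragments
are also shipped as OBO files (``oborel.fixtures.fixture_path``).

``random_model`` generates reproducible models with a controlled fraction
of deliberately planted constraint violations (exactly one named rule per
violating assertion) and returns the ground truth alongside, for
benchmarking the validator.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources

from .constraints import Mode, valid_kind_pairs
from .kinds import DECLARABLE_KINDS, EntityKind
from .model import EntityClass, OntologyModel, RelationAssertion, build_model
from .relations import get_relation, relation_registry

__all__ = [
    "pro_fragment",
    "xao_fragment",
    "go_root_fragment",
    "go_mi_fragment",
    "fixture_path",
    "FIXTURE_NAMES",
    "PlantedModel",
    "GenerationError",
    "random_model",
]

P = EntityKind.PROCESS
C = EntityKind.CONTINUANT
M = EntityKind.MATERIAL
I = EntityKind.IMMATERIAL

FIXTURE_NAMES = ("pro_fragment", "xao_fragment", "go_root_fragment", "go_mi_fragment")


def _model(
    prefix: str,
    kind: EntityKind | None,
    names: list[str | tuple[str, EntityKind]],
    edges: list[tuple[str, str, str]],
) -> OntologyModel:
    classes = []
    ids: dict[str, str] = {}
    for i, entry in enumerate(names, start=1):
        if isinstance(entry, tuple):
            name, k = entry
        else:
            name, k = entry, kind
        cid = f"{prefix}:FIX{i:02d}"
        ids[name] = cid
        classes.append(EntityClass(cid, name, k))
    relations = [
        RelationAssertion(get_relation(rel), ids[src], ids[tgt])
        for rel, src, tgt in edges
    ]
    return build_model(classes, relations)


def pro_fragment() -> OntologyModel:
    """PRotein Ontology fragment: 6 material continuants, 4 is_a + 2
    derives_from."""
    return _model(
        "PRO",
        M,
        [
            "TGF-Beta",
            "TGF-Beta 1",
            "Proteolytic Cleavage Product",
            "TGF-Beta 1 Proteolytic Cleavage Product",
            "TGF-Beta 1 Isoform 1",
            "TGF-Beta 1 Isoform 1 Cleaved 1",
        ],
        [
            ("is_a", "TGF-Beta 1", "TGF-Beta"),
            ("is_a", "TGF-Beta 1 Proteolytic Cleavage Product",
             "Proteolytic Cleavage Product"),
            ("derives_from", "TGF-Beta 1 Proteolytic Cleavage Product",
             "TGF-Beta 1"),
            ("is_a", "TGF-Beta 1 Isoform 1", "TGF-Beta 1"),
            ("is_a", "TGF-Beta 1 Isoform 1 Cleaved 1",
             "TGF-Beta 1 Proteolytic Cleavage Product"),
            ("derives_from", "TGF-Beta 1 Isoform 1 Cleaved 1",
             "TGF-Beta 1 Isoform 1"),
        ],
    )


def xao_fragment() -> OntologyModel:
    """Xenopus developmental-stage fragment: 10 processes, 6 is_a +
    3 part_of + 2 preceded_by."""
    return _model(
        "XAO",
        P,
        [
            "Xenopus Developmental Stage",
            "Unfertilized Egg",
            "Embryonic Stage",
            "Adult",
            "Death",
            "Blastula",
            "Neurula",
            "NF Stage 7",
            "NF Stage 8",
            "NF Stage 9",
        ],
        [
            ("is_a", "Unfertilized Egg", "Xenopus Developmental Stage"),
            ("is_a", "Embryonic Stage", "Xenopus Developmental Stage"),
            ("is_a", "Adult", "Xenopus Developmental Stage"),
            ("is_a", "Death", "Xenopus Developmental Stage"),
            ("is_a", "Blastula", "Embryonic Stage"),
            ("is_a", "Neurula", "Embryonic Stage"),
            ("part_of", "NF Stage 7", "Blastula"),
            ("part_of", "NF Stage 8", "Blastula"),
            ("part_of", "NF Stage 9", "Blastula"),
            ("preceded_by", "NF Stage 8", "NF Stage 7"),
            ("preceded_by", "NF Stage 9", "NF Stage 8"),
        ],
    )


def go_root_fragment() -> OntologyModel:
    """The historical Gene Ontology root with its three branches.

    The root is untyped; its Biological Process and Molecular Function
    subclasses are processes while Cellular Component is a continuant, so
    kind inference drives the root to BOTTOM — an unsatisfiable concept.
    """
    return _model(
        "GO",
        None,
        [
            ("Gene Ontology", EntityKind.UNKNOWN),
            ("Biological Process", P),
            ("Cellular Component", C),
            ("Molecular Function", P),
        ],
        [
            ("is_a", "Biological Process", "Gene Ontology"),
            ("is_a", "Cellular Component", "Gene Ontology"),
            ("is_a", "Molecular Function", "Gene Ontology"),
        ],
    )


def go_mi_fragment() -> OntologyModel:
    """Gene Ontology process fragment (August-2011 structure) with two
    multiple-inheritance sites and one relation-embedded term name."""
    return _model(
        "GO",
        P,
        [
            "Developmental Process",
            "Cellular Process",
            "Cellular Developmental Process",
            "Cell Communication",
            "Signaling",
            "Cell-Cell Signaling",
            "Cell Fate Commitment",
            "Cell-Cell Signaling Involved in Cell Fate Commitment",
        ],
        [
            ("is_a", "Cellular Developmental Process", "Developmental Process"),
            ("is_a", "Cellular Developmental Process", "Cellular Process"),
            ("is_a", "Cell-Cell Signaling", "Cell Communication"),
            ("is_a", "Cell-Cell Signaling", "Signaling"),
            ("is_a", "Cell-Cell Signaling Involved in Cell Fate Commitment",
             "Cell-Cell Signaling"),
            ("part_of", "Cell-Cell Signaling Involved in Cell Fate Commitment",
             "Cell Fate Commitment"),
        ],
    )


def fixture_path(name: str):
    """Filesystem path of a shipped fixture OBO file (context-manager-free
    for a regular installed package)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(name)
    return resources.files("oborel").joinpath("data", f"{name}.obo")


# -- random generator ----------------------------------------------------


class GenerationError(RuntimeError):
    """The requested model cannot be generated (e.g. no class of a kind a
    violation template requires)."""


@dataclass
class PlantedModel:
    """A generated model with its planted ground truth."""

    model: OntologyModel
    #: (rule_id, (relation, source, target)) per deliberately violating
    #: assertion — exactly what STRICT validation must recover.
    planted_issues: list[tuple[str, tuple[str, str, str]]]
    seed: int


# Violation templates, curated so each yields exactly ONE STRICT error of
# the named rule and no other issue.  (relation, source kind, target kind);
# IRREFLEXIVE templates reuse one class for both ends.
_VIOLATION_TEMPLATES: dict[str, list[tuple[str, EntityKind, EntityKind]]] = {
    "ENDPOINT_KIND": [
        ("has_agent", P, I),
        ("contained_in", M, M),
        ("contained_in", I, I),
        ("derives_from", M, I),
        ("preceded_by", P, C),
        ("has_participant", P, P),
        ("participates_in", C, C),
        ("located_in", P, C),
        ("agent_in", I, P),
    ],
    "SAME_BRANCH": [
        ("part_of", P, C),
        ("part_of", C, P),
        ("part_of", P, M),
        ("part_of", I, P),
        ("has_part", P, C),
        ("has_part", C, P),
        ("has_part", M, P),
        ("has_part", P, I),
        ("is_a", P, C),
        ("is_a", C, P),
        ("is_a", P, M),
        ("is_a", M, P),
        ("is_a", P, I),
        ("is_a", I, P),
        ("proper_part_of", P, C),
        ("proper_part_of", P, M),
    ],
    "CONDITIONAL_KIND": [
        ("part_of", M, C),
        ("part_of", C, I),
        ("has_part", C, M),
        ("has_part", I, C),
        ("is_a", M, C),
        ("is_a", C, I),
        ("is_a", I, M),
        ("is_a", M, I),
    ],
    "IRREFLEXIVE": [
        ("proper_part_of", P, P),
        ("proper_part_of", C, C),
        ("proper_part_of", M, M),
        ("has_proper_part", I, I),
        ("has_proper_part", M, M),
    ],
}

#: Class-level relations the conforming sampler draws from.  The integral
#: variants are excluded so conforming assertions are clean even of
#: RECIPROCITY warnings.
_CONFORMING_KINDS = tuple(
    k
    for k in relation_registry()
    if k.is_association or k.name == "is_a"
    if k.name not in ("integral_part_of", "has_integral_part")
)


def random_model(
    n_classes: int,
    n_relations: int,
    violation_rate: float,
    seed: int,
) -> PlantedModel:
    """Generate a reproducible model with planted constraint violations.

    Class kinds are sampled uniformly from the four declarable kinds.  Each
    assertion is either *conforming* (its endpoint kinds drawn from the
    relation's valid kind pairs, hence zero STRICT issues) or, with
    probability ``violation_rate``, *violating* exactly one named rule.
    The planted ground truth lists every violation inserted; STRICT
    validation recovers it exactly, by construction.
    """
    if n_classes < 2:
        raise GenerationError("need at least 2 classes")
    if not 0.0 <= violation_rate <= 1.0:
        raise GenerationError("violation_rate must be in [0, 1]")
    rng = random.Random(seed)

    classes = [
        EntityClass(f"RND:{i:04d}", f"random class {i}", rng.choice(DECLARABLE_KINDS))
        for i in range(n_classes)
    ]
    pools: dict[EntityKind, list[str]] = {k: [] for k in DECLARABLE_KINDS}
    for cls in classes:
        pools[cls.declared_kind].append(cls.id)

    model = build_model(classes)
    planted: list[tuple[str, tuple[str, str, str]]] = []
    used: set[tuple[str, str, str]] = set()

    valid_cache = {
        kind.name: sorted(
            valid_kind_pairs(kind, Mode.STRICT),
            key=lambda p: (p[0].value, p[1].value),
        )
        for kind in _CONFORMING_KINDS
    }

    def pick_pair(rel_name: str, sk: EntityKind, tk: EntityKind, distinct: bool):
        src_pool, tgt_pool = pools[sk], pools[tk]
        if not src_pool or not tgt_pool:
            return None
        for _ in range(200):
            s = rng.choice(src_pool)
            t = rng.choice(tgt_pool)
            if distinct and s == t:
                continue
            if (rel_name, s, t) in used:
                continue
            return s, t
        return None

    for _ in range(n_relations):
        if rng.random() < violation_rate:
            # prefer a uniformly chosen rule, but fall back to any other
            # plantable rule before giving up (a class-kind draw may lack
            # e.g. processes, making SAME_BRANCH inherently unplantable)
            rule_order = sorted(_VIOLATION_TEMPLATES)
            rng.shuffle(rule_order)
            placed = False
            for rule_id in rule_order:
                templates = list(_VIOLATION_TEMPLATES[rule_id])
                rng.shuffle(templates)
                for rel_name, sk, tk in templates:
                    if rule_id == "IRREFLEXIVE":
                        candidates = [(c, c) for c in pools[sk]]
                        rng.shuffle(candidates)
                        pair = next(
                            (
                                p
                                for p in candidates
                                if (rel_name, p[0], p[1]) not in used
                            ),
                            None,
                        )
                    else:
                        pair = pick_pair(rel_name, sk, tk, distinct=True)
                    if pair is None:
                        continue
                    triple = (rel_name, pair[0], pair[1])
                    model.add_relation(
                        RelationAssertion(get_relation(rel_name), pair[0], pair[1])
                    )
                    used.add(triple)
                    planted.append((rule_id, triple))
                    placed = True
                    break
                if placed:
                    break
            if not placed:
                raise GenerationError(
                    "cannot plant a violation with the available class kinds"
                )
        else:
            placed = False
            for _ in range(200):
                kind = rng.choice(_CONFORMING_KINDS)
                rule_irreflexive = kind.name in ("proper_part_of", "has_proper_part")
                pairs = [
                    (sk, tk)
                    for sk, tk in valid_cache[kind.name]
                    if pools[sk] and pools[tk]
                    and not (
                        rule_irreflexive and sk is tk and len(pools[sk]) < 2
                    )
                ]
                if not pairs:
                    continue
                sk, tk = rng.choice(pairs)
                pair = pick_pair(kind.name, sk, tk, distinct=rule_irreflexive)
                if pair is None:
                    continue
                model.add_relation(RelationAssertion(kind, pair[0], pair[1]))
                used.add((kind.name, *pair))
                placed = True
                break
            if not placed:
                raise GenerationError("cannot place a conforming assertion")
    return PlantedModel(model=model, planted_issues=planted, seed=seed)
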
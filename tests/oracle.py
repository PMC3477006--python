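"""Independent brute-force evaluator of the relation endpoint rules.

This module re-states the constraint semantics from scratch as literal
data and small predicates over the four declarable kinds.  It deliberately
imports nothing from the engine under test: agreement between the two is
the point of the oracle-equivalence tests.
"""

PROCESS = "process"
CONTINUANT = "continuant"
MATERIAL = "material"
IMMATERIAL = "immaterial"
KINDS = (PROCESS, CONTINUANT, MATERIAL, IMMATERIAL)

_CONTINUANTS = {CONTINUANT, MATERIAL, IMMATERIAL}


def below(a: str, b: str) -> bool:
    """a is at-or-below b: material/immaterial are kinds of continuant."""
    return a == b or (b == CONTINUANT and a in _CONTINUANTS)


# relation -> (source bound, target bound, same-branch?, conditionals,
# is_a parity?).  Conditionals: (antecedent end, antecedent kind,
# consequent kind) meaning "if that end is the antecedent kind, the other
# end must be the consequent kind".
RULES: dict[str, tuple] = {
    "is_a": (None, None, True, (), True),
    "part_of": (
        None, None, True,
        (("src", MATERIAL, MATERIAL), ("tgt", IMMATERIAL, IMMATERIAL)),
        False,
    ),
    "proper_part_of": (
        None, None, True,
        (("src", MATERIAL, MATERIAL), ("tgt", IMMATERIAL, IMMATERIAL)),
        False,
    ),
    "integral_part_of": (
        None, None, True,
        (("src", MATERIAL, MATERIAL), ("tgt", IMMATERIAL, IMMATERIAL)),
        False,
    ),
    "has_part": (
        None, None, True,
        (("tgt", MATERIAL, MATERIAL), ("src", IMMATERIAL, IMMATERIAL)),
        False,
    ),
    "has_proper_part": (
        None, None, True,
        (("tgt", MATERIAL, MATERIAL), ("src", IMMATERIAL, IMMATERIAL)),
        False,
    ),
    "has_integral_part": (
        None, None, True,
        (("tgt", MATERIAL, MATERIAL), ("src", IMMATERIAL, IMMATERIAL)),
        False,
    ),
    "located_in": (CONTINUANT, CONTINUANT, False, (), False),
    "location_of": (CONTINUANT, CONTINUANT, False, (), False),
    "adjacent_to": (CONTINUANT, CONTINUANT, False, (), False),
    "contained_in": (MATERIAL, IMMATERIAL, False, (), False),
    "contains": (IMMATERIAL, MATERIAL, False, (), False),
    "derives_from": (MATERIAL, MATERIAL, False, (), False),
    "derived_into": (MATERIAL, MATERIAL, False, (), False),
    "transformation_of": (MATERIAL, MATERIAL, False, (), False),
    "preceded_by": (PROCESS, PROCESS, False, (), False),
    "precedes": (PROCESS, PROCESS, False, (), False),
    "has_participant": (PROCESS, CONTINUANT, False, (), False),
    "participates_in": (CONTINUANT, PROCESS, False, (), False),
    "has_agent": (PROCESS, MATERIAL, False, (), False),
    "agent_in": (MATERIAL, PROCESS, False, (), False),
}


def pair_valid(relation: str, src: str, tgt: str) -> bool:
    """Strict validity of a (source kind, target kind) pair for a relation,
    assuming two distinct, fully stereotyped endpoint classes."""
    sbound, tbound, same_branch, conds, parity = RULES[relation]
    if sbound is not None and not below(src, sbound):
        return False
    if tbound is not None and not below(tgt, tbound):
        return False
    if same_branch:
        src_proc, tgt_proc = src == PROCESS, tgt == PROCESS
        if src_proc != tgt_proc:
            return False
    if parity and src in _CONTINUANTS and tgt in _CONTINUANTS and src != tgt:
        return False
    for end, ante, cons in conds:
        a, other = (src, tgt) if end == "src" else (tgt, src)
        if below(a, ante) and not below(other, cons):
            return False
    return True


def valid_pairs(relation: str) -> set[tuple[str, str]]:
    return {
        (s, t) for s in KINDS for t in KINDS if pair_valid(relation, s, t)
    }
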
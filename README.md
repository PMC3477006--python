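# oborel

Executable tooling for the **OBO Relation Ontology profile**: a typed
ontology-graph model, a constraint engine for the relation inventory's
endpoint rules, a kind-inference engine that detects unsatisfiable
concepts, lint rules for common ontology defects, and OBO flat-file I/O.

## The problem

Biomedical ontologies curated in the OBO Foundry (GO, PRO, XAO, ...) link
their terms with the relations of the OBO Relation Ontology — `is_a`,
`part_of`, `derives_from`, `preceded_by`, `has_participant` and so on —
but the OBO flat file format has no slot for the ontological
classification those relations presuppose.  Every entity class is either a
**continuant** (things: cell, DNA, hemoglobin) or a **process**
(activities: a developmental stage), and continuants subdivide into
**material** and **immaterial** (cavities, lumina).  Each relation
constrains the kinds of classes it may connect: `has_agent` links a
process to a *material* continuant; `preceded_by` links two processes; a
*material* part can only be part of a *material* whole, while an
*immaterial* part may sit in either.  Because plain OBO terms are untyped,
these constraints are enforced only by curators' tacit knowledge — which
is exactly where inconsistencies creep in.

`oborel` makes the discipline executable, for ontology curators and
tool builders:

* a **kind lattice** `UNKNOWN ⊐ {PROCESS, CONTINUANT}`,
  `CONTINUANT ⊐ {MATERIAL, IMMATERIAL}`, with `BOTTOM` marking
  contradiction; disjointness of branches is the meet `a ∧ b = ⊥`;
* the **22-relation inventory** (8 foundational, 5 spatial, 5 temporal,
  4 participation) with inverse pairings and per-relation endpoint rules;
* a **validator** (strict and lenient modes) reporting rule-tagged issues
  (`ENDPOINT_KIND`, `SAME_BRANCH`, `CONDITIONAL_KIND`, `IRREFLEXIVE`, ...),
  plus the instance-level *all/some* check: a class-level `R(C, C₁)`
  promises every instance of `C` an `R`-link to some instance of `C₁`;
* **kind inference**: fixpoint propagation of the constraints as meets
  over the graph; a class driven to `⊥` is an *unsatisfiable concept*
  (the historical "Gene Ontology" root term is the canonical example);
* **lint**: multiple-inheritance detection with `contributes_to`
  replacement suggestions, and "X involved in Y" term names that embed a
  relation between two other terms;
* **OBO I/O** with kind annotations (`property_value: oborel:kind ...`)
  so that parse ∘ write is the identity, and deterministic DOT export in
  the profile's UML-flavoured notation.

## Worked example

The package ships four in-memory fragments (also as OBO files under
`oborel/data/`).  Inferring kinds over the historical Gene Ontology root —
whose three branches were once attached to a "Gene Ontology" term by
`is_a` — detects that the root cannot be typed:

```text
$ oborel infer src/oborel/data/go_root_fragment.obo
inferred kinds:
  GO:FIX01: bottom
  GO:FIX02: process
  GO:FIX03: continuant
  GO:FIX04: process
unsatisfiable classes:
  GO:FIX01
    - GO:FIX01: unknown -> process (subtype kind via is_a(GO:FIX02 -> GO:FIX01))
    - GO:FIX01: process -> bottom (subtype kind via is_a(GO:FIX03 -> GO:FIX01))
```

`is_a` may only connect two continuants or two processes, so the root
(`GO:FIX01`) is narrowed to *process* by its Biological Process subclass
and then to `bottom` by the Cellular Component subclass — an invalid
concept, with the narrowing chain as the explanation.  The contradiction
stays at the root; the branches keep their own kinds.  Exit status is 1
because an unsatisfiable class was found.

Validating the TGF-Beta protein fragment (six material continuants,
`is_a` + `derives_from`) and computing usage statistics on the Xenopus
developmental-stage fragment (ten processes related by `is_a`, `part_of`
and `preceded_by`):

```text
$ oborel validate src/oborel/data/pro_fragment.obo
validation (strict mode): 0 error(s), 0 warning(s)

$ oborel stats src/oborel/data/xao_fragment.obo --subset is_a,part_of
relation usage (11 assertion(s)):
  is_a                 6
  part_of              3
  preceded_by          2
subset {is_a, part_of}: 9/11 = 0.8182
```

The same functionality is available as a library:

```python
from oborel import valid_kind_pairs, validate_model, Mode
from oborel.fixtures import pro_fragment

len(valid_kind_pairs("part_of"))          # 7 of the 16 kind pairs are valid
validate_model(pro_fragment(), Mode.STRICT).errors   # []
```

Other subcommands: `oborel lint` (multiple inheritance, embedded relation
names), `oborel export-dot` (deterministic GraphViz text), `oborel gen`
(random models with planted, ground-truthed violations), each with
`--format json` and an optional YAML instance sidecar via `--instances`.

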
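# Methods

## The kind lattice

Entity classes are classified on a six-value meet-semilattice:

```
            UNKNOWN
            /     \
      PROCESS   CONTINUANT
                /        \
          MATERIAL    IMMATERIAL
             \    \    /    /
              ---BOTTOM----
```

`UNKNOWN` (top) is the state of an unstereotyped OBO term — it could still
be anything.  `BOTTOM` encodes contradiction.  The four interior values are
the declarable kinds.  Mutual exclusivity of process/continuant and of
material/immaterial is realised as the meet: incomparable kinds meet at
`BOTTOM`.  `kind_satisfies(a, b)` (a is at or below b) is equivalent to
`kind_meet(a, b) == a`, which the tests assert exhaustively.

The formal literature indexes instantiation by time ("c instantiates C at
time t"); this model is time-free.  Nothing in the structural checks below
depends on the time parameter, but relations whose full semantics is
temporal-identity-based (`transformation_of`) are only checked for their
endpoint kinds.

## Relation inventory and endpoint rules

The registry holds exactly the 22 canonical relations, partitioned
8 foundational / 5 spatial / 5 temporal / 4 participation, with nine
involutive inverse pairs (`part_of`↔`has_part`, `located_in`↔`location_of`,
`contained_in`↔`contains`, `derives_from`↔`derived_into`,
`preceded_by`↔`precedes`, `has_participant`↔`participates_in`,
`has_agent`↔`agent_in`, and the proper/integral part variants).
Hyphenated spellings (`derives-from`) are normalized to underscores on
input; underscores are emitted.  `instance_of` is the single
instance-to-class relation; everything else is class-level.

Each relation carries a `KindConstraint`:

| relation family | source bound | target bound | coupling |
| --- | --- | --- | --- |
| `is_a` | — | — | same branch + specification parity |
| `part_of` family | — | — | same branch + material/immaterial conditionals |
| `located_in`, `location_of`, `adjacent_to` | continuant | continuant | — |
| `contained_in` / `contains` | material / immaterial | immaterial / material | — |
| `derives_from`, `derived_into`, `transformation_of` | material | material | — |
| `preceded_by`, `precedes` | process | process | — |
| `has_participant` / `participates_in` | process / continuant | continuant / process | — |
| `has_agent` / `agent_in` | process / material | material / process | — |

The `part_of` conditionals are: a material part implies a material whole;
an immaterial whole implies immaterial parts.  (An immaterial part may sit
in a material whole.)  The `has_part` family mirrors them — inversion is
the only reading consistent with `has_part` being the inverse of
`part_of`.  The proper variants are irreflexive; the integral variants
expect a reciprocal whole-side assertion.  The location family carries no
material/immaterial restriction; only containment is material-specific.

**is_a specification parity.**  Within the continuant branch, the two ends
of an `is_a` must carry the *same* level of specification:
continuant–continuant, material–material, immaterial–immaterial.  A
material class specializing a bare continuant is flagged in strict mode.
This is the stricter of two defensible readings (the other would allow a
specified subtype under an unspecified supertype); it is the one this
package enforces, and the lenient mode effectively provides the other
(only material-vs-immaterial conflicts are flagged there).  Parity
violations are reported under `CONDITIONAL_KIND`; branch mismatches under
`SAME_BRANCH`, and when the branch rule fails the parity check is skipped
so one root cause yields one issue.

A literal consequence adopted deliberately: `part_of(continuant-unspecified,
material)` is valid — neither conditional's antecedent is established.

## Validation modes

* **STRICT** — the profile's intended regime: a declared kind must
  *satisfy* each bound (`declared ⊑ bound`).  Untyped (`UNKNOWN`)
  endpoints fail branch checks, and untyped non-obsolete classes get an
  `UNTYPED_CLASS` warning.
* **LENIENT** — for plain OBO inputs: a kind passes if it is still
  *refinable* to the bound (`meet(declared, bound) ≠ ⊥`).

Strict issues are always a superset of lenient issues (property-tested).
Rule ids form a closed set: `ENDPOINT_KIND`, `SAME_BRANCH`,
`CONDITIONAL_KIND`, `IRREFLEXIVE`, `UNTYPED_CLASS`, `RECIPROCITY`,
`ALL_SOME`, `UNSATISFIABLE_KIND`.  Errors are the first four plus
`ALL_SOME`; `UNTYPED_CLASS` and `RECIPROCITY` are warnings — the
reciprocal of an integral part relation is part of that relation's own
semantics, so its absence as an explicit assertion is advisory, not
inconsistent.  Reports order issues by (rule id, subject), making
validation insensitive to assertion insertion order.  Obsolete classes are
retained in models but excluded from validation, inference and lint.

The *all/some* checker evaluates class-level associations against instance
data: for `R(C, C₁)` every instance of `C` needs at least one `R`-link to
an instance of `C₁` (uncovered instances yield `ALL_SOME`); instance links
are additionally endpoint-checked against the kinds of their classes.
`is_a` is a generalization, not an association, and has no instance-level
link form.  Instance coverage uses direct instantiation only — there is no
closure over `is_a` at the instance layer, consistent with the time-free,
advisory scope of the checker.

## Kind inference

`infer_kinds` initializes every class to its declared kind and applies the
constraint table as meet operations until fixpoint: endpoint bounds narrow
an endpoint toward the bound; the same-branch coupling propagates a
resolved branch across part-whole edges (lazily — no case splitting, so
inference is polynomial but incomplete: a branch-ambiguous model stays
`UNKNOWN` rather than guessing); the conditionals fire once their
antecedent is established; and `is_a` meets each endpoint with the other's
kind (subtype and supertype share branch and specification under parity).

Propagation runs in *synchronous rounds*: all narrowing facts of a round
are derived from the previous round's kinds and folded in by meets.
Because meets commute, the inferred kinds are independent of assertion
order; because kinds only descend a finite lattice, at most
(#classes × lattice height) rounds run.  A class at `BOTTOM` emits no
facts to its neighbours: the contradiction is *its* diagnosis, and
flooding it outward would mark every connected class unsatisfiable.  This
is what localizes the "Gene Ontology"-root collapse to the root itself
while its branches keep their declared kinds.  Provenance records each
lattice descent with the assertion that caused it, giving a short
human-readable explanation chain per unsatisfiable class.

Inference only refines: the inferred kind is always at or below the
declaration, with contradiction surfacing as `BOTTOM` rather than a
silent reassignment.  It reports kinds; it never writes them back unless
`apply_assignment` is called explicitly.

## Fixture fragments

The four packaged fragments implement exactly the class and relation sets
documented above — deliberately small excerpts, not snapshots of any
ontology release.  Ids are synthetic stable strings (`PRO:FIX01`, ...)
because the fragments are identified by label in their sources.  Expected
behaviour, all asserted by tests:

* PRO fragment: 6 material classes, 4 `is_a` + 2 `derives_from`; strict
  validation is clean.
* XAO fragment: 10 process classes, 6 `is_a` + 3 `part_of` +
  2 `preceded_by`; clean.
* GO root: 4 classes, 3 `is_a`; exactly one unsatisfiable class.
* GO multiple-inheritance fragment: 8 process classes; 2
  multiple-inheritance findings, 1 embedded-name finding, 0 constraint
  errors (multiple inheritance is lint, not a violation).

## Random generator

`random_model(n_classes, n_relations, violation_rate, seed)` samples class
kinds uniformly from the four declarable kinds and emits each assertion
either *conforming* — endpoint kinds drawn from the relation's valid kind
pairs, so it contributes zero strict issues — or, with probability
`violation_rate`, *violating*.  Violations come from a curated template
table; every template has been verified to yield exactly one strict error
of its named rule, so the planted ground truth and the validator's error
list coincide element-for-element (precision = recall = 1.0, asserted over
many seeds).  At most one violation is planted per assertion.  The
conforming sampler excludes the integral part variants so conforming
models are warning-free too.  When a uniformly chosen violation rule is
unplantable with the sampled kind pools (e.g. `SAME_BRANCH` needs both
branches present), the generator falls back to another rule before
raising a generation error.  Ground truth is guaranteed under STRICT
validation; LENIENT may legitimately miss refinable violations — that is
the point of the mode split.

What the generator does *not* emulate about real ontologies: term-name
semantics (names are placeholders, so embedded-name lint is exercised on
the curated fragments instead), deep `is_a` hierarchies with inherited
constraints, instance data, and obsolete terms.  Passing the recovery
benchmark therefore demonstrates the validator's rule logic, not its
behaviour on the full messiness of a production ontology.

## OBO dialect

OBO 1.2-style subset: header plus `[Term]` stanzas with `id`, `name`,
`is_a`, `relationship`, `is_obsolete`.  All other tags are preserved
verbatim and re-emitted; trailing `! comments` and `{qualifier}` blocks on
interpreted lines are stripped; LF and CRLF are accepted, LF emitted;
identifiers are opaque strings (no CURIE expansion).  Kinds are serialized
as `property_value: oborel:kind <kind>` in a reserved namespace because
the format has no stereotype slot; parse ∘ write ∘ parse is the identity
on (classes, kinds, assertions), property-tested on random models.
Duplicate term ids and target-less relationship lines are format errors;
dangling targets and non-inventory relation names are *warnings* (recorded
in `model.metadata["parse_warnings"]`) so that loading real files is
total.  Non-inventory names (e.g. `regulates`, `contributes_to`,
`involved_in`) load as unconstrained extension relations — no endpoint
bounds are invented for them.

The instance sidecar is a small versioned YAML document
(`version` / `instances` / `links`); see `oborel.obo.parse_instance_data`.

## Reporting and DOT

JSON reports carry `schema_version: 1` and stable rule ids.  DOT export is
plain deterministic text: nodes sorted by id labeled `name\n<<kind>>`,
`is_a` as a hollow-triangle generalization (`arrowhead=onormal`), the
`part_of` family as shared aggregation with the open diamond at the whole
end (shared rather than composite aggregation — parts may outlive the
whole), all other relations as `<<name>>`-labeled edges.  Output is
byte-identical across runs on the same model.

CLI exit codes: 0 clean, 1 error-severity issues (or unsatisfiable classes
for `infer`), 2 on I/O or format failure.

## Problem sizes

The test-suite and acceptance-script benchmarks use models of 50 classes /
200 assertions over 20 seeds for recovery, and ~100 models of 12 classes /
30 assertions for round-trip checks — comfortably past the point where
the combinatorics of the rule table are fully exercised (every violation
template and every valid kind pair occurs many times), while keeping the
whole suite under a few seconds.

## Known limitations

* No satisfiability search: same-branch disjunctions are propagated
  lazily, so inference is incomplete (sound but may leave `UNKNOWN`).
* `adjacent_to`'s no-overlap spatial semantics and `transformation_of`'s
  identity-through-time semantics are not structurally decidable and are
  not checked beyond endpoint kinds.
* No OWL/RDF I/O; no OBO logical definitions (`intersection_of` etc.).
* Embedded-name lint matches normalized names exactly (no stemming):
  false negatives are preferred over wrong refactoring suggestions.
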
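"""Advisory lint rules for common ontology defects.

Two structural smells are flagged, both purely advisory (no rewriting):

* **multiple inheritance** — a class with two or more is_a supertypes
  overloads the meaning of is_a within one ontology and hinders automatic
  alignment; in many cases one of the is_a edges is better expressed as a
  weaker ``contributes_to`` relation.
* **relation-embedded names** — a term name of the shape
  "X involved in Y" where X and Y are themselves terms of the ontology
  encodes a relation inside a label; a direct relation between the two
  named classes is the cleaner modeling.

Plus simple per-relation usage statistics (counts and subset fractions).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .model import OntologyModel

__all__ = [
    "LintFinding",
    "find_multiple_inheritance",
    "find_embedded_relation_names",
    "relation_usage_stats",
    "UsageStats",
    "LintConfigError",
]


class LintConfigError(ValueError):
    """A lint pattern configuration is malformed."""


@dataclass(frozen=True, slots=True)
class LintFinding:
    rule_id: str  # MULTIPLE_INHERITANCE | EMBEDDED_RELATION_NAME
    subject: tuple[str, ...]
    suggestion: str

    def to_dict(self) -> dict:
        return {
            "rule": self.rule_id,
            "subject": list(self.subject),
            "suggestion": self.suggestion,
        }


def find_multiple_inheritance(model: OntologyModel) -> list[LintFinding]:
    """One finding per class with two or more outgoing is_a assertions.

    The suggestion names ``contributes_to`` (an extension relation outside
    the canonical inventory) as a candidate replacement for one of the
    is_a edges.  Obsolete classes are ignored.
    """
    findings = []
    for cls in model.classes:
        if cls.obsolete:
            continue
        parents = [
            r.target_id
            for r in model.relations_from(cls.id)
            if r.kind.name == "is_a"
        ]
        if len(parents) >= 2:
            names = ", ".join(
                model.get_class(p).name or p for p in sorted(parents)
            )
            findings.append(
                LintFinding(
                    "MULTIPLE_INHERITANCE",
                    (cls.id, *sorted(parents)),
                    f"{cls.name or cls.id!r} specializes multiple supertypes "
                    f"({names}); consider replacing one is_a with a "
                    "contributes_to relation (non-inventory extension)",
                )
            )
    findings.sort(key=lambda f: f.subject)
    return findings


def _normalize_name(name: str) -> str:
    return " ".join(name.lower().split())


def find_embedded_relation_names(
    model: OntologyModel, patterns: tuple[str, ...] = ("involved in",)
) -> list[LintFinding]:
    """Flag term names of the shape "<X> <pattern> <Y>".

    A finding is produced only when both halves resolve (case- and
    whitespace-insensitively) to names of *other* classes in the model, so
    suggestions never point at classes the ontology does not contain.
    """
    if not patterns:
        raise LintConfigError("at least one name pattern is required")
    for pat in patterns:
        if not isinstance(pat, str) or not pat.strip():
            raise LintConfigError(f"malformed lint pattern: {pat!r}")

    by_name = {
        _normalize_name(cls.name): cls
        for cls in model.classes
        if cls.name and not cls.obsolete
    }
    findings = []
    for cls in model.classes:
        if cls.obsolete or not cls.name:
            continue
        norm = _normalize_name(cls.name)
        for pat in patterns:
            needle = _normalize_name(pat)
            for m in re.finditer(re.escape(needle), norm):
                left = norm[: m.start()].strip()
                right = norm[m.end() :].strip()
                x = by_name.get(left)
                y = by_name.get(right)
                if x is None or y is None or x.id == cls.id or y.id == cls.id:
                    continue
                findings.append(
                    LintFinding(
                        "EMBEDDED_RELATION_NAME",
                        (cls.id, x.id, y.id),
                        f"name of {cls.id} embeds the relation {needle!r} "
                        f"between {x.name!r} and {y.name!r}; consider a direct "
                        f"relation (e.g. involved_in) from {x.id} to {y.id} "
                        "instead of a combined term",
                    )
                )
    findings.sort(key=lambda f: f.subject)
    return findings


@dataclass
class UsageStats:
    """Per-relation assertion counts plus one subset fraction."""

    counts: dict[str, int] = field(default_factory=dict)
    total: int = 0
    subset: tuple[str, ...] = ()
    subset_count: int = 0
    subset_fraction: float = 0.0
    #: False when the model holds no assertions (fraction reported as 0).
    fraction_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "counts": dict(sorted(self.counts.items())),
            "total": self.total,
            "subset": list(self.subset),
            "subset_count": self.subset_count,
            "subset_fraction": self.subset_fraction,
            "fraction_defined": self.fraction_defined,
        }


def relation_usage_stats(
    model: OntologyModel, subset: tuple[str, ...] = ()
) -> UsageStats:
    """Count assertions per relation kind and the fraction in ``subset``.

    Fractions over all kinds sum to one; an empty model has no defined
    fraction and reports 0 with ``fraction_defined=False``.
    """
    counts: dict[str, int] = {}
    for assertion in model.relations:
        counts[assertion.kind.name] = counts.get(assertion.kind.name, 0) + 1
    total = sum(counts.values())
    subset_names = {n for n in subset}
    subset_count = sum(v for k, v in counts.items() if k in subset_names)
    if total == 0:
        return UsageStats(counts, 0, tuple(subset), 0, 0.0, fraction_defined=False)
    return UsageStats(
        counts, total, tuple(subset), subset_count, subset_count / total
    )
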
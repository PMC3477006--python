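"""JSON and plain-text rendering of validation, inference and lint output.

The JSON layout is versioned (``schema_version``) and stable: tooling can
rely on the ``issues``/``findings`` arrays and their ``rule`` ids.
"""

from __future__ import annotations

import json

from .constraints import ValidationIssue, ValidationReport
from .inference import KindAssignment
from .lint import LintFinding, UsageStats

__all__ = [
    "SCHEMA_VERSION",
    "validation_to_json",
    "validation_to_text",
    "inference_to_json",
    "inference_to_text",
    "lint_to_json",
    "lint_to_text",
    "stats_to_json",
    "stats_to_text",
]

SCHEMA_VERSION = 1


def _envelope(kind: str, payload: dict) -> dict:
    return {"schema_version": SCHEMA_VERSION, "report": kind, **payload}


def validation_to_json(report: ValidationReport, extra_issues=()) -> str:
    payload = report.to_dict()
    if extra_issues:
        payload["issues"] = payload["issues"] + [i.to_dict() for i in extra_issues]
        counts = payload["counts"]
        for issue in extra_issues:
            counts[issue.rule_id] = counts.get(issue.rule_id, 0) + 1
    return json.dumps(_envelope("validation", payload), indent=2, sort_keys=True)


def _issue_lines(issues: list[ValidationIssue]) -> list[str]:
    return [
        f"{i.severity.value.upper():7s} {i.rule_id:17s} "
        f"{'/'.join(i.subject)}: {i.message}"
        for i in issues
    ]


def validation_to_text(report: ValidationReport, extra_issues=()) -> str:
    issues = list(report.issues) + list(extra_issues)
    lines = [f"validation ({report.mode.value} mode): "
             f"{len(report.errors) + sum(1 for i in extra_issues if i.severity.value == 'error')} error(s), "
             f"{len(report.warnings) + sum(1 for i in extra_issues if i.severity.value == 'warning')} warning(s)"]
    lines += _issue_lines(issues)
    return "\n".join(lines) + "\n"


def inference_to_json(assignment: KindAssignment) -> str:
    return json.dumps(
        _envelope("inference", assignment.to_dict()), indent=2, sort_keys=True
    )


def inference_to_text(assignment: KindAssignment) -> str:
    lines = ["inferred kinds:"]
    for cid, kind in sorted(assignment.kinds.items()):
        lines.append(f"  {cid}: {kind.value}")
    unsat = sorted(assignment.unsatisfiable())
    if unsat:
        lines.append("unsatisfiable classes:")
        for cid in unsat:
            lines.append(f"  {cid}")
            for step in assignment.chain(cid):
                lines.append(f"    - {step}")
    else:
        lines.append("no unsatisfiable classes")
    return "\n".join(lines) + "\n"


def lint_to_json(findings: list[LintFinding]) -> str:
    return json.dumps(
        _envelope("lint", {"findings": [f.to_dict() for f in findings]}),
        indent=2,
        sort_keys=True,
    )


def lint_to_text(findings: list[LintFinding]) -> str:
    lines = [f"lint: {len(findings)} finding(s)"]
    for f in findings:
        lines.append(f"{f.rule_id:24s} {'/'.join(f.subject)}")
        lines.append(f"  suggestion: {f.suggestion}")
    return "\n".join(lines) + "\n"


def stats_to_json(stats: UsageStats) -> str:
    return json.dumps(_envelope("stats", stats.to_dict()), indent=2, sort_keys=True)


def stats_to_text(stats: UsageStats) -> str:
    lines = [f"relation usage ({stats.total} assertion(s)):"]
    for name, count in sorted(stats.counts.items()):
        lines.append(f"  {name:20s} {count}")
    if stats.subset:
        frac = f"{stats.subset_fraction:.4f}" if stats.fraction_defined else "n/a"
        lines.append(
            f"subset {{{', '.join(stats.subset)}}}: "
            f"{stats.subset_count}/{stats.total} = {frac}"
        )
    return "\n".join(lines) + "\n"
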
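"""Multi-analyte drug-association rules and their evaluation.

A rule is an if-then statement: a conjunction of criteria over a patient's
mutation, copy-number, mRNA-expression and IHC findings, associated with one
therapy.  Each matched rule counts as one drug association; the same drug may
accrue several associations through distinct rules.  Indeterminate findings
(e.g. a mutation result on a low-coverage gene) never satisfy a criterion —
they are reported, not treated as negative evidence.

Rule files are YAML: a list of documents with fields ``id``, ``drug``,
optional ``note`` and a non-empty ``criteria`` list of
``{analyte, target, op, value}`` mappings.  Serialization round-trips
losslessly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from numbers import Real
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "ANALYTES",
    "OPS",
    "Criterion",
    "Rule",
    "Finding",
    "PatientProfile",
    "AssociationReport",
    "RuleParseError",
    "parse_rules",
    "parse_rules_text",
    "dump_rules",
    "save_rules",
    "evaluate",
    "association_count_vs_adequacy",
]

ANALYTES = ("mutation", "copy_number", "mrna", "ihc")
OPS = ("present", "absent", "eq", "ne", "lt", "le", "gt", "ge", "in")
_NUMERIC_OPS = ("lt", "le", "gt", "ge")

#: string values read as a negative / wild-type finding
NEGATIVE_TOKENS = frozenset(
    {"absent", "negative", "none", "not_detected", "wt", "wild_type", "wildtype", "normal", ""}
)


class RuleParseError(ValueError):
    """Raised when a rule file fails validation; names the offending field."""


def _is_present(value: Any) -> bool:
    if value is None:
        return False
    if isinstance(value, bool):
        return value
    if isinstance(value, Real):
        return float(value) != 0.0
    return str(value).strip().lower() not in NEGATIVE_TOKENS


@dataclass(frozen=True)
class Criterion:
    analyte: str
    target: str
    op: str
    value: Any = None

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise RuleParseError(
                f"unknown analyte {self.analyte!r} (expected one of {ANALYTES})"
            )
        if self.op not in OPS:
            raise RuleParseError(f"unknown predicate op {self.op!r} (expected one of {OPS})")
        if not self.target:
            raise RuleParseError("criterion target must be non-empty")
        if self.op in ("present", "absent") and self.value is not None:
            raise RuleParseError(f"predicate {self.op!r} takes no value")
        if self.op in _NUMERIC_OPS and not isinstance(self.value, Real):
            raise RuleParseError(f"predicate {self.op!r} needs a numeric value, got {self.value!r}")
        if self.op == "in" and not isinstance(self.value, (list, tuple, set, frozenset)):
            raise RuleParseError("predicate 'in' needs a list of admissible values")
        if self.op in ("eq", "ne") and self.value is None:
            raise RuleParseError(f"predicate {self.op!r} needs a comparison value")

    def satisfied_by(self, profile: "PatientProfile") -> bool:
        finding = profile.get(self.analyte, self.target)
        if finding is None or finding.indeterminate:
            return False
        v = finding.value
        if self.op == "present":
            return _is_present(v)
        if self.op == "absent":
            return not _is_present(v)
        if self.op == "in":
            return v in self.value
        if self.op == "eq":
            return v == self.value
        if self.op == "ne":
            return v != self.value
        if not isinstance(v, Real):
            return False
        x, y = float(v), float(self.value)
        return {"lt": x < y, "le": x <= y, "gt": x > y, "ge": x >= y}[self.op]


@dataclass(frozen=True)
class Rule:
    rule_id: str
    drug: str
    criteria: tuple[Criterion, ...]
    note: str = ""

    def __post_init__(self) -> None:
        if not self.drug:
            raise RuleParseError(f"rule {self.rule_id!r}: drug must be non-empty")
        if not self.criteria:
            raise RuleParseError(f"rule {self.rule_id!r}: criteria list must be non-empty")

    def matches(self, profile: "PatientProfile") -> bool:
        return all(c.satisfied_by(profile) for c in self.criteria)


@dataclass(frozen=True)
class Finding:
    """One analyte result; ``indeterminate`` marks e.g. low-coverage calls."""

    value: Any
    indeterminate: bool = False


class PatientProfile:
    """Findings keyed by (analyte, target)."""

    def __init__(self, findings: Mapping[tuple[str, str], Finding] | None = None):
        self._findings: dict[tuple[str, str], Finding] = {}
        for (analyte, target), finding in (findings or {}).items():
            self.set(analyte, target, finding)

    def set(self, analyte: str, target: str, finding: Finding) -> None:
        if analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {analyte!r}")
        self._findings[(analyte, str(target))] = finding

    def get(self, analyte: str, target: str) -> Finding | None:
        return self._findings.get((analyte, target))

    def items(self):
        return self._findings.items()

    def __len__(self) -> int:
        return len(self._findings)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PatientProfile":
        """Build from a findings table with columns analyte, target, value
        and optional indeterminate."""
        profile = cls()
        has_flag = "indeterminate" in df.columns
        for row in df.itertuples(index=False):
            profile.set(
                str(row.analyte),
                str(row.target),
                Finding(row.value, bool(getattr(row, "indeterminate", False)) if has_flag else False),
            )
        return profile


@dataclass(frozen=True)
class AssociationReport:
    matched: tuple[tuple[str, str], ...]  # (rule_id, drug)
    association_count: int
    per_drug: Mapping[str, int]
    count_mode: str = "rules"


def evaluate(
    profile: PatientProfile, rules: Sequence[Rule], count_mode: str = "rules"
) -> AssociationReport:
    """Evaluate a patient profile against the rule list.

    ``count_mode="rules"`` (default) counts matched rules — one if-then
    association each.  ``count_mode="criteria"`` counts every satisfied
    criterion across all rules instead.
    """
    if count_mode not in ("rules", "criteria"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    matched = tuple((r.rule_id, r.drug) for r in rules if r.matches(profile))
    if count_mode == "rules":
        count = len(matched)
    else:
        count = sum(c.satisfied_by(profile) for r in rules for c in r.criteria)
    per_drug = Counter(drug for _, drug in matched)
    return AssociationReport(
        matched=matched,
        association_count=count,
        per_drug=dict(per_drug),
        count_mode=count_mode,
    )


# ---------------------------------------------------------------------------
# rule-file grammar (YAML)


def _criterion_from_mapping(raw: Any, where: str) -> Criterion:
    if not isinstance(raw, Mapping):
        raise RuleParseError(f"{where}: criterion must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - {"analyte", "target", "op", "value"}
    if unknown:
        raise RuleParseError(f"{where}: unknown criterion fields {sorted(unknown)}")
    try:
        return Criterion(
            analyte=raw.get("analyte"),
            target=str(raw.get("target", "")),
            op=raw.get("op"),
            value=raw.get("value"),
        )
    except RuleParseError as exc:
        raise RuleParseError(f"{where}: {exc}") from None


def parse_rules_text(text: str) -> list[Rule]:
    """Parse YAML rule text; an empty document yields an empty rule list."""
    docs = yaml.safe_load(text)
    if docs is None:
        return []
    if not isinstance(docs, list):
        raise RuleParseError("rule file must contain a YAML list of rules")
    out: list[Rule] = []
    for i, raw in enumerate(docs):
        where = f"rule #{i + 1}"
        if not isinstance(raw, Mapping):
            raise RuleParseError(f"{where}: must be a mapping")
        unknown = set(raw) - {"id", "drug", "note", "criteria"}
        if unknown:
            raise RuleParseError(f"{where}: unknown fields {sorted(unknown)}")
        crits = raw.get("criteria")
        if not isinstance(crits, list) or not crits:
            raise RuleParseError(f"{where}: 'criteria' must be a non-empty list")
        rule_id = str(raw.get("id", f"R{i + 1:03d}"))
        try:
            out.append(
                Rule(
                    rule_id=rule_id,
                    drug=str(raw.get("drug", "")),
                    criteria=tuple(
                        _criterion_from_mapping(c, f"{where} ({rule_id}) criterion #{j + 1}")
                        for j, c in enumerate(crits)
                    ),
                    note=str(raw.get("note", "")),
                )
            )
        except RuleParseError as exc:
            if str(exc).startswith(where):
                raise
            raise RuleParseError(f"{where} ({rule_id}): {exc}") from None
    return out


def parse_rules(path: str | Path) -> list[Rule]:
    """Parse a YAML rule file from disk."""
    return parse_rules_text(Path(path).read_text())


def dump_rules(rules: Iterable[Rule]) -> str:
    """Serialize rules back to the YAML grammar (lossless round trip)."""
    docs = []
    for r in rules:
        crits = []
        for c in r.criteria:
            doc: dict[str, Any] = {"analyte": c.analyte, "target": c.target, "op": c.op}
            if c.value is not None:
                doc["value"] = list(c.value) if isinstance(c.value, (tuple, set, frozenset)) else c.value
            crits.append(doc)
        entry: dict[str, Any] = {"id": r.rule_id, "drug": r.drug, "criteria": crits}
        if r.note:
            entry["note"] = r.note
        docs.append(entry)
    return yaml.safe_dump(docs, sort_keys=False)


def save_rules(rules: Iterable[Rule], path: str | Path) -> None:
    Path(path).write_text(dump_rules(rules))


# ---------------------------------------------------------------------------
# cohort hand-off


def association_count_vs_adequacy(
    items: Sequence[tuple[PatientProfile, Any]],
    rules: Sequence[Rule],
    scheme,
    axis: str = "tumor",
    count_mode: str = "rules",
) -> pd.DataFrame:
    """Mean +/- SEM association counts per adequacy bin.

    ``items`` pairs each patient profile with its specimen (anything exposing
    ``area_mm2`` and ``percent_tumor_nuclei`` as a fraction); ``scheme`` is a
    :class:`ngsadequacy.cohort.BinScheme`.  Empty bins are absent from the
    output; single-specimen bins carry SEM NaN and ``sem_defined`` False.
    """
    if axis not in ("tumor", "area"):
        raise ValueError(f"axis must be 'tumor' or 'area', got {axis!r}")
    counts = [evaluate(p, rules, count_mode).association_count for p, _ in items]
    if axis == "tumor":
        values = [100.0 * s.percent_tumor_nuclei for _, s in items]
        bins = scheme.tumor_bin(values)
    else:
        values = [s.area_mm2 for _, s in items]
        bins = scheme.area_bin(values)
    df = pd.DataFrame({"bin": bins, "count": counts})
    grouped = df.groupby("bin", observed=True)["count"]
    out = grouped.agg(n="size", mean="mean", sem=lambda v: v.sem(ddof=1))
    out["sem_defined"] = out["n"] > 1
    return out.reset_index()
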
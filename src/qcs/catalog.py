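"""Rule-base data model: comorbid conditions, clinical-code lists, and
Qualifying Comorbidity Sets.

A *catalog* holds everything the classifier needs: the comorbid conditions a
screener can select (each carrying display text and claims-code mappings) and
the qualifying sets — combinations of 1 to 3 conditions whose joint presence
classifies a patient as multimorbid.

Catalogs are authored as JSON documents (see ``data/catalog.schema.json`` for
the published schema) and validated on load. All clinical codes are stored in
a canonical dialect: uppercase, no periods, no whitespace. Both dotted
("I50.9") and undotted ("I509") inputs are accepted and normalize to the same
entry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterable, Mapping

__all__ = [
    "CodeSystem",
    "CodeEntry",
    "Condition",
    "QualifyingSet",
    "Catalog",
    "CatalogError",
    "Issue",
    "normalize_code",
    "load_catalog",
    "load_catalog_file",
    "serialize_catalog",
    "validate_catalog",
    "conditions_by_system",
]


class CatalogError(ValueError):
    """Raised when a catalog document or value violates the catalog contract.

    ``path`` locates the offending value inside the source document, e.g.
    ``conditions[2].codes[0].system``.
    """

    def __init__(self, message: str, path: str = "$"):
        super().__init__(f"{path}: {message}")
        self.path = path
        self.reason = message


class CodeSystem(str, Enum):
    """Closed enumeration of supported clinical code systems."""

    ICD9CM = "ICD9CM"
    ICD10CM = "ICD10CM"
    CPT = "CPT"
    HCPCS = "HCPCS"

    @classmethod
    def parse(cls, label: str, path: str = "$") -> "CodeSystem":
        try:
            return cls(str(label).strip().upper())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise CatalogError(
                f"unknown code system {label!r} (expected one of: {valid})", path
            ) from None


def normalize_code(raw: str, system: CodeSystem) -> str:
    """Return the canonical form of a clinical code string.

    Canonical form is uppercase with all periods and whitespace removed, so
    dotted and undotted dialects compare equal. Idempotent. The ``system``
    argument is required to keep callers explicit about provenance (ICD-9 vs
    ICD-10 strings are not distinguishable from the text alone); it does not
    alter the normalization itself.

    Raises :class:`CatalogError` if nothing is left after normalization.
    """
    if not isinstance(system, CodeSystem):
        raise CatalogError(f"unknown code system {system!r}")
    normalized = "".join(str(raw).upper().split()).replace(".", "")
    if not normalized:
        raise CatalogError(f"code {raw!r} is empty after normalization")
    return normalized


@dataclass(frozen=True)
class CodeEntry:
    """One clinical code mapped to a condition.

    ``match_kind`` is either ``"exact"`` (the patient code must equal
    ``normalized``) or ``"prefix"`` (the patient code must start with it).
    """

    system: CodeSystem
    raw: str
    normalized: str
    match_kind: str = "exact"

    MATCH_KINDS = ("exact", "prefix")

    @classmethod
    def from_raw(
        cls, raw: str, system: CodeSystem, match_kind: str = "exact", path: str = "$"
    ) -> "CodeEntry":
        if match_kind not in cls.MATCH_KINDS:
            raise CatalogError(
                f"unknown match kind {match_kind!r} (expected exact or prefix)", path
            )
        try:
            normalized = normalize_code(raw, system)
        except CatalogError as exc:
            raise CatalogError(exc.reason, path) from None
        return cls(system=system, raw=str(raw), normalized=normalized, match_kind=match_kind)


@dataclass(frozen=True)
class Condition:
    """A selectable comorbid condition with its clinical-code mappings."""

    id: str
    display_name: str
    organ_system: str
    clinical_definition: str = ""
    included_diagnoses: tuple[str, ...] = ()
    excluded_diagnoses: tuple[str, ...] = ()
    codes: tuple[CodeEntry, ...] = ()


@dataclass(frozen=True)
class QualifyingSet:
    """A combination of 1-3 condition ids that establishes multimorbidity."""

    members: frozenset[str]
    label: str | None = None

    def sort_key(self) -> tuple[int, tuple[str, ...]]:
        """Deterministic ordering: smaller sets first, then lexicographic."""
        return (len(self.members), tuple(sorted(self.members)))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return "{" + ", ".join(sorted(self.members)) + "}"


@dataclass
class Catalog:
    """The full rule base: conditions plus qualifying sets.

    ``conditions`` preserves document order (Python dicts are
    insertion-ordered). ``non_clinical`` marks demonstration catalogs that
    must not be used against real claims without explicit opt-in.
    """

    version: str
    conditions: dict[str, Condition]
    sets: list[QualifyingSet]
    non_clinical: bool = False

    def condition(self, condition_id: str) -> Condition:
        try:
            return self.conditions[condition_id]
        except KeyError:
            raise CatalogError(f"unknown condition id {condition_id!r}") from None

    def __contains__(self, condition_id: str) -> bool:
        return condition_id in self.conditions


# ---------------------------------------------------------------------------
# Loading / serialization


def _require(doc: Mapping[str, Any], key: str, typ: type, path: str) -> Any:
    if key not in doc:
        raise CatalogError(f"missing required key {key!r}", path)
    value = doc[key]
    if not isinstance(value, typ):
        raise CatalogError(
            f"key {key!r} must be {typ.__name__}, got {type(value).__name__}", path
        )
    return value


def _parse_condition(entry: Any, path: str) -> Condition:
    if not isinstance(entry, Mapping):
        raise CatalogError("condition must be an object", path)
    cid = _require(entry, "id", str, path)
    if not cid.strip():
        raise CatalogError("condition id must be non-empty", path)
    organ = _require(entry, "organ_system", str, path)
    if not organ.strip():
        raise CatalogError(f"condition {cid!r} has empty organ_system", path)
    display = entry.get("display_name", cid)
    included = tuple(str(t) for t in entry.get("included_diagnoses", []))
    excluded = tuple(str(t) for t in entry.get("excluded_diagnoses", []))
    overlap = set(included) & set(excluded)
    if overlap:
        raise CatalogError(
            f"included and excluded diagnoses overlap: {sorted(overlap)}", path
        )
    codes = []
    for j, code_doc in enumerate(entry.get("codes", [])):
        cpath = f"{path}.codes[{j}]"
        if not isinstance(code_doc, Mapping):
            raise CatalogError("code entry must be an object", cpath)
        system = CodeSystem.parse(_require(code_doc, "system", str, cpath), cpath)
        codes.append(
            CodeEntry.from_raw(
                _require(code_doc, "code", str, cpath),
                system,
                code_doc.get("match", "exact"),
                cpath,
            )
        )
    return Condition(
        id=cid,
        display_name=str(display),
        organ_system=organ,
        clinical_definition=str(entry.get("clinical_definition", "")),
        included_diagnoses=included,
        excluded_diagnoses=excluded,
        codes=tuple(codes),
    )


def load_catalog(source: str | Mapping[str, Any]) -> Catalog:
    """Parse and validate a catalog document.

    ``source`` is either a JSON text or an already-parsed mapping. Every
    violation of the catalog invariants raises :class:`CatalogError` with a
    path into the document. Loading is deterministic: condition iteration
    order equals document order.
    """
    if isinstance(source, str):
        try:
            doc = json.loads(source)
        except json.JSONDecodeError as exc:
            raise CatalogError(f"document is not valid JSON: {exc}") from None
    else:
        doc = source
    if not isinstance(doc, Mapping):
        raise CatalogError("top-level document must be a JSON object")

    version = str(_require(doc, "version", str, "$"))
    raw_conditions = _require(doc, "conditions", list, "$")
    raw_sets = _require(doc, "sets", list, "$")
    if not raw_conditions:
        raise CatalogError("catalog must define at least one condition", "$.conditions")

    conditions: dict[str, Condition] = {}
    for i, entry in enumerate(raw_conditions):
        path = f"$.conditions[{i}]"
        condition = _parse_condition(entry, path)
        if condition.id in conditions:
            raise CatalogError(f"duplicate condition id {condition.id!r}", path)
        conditions[condition.id] = condition

    sets: list[QualifyingSet] = []
    seen_members: set[frozenset[str]] = set()
    for i, raw_set in enumerate(raw_sets):
        path = f"$.sets[{i}]"
        if not isinstance(raw_set, list):
            raise CatalogError("qualifying set must be an array of condition ids", path)
        if len(raw_set) != len(set(raw_set)):
            raise CatalogError(f"duplicate member ids in set {raw_set}", path)
        members = frozenset(str(m) for m in raw_set)
        if not 1 <= len(members) <= 3:
            raise CatalogError(f"set size {len(members)} outside allowed range 1-3", path)
        missing = sorted(m for m in members if m not in conditions)
        if missing:
            raise CatalogError(f"set member(s) not in conditions: {missing}", path)
        if members in seen_members:
            raise CatalogError(f"duplicate qualifying set {sorted(members)}", path)
        seen_members.add(members)
        sets.append(QualifyingSet(members=members))

    return Catalog(
        version=version,
        conditions=conditions,
        sets=sets,
        non_clinical=bool(doc.get("non_clinical", False)),
    )


def load_catalog_file(path: str) -> Catalog:
    """Load a catalog from a UTF-8 JSON file."""
    with open(path, encoding="utf-8") as fh:
        return load_catalog(fh.read())


def serialize_catalog(catalog: Catalog) -> dict[str, Any]:
    """Serialize back to the document form; round-trips through load_catalog."""
    return {
        "version": catalog.version,
        "non_clinical": catalog.non_clinical,
        "conditions": [
            {
                "id": c.id,
                "display_name": c.display_name,
                "organ_system": c.organ_system,
                "clinical_definition": c.clinical_definition,
                "included_diagnoses": list(c.included_diagnoses),
                "excluded_diagnoses": list(c.excluded_diagnoses),
                "codes": [
                    {"system": e.system.value, "code": e.normalized, "match": e.match_kind}
                    for e in c.codes
                ],
            }
            for c in catalog.conditions.values()
        ],
        "sets": [sorted(s.members) for s in catalog.sets],
    }


# ---------------------------------------------------------------------------
# Validation / views


@dataclass(frozen=True)
class Issue:
    """One validation finding. ``level`` is ``"error"`` or ``"warning"``."""

    level: str
    path: str
    message: str


def validate_catalog(catalog: Catalog) -> list[Issue]:
    """Audit a catalog, returning every invariant violation and warning.

    Errors repeat the load-time invariants (so hand-built Catalog objects can
    be audited too); warnings flag conditions unused by any set and normalized
    codes mapped to more than one condition within the same system.
    """
    issues: list[Issue] = []

    if not catalog.conditions:
        issues.append(Issue("error", "$.conditions", "catalog has no conditions"))

    for cid, condition in catalog.conditions.items():
        path = f"$.conditions[{cid}]"
        if not condition.organ_system.strip():
            issues.append(Issue("error", path, "empty organ_system"))
        overlap = set(condition.included_diagnoses) & set(condition.excluded_diagnoses)
        if overlap:
            issues.append(
                Issue("error", path, f"included/excluded diagnoses overlap: {sorted(overlap)}")
            )

    seen: set[frozenset[str]] = set()
    used: set[str] = set()
    for i, qset in enumerate(catalog.sets):
        path = f"$.sets[{i}]"
        if not 1 <= len(qset.members) <= 3:
            issues.append(Issue("error", path, f"set size {len(qset.members)} outside 1-3"))
        missing = sorted(m for m in qset.members if m not in catalog.conditions)
        if missing:
            issues.append(Issue("error", path, f"unresolvable member(s): {missing}"))
        if qset.members in seen:
            issues.append(Issue("error", path, f"duplicate set {sorted(qset.members)}"))
        seen.add(qset.members)
        used |= qset.members

    for cid in catalog.conditions:
        if cid not in used:
            issues.append(
                Issue("warning", f"$.conditions[{cid}]", "condition unused by any qualifying set")
            )

    # same normalized code attributed to >1 condition within one system
    owners: dict[tuple[CodeSystem, str], list[str]] = {}
    for cid, condition in catalog.conditions.items():
        for entry in condition.codes:
            owners.setdefault((entry.system, entry.normalized), []).append(cid)
    for (system, code), cids in sorted(owners.items(), key=lambda kv: (kv[0][0].value, kv[0][1])):
        unique = sorted(set(cids))
        if len(unique) > 1:
            issues.append(
                Issue(
                    "warning",
                    "$.conditions",
                    f"code {code} ({system.value}) mapped to multiple conditions: {unique}",
                )
            )
    return issues


def conditions_by_system(catalog: Catalog) -> dict[str, list[Condition]]:
    """Group conditions by organ system, preserving catalog order.

    System order is first-appearance order; within a system, catalog order.
    The grouping partitions the condition set — no empty groups, no loss, no
    duplication.
    """
    grouped: dict[str, list[Condition]] = {}
    for condition in catalog.conditions.values():
        grouped.setdefault(condition.organ_system, []).append(condition)
    return grouped


def resolve_profile(condition_ids: Iterable[str], catalog: Catalog) -> frozenset[str]:
    """Validate a set of condition ids against the catalog; returns frozenset."""
    profile = frozenset(condition_ids)
    unknown = sorted(cid for cid in profile if cid not in catalog.conditions)
    if unknown:
        raise CatalogError(f"unknown condition id(s): {unknown}")
    return profile
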
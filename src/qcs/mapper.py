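"""Translate coded claims records into condition profiles.

A claims record is a bag of (code system, code string) pairs. Each code is
normalized and looked up against the catalog's per-condition code lists;
exact entries must equal the normalized code, prefix entries must start it.
Codes matching nothing are reported as unmapped, never fatal — claims feeds
carry many codes irrelevant to the rule base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .catalog import Catalog, CatalogError, CodeSystem, normalize_code

__all__ = ["CodedDiagnosis", "Hit", "MappingResult", "CodeIndex", "map_code", "map_record"]


@dataclass(frozen=True)
class CodedDiagnosis:
    """One coded claim line: a code system plus the code string as received."""

    system: CodeSystem
    code: str

    def __post_init__(self) -> None:
        if not str(self.code).strip():
            raise CatalogError("diagnosis code must be non-empty")


@dataclass(frozen=True)
class Hit:
    """One diagnosis→condition attribution, with the entry kind that matched."""

    diagnosis: CodedDiagnosis
    condition_id: str
    match_kind: str


@dataclass
class MappingResult:
    """Outcome of mapping a full record.

    ``profile`` is the set of condition ids appearing in ``hits``;
    ``hits`` and ``unmapped`` together cover every input diagnosis.
    """

    profile: frozenset[str]
    hits: list[Hit] = field(default_factory=list)
    unmapped: list[CodedDiagnosis] = field(default_factory=list)


class CodeIndex:
    """Lookup structure over a catalog's code lists.

    Exact entries live in a hash map keyed by (system, normalized code);
    prefix entries are scanned per system. Built once per catalog and reused
    across records.
    """

    def __init__(self, catalog: Catalog):
        self._exact: dict[tuple[CodeSystem, str], set[str]] = {}
        self._prefix: dict[CodeSystem, list[tuple[str, str]]] = {s: [] for s in CodeSystem}
        for cid, condition in catalog.conditions.items():
            for entry in condition.codes:
                if entry.match_kind == "exact":
                    self._exact.setdefault((entry.system, entry.normalized), set()).add(cid)
                else:
                    self._prefix[entry.system].append((entry.normalized, cid))

    def lookup(self, diag: CodedDiagnosis) -> list[Hit]:
        """All condition attributions for one diagnosis.

        When a code satisfies both an exact and a prefix entry of the same
        condition, a single hit with match_kind ``exact`` is recorded.
        """
        if not isinstance(diag.system, CodeSystem):
            raise CatalogError(f"unknown code system {diag.system!r}")
        code = normalize_code(diag.code, diag.system)
        matched: dict[str, str] = {}
        for prefix, cid in self._prefix[diag.system]:
            if code.startswith(prefix):
                matched[cid] = "prefix"
        for cid in self._exact.get((diag.system, code), ()):
            matched[cid] = "exact"  # exact dominates prefix for the same condition
        return [Hit(diag, cid, kind) for cid, kind in sorted(matched.items())]


def map_code(diag: CodedDiagnosis, catalog: Catalog) -> frozenset[str]:
    """Condition ids matching one coded diagnosis (possibly several, possibly none)."""
    return frozenset(h.condition_id for h in CodeIndex(catalog).lookup(diag))


def map_record(diags: list[CodedDiagnosis], catalog: Catalog) -> MappingResult:
    """Map a full claims record to a condition profile.

    Deterministic: hits follow input order (then condition id). Duplicate
    input codes collapse in the profile but are preserved in ``hits``.
    Errors are reported with the input index of the offending diagnosis.
    """
    index = CodeIndex(catalog)
    hits: list[Hit] = []
    unmapped: list[CodedDiagnosis] = []
    for i, diag in enumerate(diags):
        try:
            found = index.lookup(diag)
        except CatalogError as exc:
            raise CatalogError(f"diagnosis #{i}: {exc.reason}") from None
        if found:
            hits.extend(found)
        else:
            unmapped.append(diag)
    return MappingResult(
        profile=frozenset(h.condition_id for h in hits), hits=hits, unmapped=unmapped
    )
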
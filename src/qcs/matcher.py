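"""Multimorbidity decision: does a condition profile contain a qualifying set?

Two forms are provided. :func:`evaluate` is the batch form: it reports every
qualifying set contained in the profile, in a deterministic order. The
:class:`IncrementalMatcher` mirrors the interactive screening flow — it reacts
to one condition at a time and fires a trigger event on the first addition
that completes any qualifying set, after which the triggered state latches.
:func:`brute_force_oracle` is a deliberately naive reference used in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .catalog import Catalog, CatalogError, QualifyingSet, resolve_profile

__all__ = [
    "ConditionProfile",
    "MultimorbidityResult",
    "TriggerEvent",
    "IncrementalMatcher",
    "evaluate",
    "brute_force_oracle",
]

#: A patient's attributed conditions: any iterable of catalog condition ids.
ConditionProfile = frozenset[str]


@dataclass(frozen=True)
class MultimorbidityResult:
    """Classification outcome with its full witness list.

    ``matched_sets`` holds every qualifying set contained in the profile,
    sorted by (size, lexicographic member ids); ``first_triggering_set`` is
    the first element of that ordering (the set the interactive flow would
    report), or None when not multimorbid.
    """

    is_multimorbid: bool
    matched_sets: tuple[QualifyingSet, ...]
    first_triggering_set: QualifyingSet | None

    def to_dict(self) -> dict:
        return {
            "is_multimorbid": self.is_multimorbid,
            "matched_sets": [sorted(s.members) for s in self.matched_sets],
            "first_triggering_set": (
                sorted(self.first_triggering_set.members)
                if self.first_triggering_set
                else None
            ),
        }


def evaluate(profile: Iterable[str], catalog: Catalog) -> MultimorbidityResult:
    """Batch classification: all qualifying sets contained in the profile.

    Raises :class:`~qcs.catalog.CatalogError` naming any profile id absent
    from the catalog.
    """
    resolved = resolve_profile(profile, catalog)
    matched = sorted(
        (s for s in catalog.sets if s.members <= resolved), key=QualifyingSet.sort_key
    )
    return MultimorbidityResult(
        is_multimorbid=bool(matched),
        matched_sets=tuple(matched),
        first_triggering_set=matched[0] if matched else None,
    )


def brute_force_oracle(profile: Iterable[str], catalog: Catalog) -> bool:
    """Literal member-by-member subset scan over all sets. Test oracle only."""
    conditions = set(profile)
    for qset in catalog.sets:
        if all(member in conditions for member in qset.members):
            return True
    return False


@dataclass(frozen=True)
class TriggerEvent:
    """Fired by the incremental matcher when multimorbidity is established."""

    completed_set: QualifyingSet


class IncrementalMatcher:
    """Per-selection matcher with early termination.

    Maintains an inverted index (condition id → sets containing it) and a
    per-set countdown of unmet members, so each addition touches only the
    sets involving that condition. The trigger fires on the first addition
    that completes any set — ties broken by the batch ordering — and the
    triggered state latches thereafter.
    """

    def __init__(self, catalog: Catalog):
        self._catalog = catalog
        self._index: dict[str, list[int]] = {}
        for i, qset in enumerate(catalog.sets):
            for member in qset.members:
                self._index.setdefault(member, []).append(i)
        self._remaining: list[int] = [len(s.members) for s in catalog.sets]
        self._selected: set[str] = set()
        self._trigger: TriggerEvent | None = None

    @property
    def selected(self) -> frozenset[str]:
        return frozenset(self._selected)

    @property
    def triggered(self) -> TriggerEvent | None:
        return self._trigger

    def _resolve(self, condition_id: str) -> None:
        if condition_id not in self._catalog.conditions:
            raise CatalogError(f"unknown condition id {condition_id!r}")

    def add(self, condition_id: str) -> TriggerEvent | None:
        """Register a selection; returns the trigger event if this completes a set."""
        self._resolve(condition_id)
        if condition_id in self._selected:
            raise CatalogError(f"condition {condition_id!r} already selected")
        self._selected.add(condition_id)
        completed: list[QualifyingSet] = []
        for i in self._index.get(condition_id, ()):
            self._remaining[i] -= 1
            if self._remaining[i] == 0:
                completed.append(self._catalog.sets[i])
        if completed and self._trigger is None:
            winner = min(completed, key=QualifyingSet.sort_key)
            self._trigger = TriggerEvent(completed_set=winner)
            return self._trigger
        return None

    def remove(self, condition_id: str) -> None:
        """Withdraw a selection; pre-trigger, state equals never having added it."""
        self._resolve(condition_id)
        if condition_id not in self._selected:
            raise CatalogError(f"condition {condition_id!r} is not selected")
        self._selected.discard(condition_id)
        for i in self._index.get(condition_id, ()):
            self._remaining[i] += 1
        # triggered state latches; removal never un-establishes multimorbidity
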
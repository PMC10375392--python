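"""Stateful emulation of the interactive screening flow.

A session walks organ-system pages in catalog order, lets the user toggle
conditions, raises an immediate notification (status flip) the moment the
selection contains a qualifying set, and yields a final result plus a
plain-text notification payload standing in for the app's email step.

Timestamps come from an injectable clock so tests and replays are exactly
deterministic.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable

from .catalog import Catalog, CatalogError, QualifyingSet, conditions_by_system
from .matcher import IncrementalMatcher

__all__ = [
    "SessionStatus",
    "SessionError",
    "LogEvent",
    "ScreeningSession",
    "SessionResult",
    "start_session",
    "select_condition",
    "deselect_condition",
    "finish_session",
    "build_notification_payload",
]


class SessionError(RuntimeError):
    """Illegal session transition (selection after termination, double finish...)."""


class SessionStatus(str, Enum):
    IN_PROGRESS = "in_progress"
    MULTIMORBID = "multimorbid"
    COMPLETED_NOT_MULTIMORBID = "completed_not_multimorbid"


@dataclass(frozen=True)
class LogEvent:
    timestamp: float
    action: str
    detail: str = ""


@dataclass(frozen=True)
class SessionResult:
    """Immutable snapshot taken when a session finishes."""

    status: SessionStatus
    selected: tuple[str, ...]
    triggering_set: QualifyingSet | None
    elapsed_s: float | None = None


class ScreeningSession:
    """One screening pass over a catalog.

    ``clock`` is any zero-argument callable returning seconds; it defaults to
    ``time.monotonic``. The event log is append-only.
    """

    def __init__(self, catalog: Catalog, clock: Callable[[], float] | None = None):
        issues_free = bool(catalog.conditions)
        if not issues_free:
            raise CatalogError("cannot start a session on an empty catalog")
        self.catalog = catalog
        self._clock = clock or time.monotonic
        self._matcher = IncrementalMatcher(catalog)
        self.page_order: tuple[str, ...] = tuple(conditions_by_system(catalog))
        self.selected: list[str] = []
        self.status = SessionStatus.IN_PROGRESS
        self.triggering_set: QualifyingSet | None = None
        self.event_log: list[LogEvent] = []
        self.skip_instructions = False
        self._started_at = self._clock()
        self._log("session_started", f"pages={','.join(self.page_order)}")

    def _log(self, action: str, detail: str = "") -> None:
        self.event_log.append(LogEvent(self._clock(), action, detail))

    def set_skip_instructions(self, value: bool = True) -> None:
        """Record the "don't show instructions again" preference (log-only)."""
        self.skip_instructions = value
        self._log("skip_instructions", str(value).lower())

    def select(self, condition_id: str) -> None:
        if self.status is not SessionStatus.IN_PROGRESS:
            raise SessionError(
                f"session already terminated ({self.status.value}); selection rejected"
            )
        if condition_id in self._matcher.selected:
            self._log("duplicate_selection_ignored", condition_id)
            return
        event = self._matcher.add(condition_id)  # raises on unknown id
        self.selected.append(condition_id)
        self._log("selected", condition_id)
        if event is not None:
            self.status = SessionStatus.MULTIMORBID
            self.triggering_set = event.completed_set
            self._log("multimorbid_notified", ",".join(sorted(event.completed_set.members)))

    def deselect(self, condition_id: str) -> None:
        if self.status is not SessionStatus.IN_PROGRESS:
            raise SessionError(
                f"session already terminated ({self.status.value}); deselection rejected"
            )
        self._matcher.remove(condition_id)  # raises if not selected / unknown
        self.selected.remove(condition_id)
        self._log("deselected", condition_id)

    def finish(self) -> SessionResult:
        if self.status is SessionStatus.COMPLETED_NOT_MULTIMORBID or any(
            e.action == "session_finished" for e in self.event_log
        ):
            raise SessionError("session already finished")
        if self.status is SessionStatus.IN_PROGRESS:
            self.status = SessionStatus.COMPLETED_NOT_MULTIMORBID
        finished_at = self._clock()
        self._log("session_finished", self.status.value)
        return SessionResult(
            status=self.status,
            selected=tuple(self.selected),
            triggering_set=self.triggering_set,
            elapsed_s=finished_at - self._started_at,
        )


# Functional aliases matching the operation-style API.

def start_session(catalog: Catalog, clock: Callable[[], float] | None = None) -> ScreeningSession:
    return ScreeningSession(catalog, clock=clock)


def select_condition(session: ScreeningSession, condition_id: str) -> ScreeningSession:
    session.select(condition_id)
    return session


def deselect_condition(session: ScreeningSession, condition_id: str) -> ScreeningSession:
    session.deselect(condition_id)
    return session


def finish_session(session: ScreeningSession) -> SessionResult:
    return session.finish()


def build_notification_payload(result: SessionResult) -> str:
    """Deterministic plain-text summary of a finished screening.

    Carries no identifiers beyond what the result itself holds; byte-identical
    across repeated calls on the same result.
    """
    lines = [
        "== Multimorbidity screening result ==",
        f"status: {result.status.value}",
        f"selected conditions ({len(result.selected)}): "
        + (", ".join(result.selected) if result.selected else "(none)"),
    ]
    if result.triggering_set is not None:
        lines.append(
            "triggering set: " + ", ".join(sorted(result.triggering_set.members))
        )
    if result.elapsed_s is not None:
        lines.append(f"elapsed_s: {result.elapsed_s:.3f}")
    return "\n".join(lines) + "\n"
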
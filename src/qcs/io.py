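"""CSV/JSONL interchange for trials, surveys, and claims.

Trials CSV columns:
``participant_id, scenario_id, selected_ids, predicted, truth,
mmapp_time_s, comparator_time_s`` with ``selected_ids`` semicolon-delimited;
an optional ``intended_ids`` column carries ground truth per row, otherwise
intended sets are resolved from the built-in scenarios by ``scenario_id``.

Survey CSV columns: ``participant_id, statement_id, rating``.

Claims input: CSV or JSONL with ``patient_id, system, code``.
"""

from __future__ import annotations

import json
import math
from typing import Iterable

import pandas as pd

from .catalog import CodeSystem
from .evaluation import EvaluationError, TrialRecord
from .mapper import CodedDiagnosis

__all__ = [
    "read_trials_csv",
    "write_trials_csv",
    "read_survey_csv",
    "read_claims",
]

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f"}


def _parse_bool(value, column: str, row: int) -> bool:
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise EvaluationError(f"row {row}: cannot parse {column}={value!r} as yes/no")


def _parse_ids(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return frozenset()
    return frozenset(part.strip() for part in str(value).split(";") if part.strip())


def _parse_time(value) -> float | None:
    if value is None or str(value).strip() == "":
        return None
    number = float(value)
    return None if math.isnan(number) else number


def read_trials_csv(path: str) -> list[TrialRecord]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"participant_id", "scenario_id", "selected_ids", "predicted", "truth"}
    missing = required - set(frame.columns)
    if missing:
        raise EvaluationError(f"trials CSV missing column(s): {sorted(missing)}")

    intended_by_scenario: dict[str, frozenset[str]] = {}
    if "intended_ids" not in frame.columns:
        from .fixtures import builtin_scenarios

        intended_by_scenario = {f.scenario_id: f.intended for f in builtin_scenarios()}

    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        if "intended_ids" in frame.columns:
            intended = _parse_ids(getattr(row, "intended_ids"))
        else:
            intended = intended_by_scenario.get(row.scenario_id, frozenset())
        records.append(
            TrialRecord(
                participant_id=row.participant_id,
                scenario_id=row.scenario_id,
                selected=_parse_ids(row.selected_ids),
                intended=intended,
                truth_multimorbid=_parse_bool(row.truth, "truth", i),
                predicted_multimorbid=_parse_bool(row.predicted, "predicted", i),
                mmapp_time_s=_parse_time(getattr(row, "mmapp_time_s", None)),
                comparator_time_s=_parse_time(getattr(row, "comparator_time_s", None)),
            )
        )
    return records


def write_trials_csv(records: Iterable[TrialRecord], path: str) -> None:
    frame = pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "scenario_id": r.scenario_id,
                "selected_ids": ";".join(sorted(r.selected)),
                "intended_ids": ";".join(sorted(r.intended)),
                "predicted": "yes" if r.predicted_multimorbid else "no",
                "truth": "yes" if r.truth_multimorbid else "no",
                "mmapp_time_s": "" if r.mmapp_time_s is None else r.mmapp_time_s,
                "comparator_time_s": (
                    "" if r.comparator_time_s is None else r.comparator_time_s
                ),
            }
            for r in records
        ]
    )
    frame.to_csv(path, index=False)


def read_survey_csv(path: str) -> dict[str, list[int]]:
    """Ratings grouped by statement id, in file order."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"participant_id", "statement_id", "rating"}
    missing = required - set(frame.columns)
    if missing:
        raise EvaluationError(f"survey CSV missing column(s): {sorted(missing)}")
    surveys: dict[str, list[int]] = {}
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            rating = int(row.rating)
        except ValueError:
            raise EvaluationError(f"row {i}: rating {row.rating!r} is not an integer")
        surveys.setdefault(row.statement_id, []).append(rating)
    return surveys


def read_claims(path: str) -> dict[str, list[CodedDiagnosis]]:
    """Claims lines grouped by patient, preserving input order.

    Accepts CSV (``patient_id,system,code`` header) or JSONL (one object with
    those keys per line, detected by a ``.jsonl``/``.json`` suffix or a
    leading ``{``).
    """
    patients: dict[str, list[CodedDiagnosis]] = {}
    with open(path, encoding="utf-8") as fh:
        head = fh.read(1)
    if path.endswith((".jsonl", ".json")) or head == "{":
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                patients.setdefault(str(obj["patient_id"]), []).append(
                    CodedDiagnosis(
                        system=CodeSystem.parse(obj["system"], f"line {i}"),
                        code=str(obj["code"]),
                    )
                )
    else:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        for i, row in enumerate(frame.itertuples(index=False)):
            patients.setdefault(row.patient_id, []).append(
                CodedDiagnosis(
                    system=CodeSystem.parse(row.system, f"row {i}"), code=row.code
                )
            )
    return patients
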
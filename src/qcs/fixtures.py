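"""Built-in fixtures and synthetic generators.

Provides, with no external downloads:

* the five feasibility scenarios at the resolution published for the trial
  (truth labels, intended/total-possible comorbidity counts, and the
  condition labels named in the trial narrative);
* a small NON-CLINICAL demonstration catalog whose qualifying sets reproduce
  those scenario truth labels;
* the 50-trial reference dataset reconstructed from the published
  per-scenario tallies;
* seeded generators for synthetic condition profiles and synthetic rater
  trials.

The demonstration catalog's qualifying sets are invented for internal
consistency only — they are NOT the clinically derived set list, and the
catalog is flagged ``non_clinical`` so the claims classifier refuses it
without explicit opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import Catalog, CatalogError, load_catalog
from .evaluation import TrialRecord
from .matcher import evaluate

__all__ = [
    "ScenarioFixture",
    "RaterModel",
    "builtin_scenarios",
    "builtin_toy_catalog",
    "builtin_trial_records",
    "generate_patient",
    "simulate_trials",
]


@dataclass(frozen=True)
class ScenarioFixture:
    """One hypothetical patient scenario at published resolution.

    ``intended`` are the conditions actually present in the scenario;
    ``possible`` additionally includes near-miss conditions a reader might
    plausibly select (``n_total_possible`` = len(possible)).
    ``named_conditions`` are the condition labels explicitly reported in the
    trial narrative; other members are documented placeholders.
    """

    scenario_id: str
    truth_multimorbid: bool
    intended: frozenset[str]
    possible: frozenset[str]
    named_conditions: tuple[str, ...]

    @property
    def n_intended(self) -> int:
        return len(self.intended)

    @property
    def n_total_possible(self) -> int:
        return len(self.possible)


# Condition ids used throughout the fixtures (the ten conditions named in the
# trial report, grouped into a documented default organ-system taxonomy).
_CONDITIONS = [
    # (id, display, organ system)
    ("cerebrovascular_disease", "Cerebrovascular Disease", "Neurologic"),
    ("cardiac_arrhythmia", "Cardiac Arrhythmia", "Cardiac"),
    ("chronic_lung_disease", "Chronic Lung Disease", "Pulmonary"),
    ("pneumonia", "Pneumonia", "Pulmonary"),
    ("acute_kidney_injury", "Acute Kidney Injury", "Renal"),
    ("endocrine_metabolic_disorder", "Endocrine/Metabolic Disorder", "Endocrine"),
    ("diabetes_with_complications", "Diabetes with Complications", "Endocrine"),
    ("protein_calorie_malnutrition", "Protein-Calorie Malnutrition", "Nutritional"),
    ("depression", "Depression", "Psychiatric"),
    ("substance_abuse", "Substance Abuse", "Psychiatric"),
]

# Representative (not exhaustive) code lists so the claims mapper is
# exercisable end to end against the demonstration catalog.
_CODES = {
    "cerebrovascular_disease": [
        ("ICD10CM", "I63", "prefix"),
        ("ICD9CM", "434", "prefix"),
    ],
    "cardiac_arrhythmia": [
        ("ICD10CM", "I48", "prefix"),
        ("ICD10CM", "I49.9", "exact"),
        ("ICD9CM", "427", "prefix"),
    ],
    "chronic_lung_disease": [
        ("ICD10CM", "J44", "prefix"),
        ("ICD9CM", "496", "exact"),
        ("HCPCS", "E1390", "exact"),  # home oxygen concentrator
    ],
    "pneumonia": [
        ("ICD10CM", "J18", "prefix"),
        ("ICD9CM", "486", "exact"),
    ],
    "acute_kidney_injury": [
        ("ICD10CM", "N17", "prefix"),
        ("ICD9CM", "584", "prefix"),
    ],
    "endocrine_metabolic_disorder": [
        ("ICD10CM", "E83", "prefix"),
        ("ICD9CM", "276", "prefix"),
    ],
    "diabetes_with_complications": [
        ("ICD10CM", "E11.2", "prefix"),
        ("ICD10CM", "E11.5", "prefix"),
        ("ICD9CM", "250.4", "prefix"),
    ],
    "protein_calorie_malnutrition": [
        ("ICD10CM", "E44", "prefix"),
        ("ICD9CM", "263", "prefix"),
    ],
    "depression": [
        ("ICD10CM", "F32", "prefix"),
        ("ICD9CM", "311", "exact"),
    ],
    "substance_abuse": [
        ("ICD10CM", "F10.1", "prefix"),
        ("ICD9CM", "305", "prefix"),
    ],
}

# Invented qualifying sets chosen so each scenario's truth label reproduces
# under evaluate(), including the published redundancy: multimorbid scenarios
# stay multimorbid under the misses the raters actually made.
_TOY_SETS = [
    ["pneumonia"],
    ["substance_abuse"],
    ["chronic_lung_disease", "diabetes_with_complications"],
    ["acute_kidney_injury", "chronic_lung_disease"],
    ["cardiac_arrhythmia", "acute_kidney_injury"],
    ["protein_calorie_malnutrition", "depression", "chronic_lung_disease"],
]


def builtin_toy_catalog() -> Catalog:
    """The NON-CLINICAL demonstration catalog backing the built-in scenarios."""
    doc = {
        "version": "toy-1",
        "non_clinical": True,
        "conditions": [
            {
                "id": cid,
                "display_name": display,
                "organ_system": system,
                "clinical_definition": f"Demonstration definition for {display}.",
                "codes": [
                    {"system": sys_, "code": code, "match": match}
                    for sys_, code, match in _CODES.get(cid, [])
                ],
            }
            for cid, display, system in _CONDITIONS
        ],
        "sets": _TOY_SETS,
    }
    return load_catalog(doc)


def builtin_scenarios() -> list[ScenarioFixture]:
    """The five scenarios (A-E) at published resolution.

    Truth labels (No, Yes, Yes, No, Yes), intended counts (2, 4, 3, 2, 2)
    and total-possible counts (2, 5, 4, 2, 4). Members not named in the
    trial narrative are placeholders drawn from the demonstration catalog.
    """
    return [
        ScenarioFixture(
            scenario_id="A",
            truth_multimorbid=False,
            intended=frozenset({"cardiac_arrhythmia", "cerebrovascular_disease"}),
            possible=frozenset({"cardiac_arrhythmia", "cerebrovascular_disease"}),
            named_conditions=("cardiac_arrhythmia",),
        ),
        ScenarioFixture(
            scenario_id="B",
            truth_multimorbid=True,
            intended=frozenset(
                {
                    "protein_calorie_malnutrition",
                    "depression",
                    "chronic_lung_disease",
                    "diabetes_with_complications",
                }
            ),
            possible=frozenset(
                {
                    "protein_calorie_malnutrition",
                    "depression",
                    "chronic_lung_disease",
                    "diabetes_with_complications",
                    "endocrine_metabolic_disorder",
                }
            ),
            named_conditions=(
                "protein_calorie_malnutrition",
                "depression",
                "chronic_lung_disease",
            ),
        ),
        ScenarioFixture(
            scenario_id="C",
            truth_multimorbid=True,
            intended=frozenset(
                {
                    "acute_kidney_injury",
                    "chronic_lung_disease",
                    "diabetes_with_complications",
                }
            ),
            possible=frozenset(
                {
                    "acute_kidney_injury",
                    "chronic_lung_disease",
                    "diabetes_with_complications",
                    "cerebrovascular_disease",
                }
            ),
            named_conditions=("acute_kidney_injury",),
        ),
        ScenarioFixture(
            scenario_id="D",
            truth_multimorbid=False,
            intended=frozenset({"depression", "endocrine_metabolic_disorder"}),
            possible=frozenset({"depression", "endocrine_metabolic_disorder"}),
            named_conditions=(),
        ),
        ScenarioFixture(
            scenario_id="E",
            truth_multimorbid=True,
            intended=frozenset({"pneumonia", "substance_abuse"}),
            possible=frozenset(
                {
                    "pneumonia",
                    "substance_abuse",
                    "cardiac_arrhythmia",
                    "cerebrovascular_disease",
                }
            ),
            named_conditions=("pneumonia", "substance_abuse"),
        ),
    ]


# Published per-scenario tallies the 50-trial reference dataset pins exactly:
# correct status identifications, trials with an incorrect selection, and the
# per-condition miss counts reported in the trial narrative.
_CORRECT_STATUS = {"A": 9, "B": 9, "C": 10, "D": 10, "E": 10}
_INCORRECT_PICKS = {
    # scenario -> list of (participant index, condition incorrectly selected)
    "A": [(0, "endocrine_metabolic_disorder"), (1, "acute_kidney_injury")],
    "B": [(0, "substance_abuse")],
}
_MISSES = {
    # scenario -> participant index -> conditions missed. Documented
    # reconstruction: the published per-row miss tallies are not mutually
    # consistent, so only the per-condition narrative counts are honored
    # where arithmetic allows.
    "A": {2: ["cardiac_arrhythmia"], 3: ["cardiac_arrhythmia"]},
    "B": {
        1: ["protein_calorie_malnutrition", "depression"],
        2: ["protein_calorie_malnutrition", "depression"],
        3: ["protein_calorie_malnutrition", "depression"],
        4: ["protein_calorie_malnutrition"],
        5: ["protein_calorie_malnutrition"],
        6: ["protein_calorie_malnutrition"],
        7: ["protein_calorie_malnutrition"],
        8: ["protein_calorie_malnutrition"],
        9: ["protein_calorie_malnutrition"],
    },
    "C": {1: ["acute_kidney_injury"], 2: ["acute_kidney_injury"], 3: ["acute_kidney_injury"]},
    "E": {
        0: ["pneumonia"],
        1: ["pneumonia"],
        2: ["pneumonia"],
        3: ["pneumonia"],
        4: ["pneumonia"],
        5: ["pneumonia"],
        6: ["substance_abuse"],
        7: ["substance_abuse"],
        8: ["substance_abuse"],
    },
}
# In scenarios A and B exactly one participant got the status wrong. The
# wrong call in A is assigned to the participant who incorrectly selected a
# condition completing a qualifying set (false positive); in B to a
# participant whose misses broke every qualifying set (false negative).
_WRONG_STATUS = {"A": 1, "B": 3}


def builtin_trial_records(n_participants: int = 10) -> list[TrialRecord]:
    """The 50-trial reference dataset reconstructed from published tallies.

    Predicted labels are pinned data (per-scenario correct-status counts
    9, 9, 10, 10, 10), not derived from any catalog. Per-participant timing
    was not published, so time fields are None.
    """
    scenarios = builtin_scenarios()
    records: list[TrialRecord] = []
    for fixture in scenarios:
        sid = fixture.scenario_id
        for p in range(n_participants):
            selected = set(fixture.intended)
            for idx, extra in _INCORRECT_PICKS.get(sid, []):
                if idx == p:
                    selected.add(extra)
            for missed in _MISSES.get(sid, {}).get(p, []):
                selected.discard(missed)
            correct = p != _WRONG_STATUS.get(sid)
            predicted = (
                fixture.truth_multimorbid if correct else not fixture.truth_multimorbid
            )
            records.append(
                TrialRecord(
                    participant_id=f"P{p + 1:02d}",
                    scenario_id=sid,
                    selected=frozenset(selected),
                    intended=fixture.intended,
                    truth_multimorbid=fixture.truth_multimorbid,
                    predicted_multimorbid=predicted,
                )
            )
    return records


@dataclass(frozen=True)
class RaterModel:
    """Independent per-condition error model for a synthetic rater.

    ``miss_rate``: probability a truly present condition is not selected;
    ``false_select_rate``: probability an absent catalog condition is
    selected anyway.
    """

    miss_rate: float = 0.0
    false_select_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name, rate in (
            ("miss_rate", self.miss_rate),
            ("false_select_rate", self.false_select_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")


def generate_patient(
    catalog: Catalog,
    prevalence: dict[str, float],
    seed: int | None = None,
    emit_codes: bool = False,
):
    """Draw a synthetic condition profile by independent Bernoulli sampling.

    Conditions are sampled independently (no co-occurrence model — a
    documented simplification). With ``emit_codes`` the profile is
    accompanied by one code per present condition, drawn from its code list.
    """
    from .mapper import CodedDiagnosis

    for cid, p in prevalence.items():
        if cid not in catalog.conditions:
            raise CatalogError(f"prevalence key {cid!r} not in catalog")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence for {cid!r} must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    profile = frozenset(
        cid
        for cid in catalog.conditions  # catalog order keeps draws reproducible
        if rng.random() < prevalence.get(cid, 0.0)
    )
    if not emit_codes:
        return profile
    diagnoses = []
    for cid in sorted(profile):
        codes = catalog.conditions[cid].codes
        if codes:
            entry = codes[int(rng.integers(len(codes)))]
            diagnoses.append(CodedDiagnosis(system=entry.system, code=entry.normalized))
    return profile, diagnoses


def simulate_trials(
    fixtures: list[ScenarioFixture],
    rater: RaterModel,
    n_participants: int,
    catalog: Catalog,
) -> list[TrialRecord]:
    """Simulate a participants x scenarios usability trial.

    Each participant sees each scenario; their selection is the intended set
    minus independent Bernoulli(miss_rate) drops, plus Bernoulli(
    false_select_rate) additions from the non-intended catalog conditions.
    The predicted label is the catalog classification of the selection.
    Fully reproducible from ``rater.seed``.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    rng = np.random.default_rng(rater.seed)
    records: list[TrialRecord] = []
    all_conditions = list(catalog.conditions)
    for p in range(n_participants):
        for fixture in fixtures:
            selected = {
                cid for cid in sorted(fixture.intended) if rng.random() >= rater.miss_rate
            }
            for cid in all_conditions:
                if cid not in fixture.intended and rng.random() < rater.false_select_rate:
                    selected.add(cid)
            predicted = evaluate(selected, catalog).is_multimorbid
            records.append(
                TrialRecord(
                    participant_id=f"S{p + 1:02d}",
                    scenario_id=fixture.scenario_id,
                    selected=frozenset(selected),
                    intended=fixture.intended,
                    truth_multimorbid=fixture.truth_multimorbid,
                    predicted_multimorbid=predicted,
                )
            )
    return records
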
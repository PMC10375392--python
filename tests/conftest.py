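import json

import pytest
from hypothesis import strategies as st

from qcs.catalog import Catalog, load_catalog


@pytest.fixture
def toy_doc() -> dict:
    """Minimal hand-written catalog document used across unit tests."""
    return {
        "version": "test-1",
        "conditions": [
            {
                "id": "a",
                "display_name": "Condition A",
                "organ_system": "Cardiac",
                "codes": [
                    {"system": "ICD10CM", "code": "I50.9", "match": "exact"},
                    {"system": "ICD9CM", "code": "428.0", "match": "exact"},
                ],
            },
            {
                "id": "b",
                "display_name": "Condition B",
                "organ_system": "Pulmonary",
                "codes": [{"system": "ICD10CM", "code": "J18", "match": "prefix"}],
            },
            {
                "id": "c",
                "display_name": "Condition C",
                "organ_system": "Cardiac",
                "codes": [{"system": "ICD9CM", "code": "427", "match": "prefix"}],
            },
            {
                "id": "d",
                "display_name": "Condition D",
                "organ_system": "Renal",
                "codes": [{"system": "ICD10CM", "code": "N17", "match": "prefix"}],
            },
            {
                "id": "e",
                "display_name": "Condition E",
                "organ_system": "Renal",
                "codes": [],
            },
        ],
        "sets": [["a"], ["b", "c"], ["b", "d", "e"]],
    }


@pytest.fixture
def toy_catalog(toy_doc) -> Catalog:
    return load_catalog(toy_doc)


# ---------------------------------------------------------------------------
# Hypothesis strategies for random catalogs/profiles

CONDITION_POOL = [f"c{i:02d}" for i in range(30)]


@st.composite
def catalogs(draw, max_conditions: int = 30, max_sets: int = 100) -> Catalog:
    n = draw(st.integers(min_value=1, max_value=max_conditions))
    ids = CONDITION_POOL[:n]
    sets = draw(
        st.lists(
            st.frozensets(st.sampled_from(ids), min_size=1, max_size=3),
            max_size=max_sets,
            unique=True,
        )
    )
    doc = {
        "version": "hyp",
        "conditions": [
            {"id": cid, "display_name": cid, "organ_system": f"sys{i % 4}"}
            for i, cid in enumerate(ids)
        ],
        "sets": [sorted(s) for s in sets],
    }
    return load_catalog(doc)


@st.composite
def catalog_and_profile(draw):
    catalog = draw(catalogs())
    ids = list(catalog.conditions)
    profile = draw(st.frozensets(st.sampled_from(ids), max_size=len(ids)))
    return catalog, profile


@st.composite
def catalog_and_order(draw):
    """A catalog plus a duplicate-free addition order over a subset of its ids."""
    catalog = draw(catalogs(max_conditions=15, max_sets=40))
    ids = list(catalog.conditions)
    order = draw(st.permutations(ids))
    k = draw(st.integers(min_value=0, max_value=len(order)))
    return catalog, list(order[:k])
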
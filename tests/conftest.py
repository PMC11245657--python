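"""Shared fixtures: hand-built toy panels and a small simulated world."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from synthrisk.cohort import PersonPanel, default_config, generate_population

PANEL_COLUMNS = [
    "person_id", "year", "sex", "age", "region_id", "deprivation_social",
    "deprivation_material", "charlson", "regional_budget", "index_date", "outcome",
]


def make_panel(rows: list[dict], events: list[tuple] | None = None) -> PersonPanel:
    """Build a PersonPanel from explicit row dicts (defaults filled in)."""
    defaults = {
        "sex": "male", "age": 40.0, "region_id": 1, "deprivation_social": 3,
        "deprivation_material": 3, "charlson": 0, "regional_budget": 250.0,
        "outcome": 0,
    }
    recs = []
    for i, r in enumerate(rows):
        rec = dict(defaults)
        rec.setdefault("person_id", i)
        rec.update(r)
        rec.setdefault("index_date", rec["year"] + 0.5)
        recs.append(rec)
    df = pd.DataFrame(recs)[PANEL_COLUMNS]
    ev = pd.DataFrame(
        events or [], columns=["person_id", "event_type", "event_date"]
    )
    return PersonPanel(rows=df, events=ev)


@pytest.fixture(scope="session")
def small_world():
    """A small simulated stated-world panel shared across tests."""
    cfg = default_config(n_persons=30_000, seed=11)
    return generate_population(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
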
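import numpy as np
import pandas as pd
import pytest

from vwpdpa import (
    BinGrid,
    RoiLayout,
    TrialRecord,
    compute_bin_series,
    default_timeline,
    simulate_cohort,
)
from vwpdpa.simulate import CohortSpec, DEFAULT_ITEMS, GroupLatencies, GroupSpec


@pytest.fixture(scope="session")
def timeline():
    return default_timeline()


@pytest.fixture(scope="session")
def grid(timeline):
    return BinGrid.for_timeline(timeline)


@pytest.fixture(scope="session")
def layout():
    return RoiLayout()


def trial_record_from_row(row) -> TrialRecord:
    """Build a TrialRecord from one row of a trial-metadata frame."""
    return TrialRecord(
        participant_id=row["participant_id"],
        trial_id=row["trial_id"],
        item_id=row["item_id"],
        sub_experiment=str(row["sub_experiment"]),
        condition=row["condition"],
        role_of_quadrant={q: row[f"{q}_role"] for q in ("q1", "q2", "q3", "q4")},
        clicked_role=row["clicked_role"],
        accuracy=int(row["accuracy"]),
        block=int(row.get("block", 1)),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Two groups × 5 participants, all four conditions at reduced item
    counts — enough structure for pipeline-level tests."""
    spec = CohortSpec(
        groups=(
            GroupSpec("PwNH", 5),
            GroupSpec("PwHL_low_demand", 5, GroupLatencies(late=1295.0)),
        ),
        items={k: 6 for k in DEFAULT_ITEMS},
        seed=11,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_bin_series(small_cohort, layout, grid):
    return compute_bin_series(
        small_cohort.samples, small_cohort.trials, layout, grid
    )
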
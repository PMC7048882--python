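import numpy as np
import pytest

from tscoremap import (
    ItemBank,
    ItemParameters,
    Metric,
    ProbabilitySnapshot,
    build_map,
    fit_item_from_snapshots,
    make_fixture_bank,
    make_short_form_bank,
)

# Published probability snapshots for the anxiety item "My worries
# overwhelmed me" at T=60 and T=61: the only printed anchor tying the model
# to an operational calibration.
WORKED_EXAMPLE_SNAPSHOTS = [
    (60.0, [0.089, 0.442, 0.415, 0.052, 0.002]),
    (61.0, [0.063, 0.376, 0.484, 0.073, 0.003]),
]
SYMPTOM_LABELS = ["never", "rarely", "sometimes", "often", "always"]


@pytest.fixture(scope="session")
def worked_example_snapshots():
    return [ProbabilitySnapshot(t, p) for t, p in WORKED_EXAMPLE_SNAPSHOTS]


@pytest.fixture(scope="session")
def anxiety_item(worked_example_snapshots):
    """GRM item fitted to the two published probability vectors."""
    return fit_item_from_snapshots(
        worked_example_snapshots,
        K=5,
        item_id="worries_overwhelmed",
        stem="My worries overwhelmed me",
        labels=SYMPTOM_LABELS,
    )


@pytest.fixture(scope="session")
def dichotomous_item():
    return ItemParameters(
        item_id="dich", stem="", labels=["no", "yes"], slope=1.0, thresholds=[0.0]
    )


@pytest.fixture(scope="session")
def three_cat_item():
    return ItemParameters(
        item_id="tri",
        stem="",
        labels=["low", "mid", "high"],
        slope=2.0,
        thresholds=[-1.0, 1.0],
    )


@pytest.fixture(scope="session")
def never_modal_item():
    """Low-slope item whose category 2 is never the modal response."""
    return ItemParameters(
        item_id="nm",
        stem="",
        labels=SYMPTOM_LABELS,
        slope=0.8,
        thresholds=[-0.1, 0.1, 1.5, 1.7],
    )


@pytest.fixture(scope="session")
def fixture_bank_8():
    return make_fixture_bank(n_items=8, K=5, seed=42)


@pytest.fixture(scope="session")
def short_form_4(anxiety_item):
    """Four-item short form including the published-anchor item."""
    base = make_short_form_bank(seed=5, n_items=3)
    return ItemBank(
        bank_id="short_form_4",
        items=[*base.items, anxiety_item],
        metric=Metric(),
    )


@pytest.fixture(scope="session")
def short_form_map(short_form_4):
    return build_map(short_form_4)


@pytest.fixture(scope="session")
def symmetric_bank():
    """Two identical items with thresholds symmetric about theta = 0."""
    items = [
        ItemParameters(
            item_id=f"sym_{i}",
            stem="",
            labels=SYMPTOM_LABELS,
            slope=2.0,
            thresholds=[-1.5, -0.5, 0.5, 1.5],
        )
        for i in (1, 2)
    ]
    return ItemBank(bank_id="symmetric", items=items)


@pytest.fixture(scope="session")
def theta_grid():
    return np.arange(-4.0, 4.0 + 1e-9, 0.01)
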
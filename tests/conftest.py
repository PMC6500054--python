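import pandas as pd
import pytest

from finprotect.datamodel import CANONICAL_COLUMNS, SurveyDataset


def make_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical household frame from sparse row dicts."""
    defaults = dict(
        weight=1.0,
        survey_year="2012",
        region="rural",
        household_size=1,
        total_expenditure=1000.0,
        food_expenditure=300.0,
        oop_health=0.0,
        head_sex="male",
        head_marital="married",
        head_education="primary",
        head_activity="employed",
        has_child_under5=False,
        has_elderly_over60=False,
    )
    full = []
    for i, row in enumerate(rows):
        r = dict(defaults, household_id=f"H{i:04d}")
        r.update(row)
        full.append(r)
    return pd.DataFrame(full, columns=CANONICAL_COLUMNS)


@pytest.fixture
def tiny_survey() -> SurveyDataset:
    """Ten equal-weight households with distinct expenditures, 2 with large OOP."""
    rows = [
        dict(total_expenditure=1000.0 + 100 * i, food_expenditure=300.0, oop_health=0.0)
        for i in range(10)
    ]
    rows[3]["oop_health"] = 500.0
    rows[7]["oop_health"] = 550.0  # share 550/1700 ≈ 0.32
    return SurveyDataset(make_frame(rows))


@pytest.fixture
def eleven_band_survey() -> SurveyDataset:
    """Equal-weight households with food shares 0.10..0.20 and food 100..200."""
    rows = [
        dict(
            total_expenditure=round((100.0 + 10 * i) / (0.10 + 0.01 * i), 6),
            food_expenditure=100.0 + 10 * i,
        )
        for i in range(11)
    ]
    return SurveyDataset(make_frame(rows))


@pytest.fixture(scope="session")
def synthetic_2012():
    from finprotect.synth import default_params, generate_survey

    return generate_survey(default_params("2012", n_households=1000, seed=42))
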
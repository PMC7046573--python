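import pandas as pd
import pytest

import fraxepi as fx
from fraxepi.registry import records_from_frame


@pytest.fixture(scope="session")
def tables():
    return fx.study_data.fixture_tables()


@pytest.fixture(scope="session")
def marginal_records():
    """All 1058 parsed records of the marginal-matching registry."""
    result = records_from_frame(fx.study_data.study_marginal_registry())
    assert not result.rejections
    return result.records


@pytest.fixture(scope="session")
def hip_records(marginal_records):
    retained, _ = fx.filter_eligible(marginal_records, ["hip"])
    return fx.deduplicate(retained)


@pytest.fixture(scope="session")
def population():
    return fx.study_data.population_table()


@pytest.fixture(scope="session")
def printed_hip_rates(tables):
    """Printed adjusted hip rates as an incidence-style table (open 95+
    bands carry no printed rate; treated as zero hazard)."""
    frame = tables["hip"].rename(columns={"rate_printed": "rate"})
    frame = frame[["sex", "age_lo", "age_hi", "site", "rate"]].copy()
    frame["rate"] = frame["rate"].fillna(0.0)
    return frame


def write_registry_csv(path, rows):
    columns = ["person_id", "sex", "age", "year", "icd10", "admitted",
               "surgical", "pathological", "resident", "radiograph"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path


def make_record(**overrides):
    base = dict(
        person_id="P1", sex="female", age_years=62, event_year=2015,
        site="S72.0", admitted="admitted", surgical=True,
        pathological=False, resident=True, radiograph_confirmed=True,
    )
    base.update(overrides)
    return fx.FractureRecord(**base)
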
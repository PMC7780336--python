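import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import casemix as cx

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scenario():
    """Scaled-down study-like scenario: 300 cases/month over 2011-2016."""
    return cx.preset_paper_like(monthly_volume=300, seed=11)


@pytest.fixture(scope="session")
def records(scenario):
    return cx.generate(scenario)


@pytest.fixture(scope="session")
def weight_table(scenario, records):
    return cx.build_weight_table(records, (2011, 2016), cx.fee_schedule(scenario))


@pytest.fixture(scope="session")
def medical_series(records, weight_table):
    return cx.monthly_cmi(records, weight_table, "medical")


def make_records(rows):
    """Build a minimal record table from (icd, cpt, los, charge, extras) dicts.

    Fills schema boilerplate (ids, dates, ownership) so tests can state only
    what matters.  ``month`` (YYYY-MM) or ``year`` pick the discharge month.
    """
    out = []
    for i, row in enumerate(rows):
        month = row.get("month")
        if month is None:
            month = f"{row.get('year', 2013)}-06"
        los = int(row.get("los", 3))
        discharge = pd.Period(month, "M").to_timestamp() + pd.Timedelta(days=14)
        out.append(
            {
                "record_id": row.get("record_id", f"R{i:06d}"),
                "case_id": f"P{i:06d}",
                "hospital_id": row.get("hospital_id", "PRV01"),
                "ownership": row.get("ownership", "private"),
                "admission_date": discharge - pd.Timedelta(days=los),
                "discharge_date": discharge,
                "length_of_stay": los,
                "total_charge": float(row.get("charge", 1_000_000)),
                "icd_code": row.get("icd", ""),
                "cpt_codes": row.get("cpt", ""),
            }
        )
    return pd.DataFrame(out, columns=cx.records.COLUMNS)


@pytest.fixture
def toy_weights():
    """Three medical codes (weights 0.5/1.0/2.0, medium stay) plus surgical."""
    table = pd.DataFrame(
        {
            "stratum": ["medium"] * 3 + ["surgical"] * 2,
            "code": ["AAA", "BBB", "CCC", "P1", "P2"],
            "n_cases": [30, 30, 30, 0, 0],
            "mean_charge": [5e5, 1e6, 2e6, 1.2e6, 5e5],
            "weight": [0.5, 1.0, 2.0, 1.2, 0.5],
            "capped": False,
        }
    )
    return cx.WeightTable(table=table, reference_cost_medical=1e6)
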
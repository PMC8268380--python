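import numpy as np
import pytest

from crcpath.records import InpatientRecord
from crcpath.simulate import default_config, generate_population
from crcpath.cohort import extract_cohort


def make_record(record_id="R1", dx=("153.4",), proc=("45.73",), age=60,
                sex="male", race="white", income="Q1", elective=False,
                bed="large", urban=True, teaching=False, died=False,
                los=7.0, charges=40_000.0):
    return InpatientRecord(
        record_id=record_id, dx_codes=list(dx), proc_codes=list(proc),
        age_years=age, sex=sex, race=race, income_quartile=income,
        elective=elective, bed_size=bed, urban=urban, teaching=teaching,
        died=died, los_days=los, total_charges=charges)


@pytest.fixture(scope="session")
def default_cfg_small():
    """Calibrated study-condition config at a modest n (shared, read-only)."""
    return default_config(30_000, seed=11)


@pytest.fixture(scope="session")
def small_cohort(default_cfg_small):
    """Analytic cohort extracted from 30k simulated admissions."""
    records = generate_population(default_cfg_small)
    rows, log = extract_cohort(records)
    return rows
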
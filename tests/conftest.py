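import numpy as np
import pandas as pd
import pytest

from metsyn.transitions import FIXTURE_NAMES, load_printed_matrix


@pytest.fixture(scope="session")
def printed():
    """The four published reference matrices, keyed by stratum."""
    return {name: load_printed_matrix(name) for name in FIXTURE_NAMES}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)


def make_visit(subject_id, year, age=40, sex="male", state_flags=(0, 0, 0, 0),
               **overrides):
    """One healthy-by-default check-up row; flags switch components on via
    unambiguous measurement values."""
    ow, htn, dys, hyp = state_flags
    row = {
        "subject_id": subject_id,
        "visit_year": year,
        "age": age,
        "sex": sex,
        "bmi": 28.0 if ow else 22.0,
        "sbp": 150 if htn else 120,
        "dbp": 95 if htn else 75,
        "tg": 2.5 if dys else 1.0,
        "hdl": 1.5,
        "fpg": 7.0 if hyp else 5.0,
        "pg2h": np.nan,
        "on_antihypertensive": False,
        "on_antihyperglycemic": False,
        "has_chd": False,
        "has_t1dm": False,
        "has_familial_hyperlipidemia": False,
    }
    row.update(overrides)
    return row


def make_table(rows):
    return pd.DataFrame(rows)
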
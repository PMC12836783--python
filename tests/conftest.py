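import datetime as dt

import pandas as pd
import pytest

from clinotext.config import default_config
from clinotext.corpus_io import ClinicalNote, NoteCorpus, TreatmentRecord
from clinotext.synthetic import SyntheticConfig, simulate, truth_tables

D = dt.date  # shorthand used across test modules


@pytest.fixture
def config():
    return default_config("en")


@pytest.fixture
def nl_config():
    return default_config("nl")


@pytest.fixture
def small_corpus():
    return NoteCorpus(
        [
            ClinicalNote("A", D(2020, 3, 1), "outpatient", "WHO 1\nno signs of progression"),
            ClinicalNote("A", D(2020, 1, 15), "outpatient", "intake"),
            ClinicalNote("A", D(2020, 4, 15), "outpatient", "ct shows progression of known lesions"),
            ClinicalNote("B", D(2020, 2, 10), "admission", "ECOG: 2, stable disease on imaging"),
        ]
    )


@pytest.fixture
def treatments():
    return [
        TreatmentRecord("A", "osimertinib", D(2020, 3, 1)),
        TreatmentRecord("B", "osimertinib", D(2020, 2, 10)),
    ]


@pytest.fixture(scope="session")
def clean_cohort():
    """Zero-noise 60-patient simulation shared by slower tests."""
    cfg = SyntheticConfig(n_patients=60, seed=42)
    truth, rendered = simulate(cfg)
    ps_ref, surv_ref = truth_tables(truth)
    return truth, rendered, ps_ref, surv_ref


def write_csv(path, rows, columns):
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path
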
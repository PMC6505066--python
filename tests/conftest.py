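import pandas as pd
import pytest

from ehrdays.pipeline import run_pipeline_on_tables
from ehrdays.synth import CohortConfig, generate_cohort, generate_demo_patient, simulate


@pytest.fixture(scope="session")
def demo_tables():
    return generate_demo_patient()


@pytest.fixture(scope="session")
def demo_build(demo_tables, tmp_path_factory):
    out = tmp_path_factory.mktemp("demo_build")
    return run_pipeline_on_tables(demo_tables, out)


@pytest.fixture(scope="session")
def cohort_config():
    return CohortConfig(n_patients=80, n_facilities=4, seed=11,
                        sepsis_prevalence=0.12, transfer_prob=0.2,
                        nonacute_tail_prob=0.15, icu_prob=0.35)


@pytest.fixture(scope="session")
def cohort_raw(cohort_config):
    return generate_cohort(cohort_config)


@pytest.fixture(scope="session")
def cohort_build(cohort_raw, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort_build")
    return run_pipeline_on_tables(cohort_raw, out)


@pytest.fixture(scope="session")
def messy_config():
    return CohortConfig(n_patients=60, n_facilities=3, seed=5,
                        sepsis_prevalence=0.15, transfer_prob=0.15,
                        missing_loinc_rate=0.6, lab_name_variant_rate=0.5)


@pytest.fixture(scope="session")
def messy_raw(messy_config):
    return simulate(messy_config)


@pytest.fixture(scope="session")
def messy_build(messy_raw, tmp_path_factory):
    out = tmp_path_factory.mktemp("messy_build")
    return run_pipeline_on_tables(messy_raw, out)


def gt_ssh_frame(raw) -> pd.DataFrame:
    gt = raw.ground_truth_ssh.copy()
    gt["admit_date"] = pd.to_datetime(gt["admit_date"])
    gt["discharge_date"] = pd.to_datetime(gt["discharge_date"])
    gt["sepsis"] = gt["sepsis"].astype(bool)
    return gt


def gt_day_scores(raw) -> pd.DataFrame:
    gt = raw.ground_truth_days.copy()
    gt["date"] = pd.to_datetime(gt["date"])
    for comp in ("coagulation", "liver", "cardiovascular", "renal"):
        gt[comp] = pd.array(
            [pd.NA if x in ("", None) or pd.isna(x) else int(x) for x in gt[comp]],
            dtype="Int64")
    return gt
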
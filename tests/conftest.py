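import pandas as pd
import pytest

import reportlife as rl


@pytest.fixture(scope="session")
def small_cohort():
    cfg = rl.SimConfig(n_patients=300, seed=11, mean_views_per_report=3.0)
    return rl.generate_cohort(cfg)


@pytest.fixture(scope="session")
def prepared(small_cohort):
    c = small_cohort
    return rl.prepare_logs(c.sessions, c.views, c.reports,
                           dev_user_list=c.truth["dev_users"])


@pytest.fixture(scope="session")
def classified(small_cohort, prepared):
    c = small_cohort
    return rl.classify_views(prepared.views, c.reports, c.encounters,
                             patients=c.patients, mode="grouped",
                             groups=prepared.groups,
                             report_to_group=prepared.report_to_group)


def make_views(rows):
    """rows: (view_id, session_id, report_id, request_time)"""
    return pd.DataFrame(rows, columns=["view_id", "session_id", "report_id",
                                       "request_time"])


def make_encounters(rows):
    """rows: (encounter_id, patient_id, type, start, end, main_dx)"""
    df = pd.DataFrame(rows, columns=["encounter_id", "patient_id", "type",
                                     "start", "end", "main_dx"])
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    return df
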
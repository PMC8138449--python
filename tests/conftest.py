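import logging

import numpy as np
import pytest

import ppgaf as pg

logging.getLogger("ppgaf").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def sr_record():
    cfg = pg.SimConfig(rhythm="SR", duration_s=300.0, mean_hr_bpm=70.0,
                       hrv_sd_s=0.03, seed=1)
    return pg.simulate_record(cfg)


@pytest.fixture(scope="session")
def af_record():
    cfg = pg.SimConfig(rhythm="AF", duration_s=300.0, mean_hr_bpm=84.0,
                       af_irregularity_s=0.18, seed=2)
    return pg.simulate_record(cfg)


@pytest.fixture(scope="session")
def sr_window(sr_record):
    """Preprocessed, quality-accepted 1-min SR window."""
    rec = pg.preprocess_record(sr_record)
    qw = pg.select_quality_window(rec)
    assert qw.accepted
    return rec.slice(qw.start_s, qw.end_s)


@pytest.fixture(scope="session")
def af_window(af_record):
    rec = pg.preprocess_record(af_record)
    qw = pg.select_quality_window(rec)
    assert qw.accepted
    return rec.slice(qw.start_s, qw.end_s)


@pytest.fixture(scope="session")
def small_cohort_table():
    """Feature table of a 20+20 default cohort."""
    recs = pg.simulate_cohort(20, 20, seed=5)
    return pg.cohort_feature_table(recs)


@pytest.fixture(scope="session")
def full_cohort_table():
    """Feature table of the full-size default cohort (169 AF + 190 SR)."""
    recs = pg.simulate_cohort(169, 190, seed=73)
    return pg.cohort_feature_table(recs)


@pytest.fixture(scope="session")
def full_cohort_xy(full_cohort_table):
    return pg.modeling_frame(full_cohort_table)
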
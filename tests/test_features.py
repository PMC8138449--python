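import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ppgaf as pg
from ppgaf.records import PpgRecord

from .oracles import (
    ac_profile_oracle,
    cosen_oracle,
    rmssd_oracle,
    sampen_oracle,
    tpr_oracle,
)

finite_series = st.lists(
    st.floats(min_value=-10, max_value=10, allow_nan=False), min_size=5, max_size=60
)


class TestElementaryFeatures:
    def test_trivial_values(self):
        assert pg.mean_of([0.8, 0.8, 0.8]) == pytest.approx(0.8)
        assert pg.mean_of([1, 2, 3]) == pytest.approx(2.0)
        assert math.isnan(pg.mean_of([]))
        assert pg.rmssd([1.0, 1.0, 1.0]) == 0.0
        assert pg.rmssd([0.8, 1.0, 0.8, 1.0]) == pytest.approx(0.2)
        assert math.isnan(pg.rmssd([1.0]))
        assert pg.turning_point_ratio(np.arange(10)) == 0.0
        assert pg.turning_point_ratio([1, 2, 1, 2, 1, 2]) == 100.0
        assert math.isnan(pg.turning_point_ratio([1, 2]))

    def test_ties_are_not_turning_points(self):
        assert pg.turning_point_ratio([1, 2, 2, 1, 1]) == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(finite_series)
    def test_rmssd_matches_oracle(self, xs):
        assert pg.rmssd(xs) == pytest.approx(rmssd_oracle(xs), abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(finite_series)
    def test_tpr_matches_oracle_and_bounds(self, xs):
        v = pg.turning_point_ratio(xs)
        assert v == pytest.approx(tpr_oracle(xs), abs=1e-12)
        assert 0.0 <= v <= 100.0

    def test_tpr_iid_expectation_two_thirds(self):
        """For IID continuous sequences the expected TPR is 200/3."""
        rng = np.random.default_rng(42)
        vals = [pg.turning_point_ratio(rng.normal(size=1000)) for _ in range(200)]
        assert np.mean(vals) == pytest.approx(200.0 / 3.0, abs=2.0)


class TestSampleEntropy:
    def test_constant_series_zero_entropy(self):
        assert pg.sample_entropy(np.full(50, 1.3), m=2, r=0.1) == 0.0

    def test_alternating_series_matches_oracle(self):
        x = [1, 2, 1, 2, 1, 2, 1, 2]
        assert pg.sample_entropy(x, m=1, r=0.1) == pytest.approx(
            sampen_oracle(x, 1, 0.1), abs=1e-12)

    def test_random_series_matches_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        r = 0.2 * x.std()
        assert pg.sample_entropy(x, m=2, r=r) == pytest.approx(
            sampen_oracle(list(x), 2, r), abs=1e-12)

    def test_degenerate_inputs_are_nan(self):
        assert math.isnan(pg.sample_entropy([1, 2], m=2, r=0.1))
        assert math.isnan(pg.sample_entropy([1, 2, 3, 4], m=1, r=-1.0))


class TestCosen:
    def test_constant_intervals_closed_form(self):
        # SampEn = 0, so COSEn = ln(0.06) - ln(0.8)
        expected = math.log(0.06) - math.log(0.8)
        assert pg.cosen(np.full(30, 0.8)) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-2.590, abs=1e-3)

    def test_tolerance_shift_matches_oracle(self):
        rng = np.random.default_rng(9)
        pin = rng.uniform(0.6, 1.0, size=60)
        for r in (0.03, 0.06):
            assert pg.cosen(pin, r_s=r) == pytest.approx(
                cosen_oracle(pin, 1, r), abs=1e-12)

    def test_af_windows_exceed_sr_windows(self, small_cohort_table):
        g = small_cohort_table.groupby("label")["PIN_COSEn"].mean()
        assert g["AF"] > g["SR"]

    def test_too_few_intervals_nan(self):
        assert math.isnan(pg.cosen(np.full(5, 0.8)))


class TestAcProfile:
    def test_lag_zero_is_one(self):
        rng = np.random.default_rng(1)
        prof = pg.ac_profile(rng.normal(size=500), max_lag=50)
        assert prof.r[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.abs(prof.r) <= 1.0 + 1e-12)

    def test_sinusoid_truncated_sum_closed_form(self):
        """With the 1/N normalization, r[P] = 1 - P/N and
        r[P/2] = -(1 - P/(2N)) for a full-period sinusoid."""
        P, N = 64, 7680
        x = np.sin(2 * np.pi * np.arange(N) / P)
        prof = pg.ac_profile(x, max_lag=P)
        assert prof.r[P] == pytest.approx(1 - P / N, abs=1e-3)
        assert prof.r[P // 2] == pytest.approx(-(1 - P / (2 * N)), abs=1e-3)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        prof = pg.ac_profile(x, max_lag=40)
        np.testing.assert_allclose(prof.r, ac_profile_oracle(list(x), 40),
                                   atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pg.ac_profile(np.full(100, 2.0), max_lag=10)


class TestAcFeature:
    def test_white_noise_ac_is_small(self):
        rng = np.random.default_rng(7)
        vals = [pg.ac_feature(rng.normal(size=7680), fs_hz=128.0)
                for _ in range(5)]
        assert np.mean(vals) < 3.0

    def test_white_noise_profile_bound(self):
        rng = np.random.default_rng(8)
        r_abs = np.mean([np.abs(pg.ac_profile(rng.normal(size=7680), 1280).r[10:])
                         for _ in range(5)], axis=0)
        assert r_abs.max() < 0.08

    def test_scale_and_offset_invariance(self, sr_window):
        base = pg.ac_feature(sr_window)
        scaled = pg.ac_feature(3.0 * sr_window.samples + 10.0, fs_hz=sr_window.fs_hz)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_sr_exceeds_af_over_paired_seeds(self):
        diffs = []
        for seed in range(20):
            ac = {}
            for rhythm in ("SR", "AF"):
                cfg = pg.SimConfig(rhythm=rhythm, duration_s=90.0, seed=seed,
                                   noise_sd=0.03)
                rec = pg.preprocess_record(pg.simulate_record(cfg))
                ac[rhythm] = pg.ac_feature(rec.slice(0, 60))
            diffs.append(ac["SR"] - ac["AF"])
        assert np.mean(diffs) > 0
        assert np.mean([d > 0 for d in diffs]) >= 0.95

    def test_ac_decreases_with_morphology_variability(self):
        means = []
        for mv in (0.0, 0.4, 0.8):
            vals = []
            for seed in range(10):
                cfg = pg.SimConfig(rhythm="SR", duration_s=90.0, seed=seed,
                                   morph_var=mv)
                rec = pg.preprocess_record(pg.simulate_record(cfg))
                vals.append(pg.ac_feature(rec.slice(0, 60)))
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]


class TestExtractFeatures:
    def test_clean_sr_window_fully_populated(self, sr_window):
        fv = pg.extract_features(sr_window)
        d = fv.as_dict()
        assert fv.analyzable
        assert all(np.isfinite(d[k]) for k in pg.FEATURE_NAMES)
        assert 0 <= fv.PIN_TPR <= 100 and 0 <= fv.AMP_TPR <= 100
        assert 0 <= fv.AC <= 100

    def test_flat_window_unanalyzable(self):
        win = PpgRecord(np.zeros(60 * 128), 128.0)
        fv = pg.extract_features(win)
        assert not fv.analyzable
        assert all(math.isnan(fv.as_dict()[k]) for k in pg.FEATURE_NAMES)

    def test_ac_computed_without_pulse_detection(self, sr_window):
        """Suppressing the pulse detector leaves AC untouched."""
        full = pg.extract_features(sr_window)
        no_pulses = pg.extract_features(sr_window,
                                        detector=lambda w: np.empty(0))
        assert no_pulses.AC == full.AC
        assert math.isnan(no_pulses.PIN_mean) and math.isnan(no_pulses.AMP_mean)
        assert no_pulses.analyzable  # AC alone keeps the window usable

    def test_group_directions_on_small_cohort(self, small_cohort_table):
        g = small_cohort_table.groupby("label")[list(pg.FEATURE_NAMES)].mean()
        higher_in_af = ["PIN_RMSSD", "PIN_AFE", "PIN_COSEn", "PIN_TPR",
                        "AMP_RMSSD", "AMP_SampEn", "AMP_TPR"]
        lower_in_af = ["PIN_mean", "AMP_mean", "AC"]
        for f in higher_in_af:
            assert g.loc["AF", f] > g.loc["SR", f], f
        for f in lower_in_af:
            assert g.loc["AF", f] < g.loc["SR", f], f
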
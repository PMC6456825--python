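"""Generators: rhythm statistics, ground-truth bookkeeping, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ppgaf as p
from ppgaf.synth import RR_MAX_MS, RR_MIN_MS, ParameterError, _series_from_intervals


class TestSinus:
    def test_zero_noise_is_exactly_periodic(self):
        rr = p.simulate_rr_sinus(60, 800, 0, 0, 0, seed=123)
        assert np.all(rr.intervals == 800.0)
        assert rr.n_beats == 75  # 75 beats cover the minute at 800 ms
        assert rr.rhythm_truth == "sinus"

    def test_interval_sd_matches_generative_model(self):
        # Monte-Carlo: SD of generated intervals should sit near the nominal
        # 30 ms Gaussian component plus the 20 ms respiratory modulation
        sds = [p.simulate_rr_sinus(60, 800, 30, 0.25, 20, seed=s).intervals.std()
               for s in range(1000)]
        assert 20.0 < float(np.mean(sds)) < 50.0

    def test_seed_determinism(self):
        a = p.simulate_rr_sinus(60, 800, 30, 0.25, 20, seed=5)
        b = p.simulate_rr_sinus(60, 800, 30, 0.25, 20, seed=5)
        assert np.array_equal(a.intervals, b.intervals)

    @pytest.mark.parametrize("kwargs", [
        {"duration_s": 0}, {"mean_rr_ms": 200}, {"mean_rr_ms": 2000},
        {"sdnn_ms": -1},
    ])
    def test_parameter_validation(self, kwargs):
        with pytest.raises(ParameterError):
            p.simulate_rr_sinus(**{"duration_s": 60, "mean_rr_ms": 800,
                                   "sdnn_ms": 30, **kwargs})


class TestAF:
    def test_serially_uncorrelated(self):
        # i.i.d. draws: lag-1 autocorrelation near zero across replicates
        acs = []
        for s in range(1000):
            x = p.simulate_rr_af(60, 750, 350, seed=s).intervals
            x = x - x.mean()
            acs.append(float(np.dot(x[:-1], x[1:]) / np.dot(x, x)))
        assert -0.2 < float(np.mean(acs)) < 0.2
        assert np.percentile(np.abs(acs), 90) < 0.3

    def test_high_coefficient_of_variation(self):
        cvs = [np.std(p.simulate_rr_af(60, 750, 350, seed=s).intervals)
               / np.mean(p.simulate_rr_af(60, 750, 350, seed=s).intervals)
               for s in range(50)]
        assert min(cvs) > 0.15

    def test_seed_determinism_and_bounds(self):
        a = p.simulate_rr_af(60, 750, 350, seed=9)
        b = p.simulate_rr_af(60, 750, 350, seed=9)
        assert np.array_equal(a.intervals, b.intervals)
        assert a.intervals.min() >= RR_MIN_MS
        assert a.intervals.max() <= RR_MAX_MS
        assert a.rhythm_truth == "af"

    def test_mean_below_refractory_rejected(self):
        with pytest.raises(ParameterError):
            p.simulate_rr_af(60, 300, 350, seed=0)


class TestFlutter:
    @pytest.mark.parametrize("cycle,ratio,expected", [(200, 2, 400.0),
                                                      (250, 3, 750.0)])
    def test_regular_ventricular_response(self, cycle, ratio, expected):
        rr = p.simulate_rr_flutter(60, cycle, ratio)
        assert np.all(rr.intervals == expected)
        assert rr.intervals.std() == 0.0  # zero variance by construction
        assert rr.rhythm_truth == "flutter"

    def test_invalid_conduction_ratio(self):
        with pytest.raises(ParameterError):
            p.simulate_rr_flutter(60, 200, 1)


class TestEctopy:
    def test_ventricular_compensatory_conserves_pair_sum(self):
        rr = _series_from_intervals(np.full(30, 800.0), "sinus")
        out = p.inject_ectopy(rr, "ventricular", 1, 0.6, seed=1)
        i = int(np.flatnonzero(out.ectopic_flags)[0]) - 1
        assert out.intervals[i] == pytest.approx(480.0)
        assert out.intervals[i] + out.intervals[i + 1] == pytest.approx(1600.0)

    def test_atrial_non_compensatory_shortens_pair(self):
        rr = _series_from_intervals(np.full(30, 800.0), "sinus")
        out = p.inject_ectopy(rr, "atrial", 1, 0.6, seed=1)
        i = int(np.flatnonzero(out.ectopic_flags)[0]) - 1
        assert out.intervals[i] + out.intervals[i + 1] < 1600.0

    def test_zero_ectopics_is_identity(self):
        rr = p.simulate_rr_sinus(seed=2)
        assert p.inject_ectopy(rr, "atrial", 0) is rr

    def test_rhythm_label_and_flag_count(self):
        rr = p.simulate_rr_sinus(seed=3)
        out = p.inject_ectopy(rr, "atrial", 5, seed=4)
        assert out.rhythm_truth == "sinus"
        assert out.ectopic_flags.sum() == 5


class TestRendering:
    def test_ecg_maxima_at_beat_times(self):
        rr = p.simulate_rr_sinus(60, 800, 0, 0, 0, seed=1)
        w = p.render_ecg(rr, noise_sd=0.0)
        for tb in rr.beat_times:
            c = int(round(tb * w.fs))
            lo, hi = max(c - 50, 0), min(c + 50, w.samples.size)
            peak = lo + int(np.argmax(w.samples[lo:hi]))
            assert abs(peak - tb * w.fs) <= 1.0

    def test_ppg_maxima_at_beat_times(self):
        rr = p.simulate_rr_sinus(60, 800, 0, 0, 0, seed=1)
        w = p.render_ppg(rr, noise_sd=0.0)
        for tb in rr.beat_times[1:-1]:
            c = int(round(tb * w.fs))
            lo, hi = c - 6, c + 7
            peak = lo + int(np.argmax(w.samples[lo:hi]))
            assert abs(peak - tb * w.fs) <= 2.0

    def test_render_determinism(self):
        rr = p.simulate_rr_af(seed=4)
        assert np.array_equal(p.render_ecg(rr, seed=5).samples,
                              p.render_ecg(rr, seed=5).samples)
        assert np.array_equal(p.render_ppg(rr, seed=5).samples,
                              p.render_ppg(rr, seed=5).samples)

    def test_sample_count_matches_rate(self):
        rr = p.simulate_rr_sinus(seed=1)
        w = p.render_ppg(rr, fs=30)
        assert w.samples.size == round(30 * w.duration_s)

    def test_undersampled_rates_rejected(self):
        rr = p.simulate_rr_sinus(seed=1)
        with pytest.raises(ParameterError):
            p.render_ecg(rr, fs=100)
        with pytest.raises(ParameterError):
            p.render_ppg(rr, fs=20)


class TestCorrupt:
    def test_zero_duration_is_identity(self, clean_sinus_800):
        _, ppg, _ = clean_sinus_800
        assert p.corrupt(ppg, "flatline", 10, 0) is ppg

    def test_window_outside_record_rejected(self, clean_sinus_800):
        _, ppg, _ = clean_sinus_800
        with pytest.raises(ParameterError):
            p.corrupt(ppg, "flatline", 50, 30)

    def test_untouched_outside_window(self, clean_sinus_800):
        _, ppg, _ = clean_sinus_800
        out = p.corrupt(ppg, "motion_burst", 20, 10, seed=1)
        n0, n1 = int(20 * ppg.fs), int(30 * ppg.fs)
        assert np.array_equal(out.samples[:n0], ppg.samples[:n0])
        assert np.array_equal(out.samples[n1:], ppg.samples[n1:])
        assert not np.array_equal(out.samples[n0:n1], ppg.samples[n0:n1])


class TestInvariants:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=RR_MIN_MS, max_value=RR_MAX_MS),
                    min_size=1, max_size=200))
    def test_interval_time_duality(self, intervals):
        rr = _series_from_intervals(np.array(intervals), "sinus")
        rebuilt = np.concatenate([[rr.beat_times[0]],
                                  rr.beat_times[0] + np.cumsum(rr.intervals) / 1000.0])
        assert np.allclose(rebuilt, rr.beat_times, atol=1e-9)

    @pytest.mark.parametrize("gen", [
        lambda s: p.simulate_rr_sinus(seed=s),
        lambda s: p.simulate_rr_af(seed=s),
        lambda s: p.simulate_rr_flutter(),
    ])
    def test_duration_coverage_and_bounds(self, gen):
        rr = gen(42)
        assert rr.intervals.sum() / 1000.0 >= 60.0 - rr.intervals.max() / 1000.0
        assert rr.intervals.min() >= RR_MIN_MS
        assert rr.intervals.max() <= RR_MAX_MS

    def test_rhythm_separation_normalized_rmssd(self):
        # the statistical structure the classifier exploits: AF and sinus
        # normalized-RMSSD distributions essentially do not overlap
        def nrmssd(rr):
            d = np.diff(rr.intervals)
            return np.sqrt(np.mean(d**2)) / rr.intervals.mean()

        af = np.array([nrmssd(p.simulate_rr_af(seed=s)) for s in range(300)])
        si = np.array([nrmssd(p.simulate_rr_sinus(seed=s)) for s in range(300)])
        assert np.quantile(af, 0.025) > np.quantile(si, 0.975)


class TestCohort:
    def test_counts_and_prevalence(self):
        cfg = p.CohortConfig(n_subjects=200, af_prevalence=0.5, seed=42)
        cohort = p.simulate_cohort(cfg, render=False)
        assert len(cohort.subjects) == 200
        assert sum(s.gold == "af" for s in cohort.subjects) == 100
        assert cohort.n_measurements == 600

    def test_zero_prevalence_degenerate(self):
        cfg = p.CohortConfig(n_subjects=10, af_prevalence=0.0, seed=1)
        cohort = p.simulate_cohort(cfg, render=False)
        assert all(s.gold == "no_af" for s in cohort.subjects)

    def test_flutter_fraction_applies_to_af_subjects(self):
        cfg = p.CohortConfig(n_subjects=60, af_prevalence=0.5,
                             flutter_fraction=1.0, seed=3)
        cohort = p.simulate_cohort(cfg, render=False)
        af = [s for s in cohort.subjects if s.gold == "af"]
        assert all(s.rhythm == "flutter" for s in af)

    def test_serialization_round_trip_byte_identical(self, tmp_path):
        cfg = p.CohortConfig(n_subjects=3, af_prevalence=0.5,
                             artifact_rate=0.3, seed=11)
        cohort = p.simulate_cohort(cfg)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p.save_cohort(cohort, d1)
        p.save_cohort(p.simulate_cohort(cfg), d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()
        loaded = p.load_cohort(d1)
        orig = cohort.subjects[0].measurements[0]
        back = loaded.subjects[0].measurements[0]
        assert np.array_equal(orig.ppg.samples, back.ppg.samples)
        assert np.array_equal(orig.rr.intervals, back.rr.intervals)
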
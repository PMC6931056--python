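import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitbeep import GaitProfile, reference_profile, reference_summary, simulate_session, stride_waveform
from gaitbeep.errors import ParameterError, ProfileLookupError
from gaitbeep.simulate import _GoodPeakSampler


class TestStrideWaveform:
    def test_construction_peak_minus_300(self):
        p = GaitProfile()
        w = stride_waveform(p, -300.0, 1.2, 100.0)
        assert len(w) == 120
        assert w.min() == pytest.approx(-300.0, rel=0.01)

    def test_shallow_peak_minus_48(self):
        w = stride_waveform(GaitProfile(), -48.0, 0.857, 100.0)
        assert w.min() == pytest.approx(-48.0, rel=0.01)

    def test_non_negative_peak_rejected(self):
        with pytest.raises(ParameterError):
            stride_waveform(GaitProfile(), 10.0, 1.0, 100.0)
        with pytest.raises(ParameterError):
            stride_waveform(GaitProfile(), -300.0, 0.0, 100.0)

    @given(peak=st.floats(-500, -30), dur=st.floats(0.45, 1.6),
           fs=st.sampled_from([50.0, 100.0, 200.0]))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_numerical_min_matches_requested_peak(self, peak, dur, fs):
        """Brute-force minimum over the returned samples equals the peak."""
        w = stride_waveform(GaitProfile(), peak, dur, fs)
        assert len(w) == round(dur * fs)
        assert min(w) == pytest.approx(peak, rel=0.01)
        # exactly one local minimum dips below half the requested peak
        deep = w < peak / 2
        runs = np.flatnonzero(np.diff(deep.astype(int)) == 1)
        assert deep.sum() >= 1 and len(runs) <= 1


class TestSimulateSession:
    def test_step_count_tracks_cadence(self):
        p = GaitProfile(cadence=100.0, bout_plan=[(60.0, 0.0)], seed=5)
        _, truth = simulate_session(p)
        assert abs(truth.n_steps - 100) <= 1

    def test_all_good_when_p_good_is_one(self):
        p = GaitProfile(p_good=1.0, bout_plan=[(30.0, 0.0)], seed=2)
        _, truth = simulate_session(p)
        assert truth.is_good.all()

    def test_none_good_when_p_good_is_zero(self):
        p = GaitProfile(p_good=0.0, bout_plan=[(30.0, 0.0)], seed=2)
        _, truth = simulate_session(p)
        assert not truth.is_good.any()

    def test_same_seed_bitwise_identical(self):
        p = GaitProfile(seed=99, bout_plan=[(20.0, 0.0)])
        s1, t1 = simulate_session(p)
        s2, t2 = simulate_session(p)
        np.testing.assert_array_equal(s1.gyro, s2.gyro)
        np.testing.assert_array_equal(s1.accel, s2.accel)
        np.testing.assert_array_equal(t1.heel_strike_times, t2.heel_strike_times)
        np.testing.assert_array_equal(t1.true_peak_av, t2.true_peak_av)

    def test_session_duration_matches_bout_plan(self):
        p = GaitProfile(bout_plan=[(30.0, 10.0), (45.5, 0.0)], seed=1)
        series, truth = simulate_session(p)
        assert series.duration == pytest.approx(85.5, abs=1 / series.sample_rate)
        assert truth.bout_intervals == [(0.0, 30.0), (40.0, 85.5)]

    def test_rest_intervals_contain_only_noise(self):
        p = GaitProfile(bout_plan=[(20.0, 10.0), (20.0, 0.0)], noise_sd=1.0, seed=3)
        series, _ = simulate_session(p)
        av = series.gyro[:, 1]
        rest = av[int(21.0 * series.sample_rate):int(29.0 * series.sample_rate)]
        assert np.abs(rest).max() < 6.0  # pure noise, no stride lobes

    def test_invalid_profiles_rejected(self):
        for bad in [dict(cadence=0), dict(av_mean=10), dict(p_good=1.5),
                    dict(bout_plan=[]), dict(bad_attenuation=0.0),
                    dict(noise_sd=-1)]:
            with pytest.raises(ParameterError):
                GaitProfile(**bad).validate()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_ground_truth_invariants_hold(self, seed):
        """Random profiles always yield a self-consistent answer key."""
        rng = np.random.default_rng(seed)
        p = GaitProfile(
            cadence=float(rng.uniform(50, 130)),
            av_mean=float(rng.uniform(-300, -110)),
            av_sd=float(rng.uniform(0, 50)),
            p_good=float(rng.uniform(0, 1)),
            noise_sd=float(rng.uniform(0, 10)),
            bout_plan=[(float(rng.uniform(5, 15)), 0.0)],
            seed=seed,
        )
        series, truth = simulate_session(p)
        series.validate()
        truth.validate(p.threshold_av)

    def test_good_peak_mean_converges_to_profile_mean(self):
        p = GaitProfile(p_good=1.0, bout_plan=[(400.0, 0.0)], seed=11)
        _, truth = simulate_session(p)
        n = truth.n_steps
        assert n >= 500
        assert truth.true_peak_av.mean() == pytest.approx(
            p.av_mean, abs=3 * p.av_sd / np.sqrt(n))

    def test_ground_truth_cv_converges_to_profile_cv(self):
        p = GaitProfile(av_mean=-150.0, av_sd=30.0, p_good=1.0,
                        bout_plan=[(660.0, 0.0)], seed=8)
        _, truth = simulate_session(p)
        assert truth.n_steps >= 1000
        cv = 100 * truth.true_peak_av.std(ddof=1) / abs(truth.true_peak_av.mean())
        assert cv == pytest.approx(20.0, abs=1.5)


class TestGoodPeakSampler:
    def test_moment_matching_under_truncation(self):
        sampler = _GoodPeakSampler(-150.0, 30.0, upper=-105.0)
        rng = np.random.default_rng(0)
        draws = np.array([sampler.draw(rng) for _ in range(20000)])
        assert draws.max() <= -105.0
        assert draws.mean() == pytest.approx(-150.0, abs=0.7)
        assert draws.std(ddof=1) == pytest.approx(30.0, abs=0.7)

    def test_infeasible_target_falls_back_to_rejection(self):
        sampler = _GoodPeakSampler(-80.0, 40.0, upper=-105.0)
        rng = np.random.default_rng(0)
        draws = np.array([sampler.draw(rng) for _ in range(2000)])
        assert draws.max() <= -105.0


class TestReferenceProfiles:
    def test_most_impaired_persona_pre_training(self):
        p = reference_profile("A", "pre", "without")
        assert p.cadence == 70 and p.av_mean == -48 and p.p_good == 0.0

    def test_best_persona_post_training(self):
        p = reference_profile("F", "post", "without")
        assert p.cadence == 110 and p.av_mean == -250 and p.p_good == 0.99

    def test_av_sd_derived_from_cv(self):
        p = reference_profile("E", "pre", "without")
        assert p.av_sd == pytest.approx(165 * 0.24)

    def test_unknown_persona_raises(self):
        with pytest.raises(ProfileLookupError):
            reference_profile("Z", "pre", "without")
        with pytest.raises(ProfileLookupError):
            reference_summary("A", "mid", "without")
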
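"""Windowing, heart-rate-band amplitude extraction, and trend features."""

import numpy as np
import pytest

from ppgloss import (AMHRSeries, HRBand, PPGRecord, RecordError, SimConfig,
                     WindowScheme, amhr_from_sequence, extract_sequences,
                     featurize_record, simulate_record, trend_features,
                     truncate_record)


def tone_record(duration=600.0, **kw):
    base = dict(duration_s=duration, channel_noise_sd=(0.0,),
                resp_mod_frac=0.0, wander_amp=0.0, n_harmonics=0,
                amp_decay_frac=0.0, hr_hz=1.2, seed=0)
    base.update(kw)
    return simulate_record(SimConfig(**base))


class TestSequences:
    def test_default_scheme_on_600s_record(self):
        seqs = extract_sequences(tone_record(600.0), channel=0)
        assert [s for s, _ in seqs] == [0.0, 120.0, 240.0, 360.0, 480.0]
        assert all(x.size == 120 * 80 for _, x in seqs)

    def test_short_record_rejected(self):
        with pytest.raises(RecordError, match="too short"):
            extract_sequences(tone_record(130.0), channel=0)

    def test_custom_start_times(self):
        scheme = WindowScheme(starts_s=(0.0, 300.0))
        seqs = extract_sequences(tone_record(600.0), scheme, channel=0)
        assert [s for s, _ in seqs] == [0.0, 300.0]


class TestAMHR:
    def test_unit_tone_amplitude(self):
        seq = tone_record(480.0).channel(0)[: 120 * 80]
        assert amhr_from_sequence(seq, 80.0) == pytest.approx(1.0, rel=0.05)

    def test_zero_signal(self):
        assert amhr_from_sequence(np.zeros(120 * 80), 80.0) == pytest.approx(0.0, abs=1e-9)

    def test_decaying_envelope_time_average(self):
        # envelope falls 1.0 -> 0.8 across the sequence; the mean AM_HR is
        # the time-average of the envelope, about 0.9
        t = np.arange(120 * 80) / 80.0
        env = 1.0 - 0.2 * t / 120.0
        seq = env * np.sin(2 * np.pi * 1.2 * t)
        assert amhr_from_sequence(seq, 80.0) == pytest.approx(0.9, rel=0.05)

    def test_band_above_nyquist_rejected(self):
        from ppgloss.exceptions import ConfigError
        with pytest.raises(ConfigError, match="Nyquist"):
            amhr_from_sequence(np.zeros(120 * 80), 80.0,
                               band=HRBand(f_lo=0.66, f_hi=11.0))


class TestTrendFeatures:
    def test_collinear_series_closed_form(self):
        series = AMHRSeries(times=[0.0, 120.0, 240.0, 360.0],
                            values=[5.0, 4.9, 4.8, 4.7])
        v = trend_features(series)
        assert v.slope == pytest.approx(-1.0 / 1200.0, abs=1e-12)
        assert v.r2 == pytest.approx(1.0, abs=1e-12)
        assert v.abs_change == pytest.approx(-0.3, abs=1e-12)
        assert v.pct_change == pytest.approx(-6.0, abs=1e-10)

    def test_constant_series_has_no_trend(self):
        v = trend_features(AMHRSeries(times=[0, 1, 2, 3], values=[2, 2, 2, 2]))
        assert (v.slope, v.r2, v.abs_change, v.pct_change) == (0, 0, 0, 0)

    def test_ols_matches_normal_equations_oracle(self):
        times = np.array([0.0, 120.0, 240.0, 360.0, 480.0])
        values = np.array([3.0, 3.4, 2.9, 3.3, 2.8])
        v = trend_features(AMHRSeries(times=times, values=values))
        # independent oracle: solve the normal equations directly
        A = np.array([[len(times), times.sum()],
                      [times.sum(), (times ** 2).sum()]])
        b = np.array([values.sum(), (times * values).sum()])
        intercept, slope = np.linalg.solve(A, b)
        fitted = intercept + slope * times
        r2 = 1.0 - ((values - fitted) ** 2).sum() / \
            ((values - values.mean()) ** 2).sum()
        assert v.slope == pytest.approx(slope, abs=1e-10)
        assert v.r2 == pytest.approx(r2, abs=1e-10)

    def test_zero_first_value_rejected(self):
        with pytest.raises(RecordError, match="percentage change"):
            trend_features(AMHRSeries(times=[0, 1], values=[0.0, 1.0]))

    def test_time_reversal_antisymmetry(self):
        series = AMHRSeries(times=[0.0, 60.0, 120.0, 180.0],
                            values=[3.0, 2.5, 2.6, 2.0])
        rev = AMHRSeries(times=series.times, values=series.values[::-1])
        v, w = trend_features(series), trend_features(rev)
        assert w.slope == pytest.approx(-v.slope, abs=1e-12)
        assert w.abs_change == pytest.approx(-v.abs_change, abs=1e-12)
        assert w.r2 == pytest.approx(v.r2, abs=1e-12)
        assert np.sign(w.pct_change) == -np.sign(v.pct_change)


class TestFeaturizeRecord:
    def test_euvolemic_record_has_flat_trend(self):
        rec = simulate_record(SimConfig(duration_s=600.0, amp_decay_frac=0.0,
                                        seed=11))
        v = featurize_record(rec).vector
        assert abs(v.pct_change) < 5.0

    def test_blood_loss_record_recovers_decay(self):
        rec = simulate_record(SimConfig(duration_s=600.0, amp_decay_frac=0.5,
                                        seed=12))
        res = featurize_record(rec)
        v = res.vector
        assert v.slope < 0
        # sequence centers span 60..540 s of a 600 s linear decay, so the
        # endpoint change is 0.5 * (540-60)/600 / (1 - 0.5*60/600) = -42%
        assert v.pct_change == pytest.approx(-42.1, abs=10.0)
        assert res.series.values.shape == (5,)
        assert res.channel_index == 0

    def test_short_record_propagates_error(self):
        with pytest.raises(RecordError, match="too short"):
            featurize_record(tone_record(130.0))

    def test_scale_equivariance(self):
        rec = simulate_record(SimConfig(duration_s=480.0, amp_decay_frac=0.3,
                                        seed=13, channel_noise_sd=(0.01,)))
        scaled = PPGRecord(fs=rec.fs, samples=7.5 * rec.samples,
                           channel_ids=list(rec.channel_ids))
        v = featurize_record(rec).vector
        w = featurize_record(scaled).vector
        assert w.slope == pytest.approx(7.5 * v.slope, rel=1e-6)
        assert w.abs_change == pytest.approx(7.5 * v.abs_change, rel=1e-6)
        assert w.r2 == pytest.approx(v.r2, rel=1e-6)
        assert w.pct_change == pytest.approx(v.pct_change, rel=1e-6)


class TestTruncate:
    def test_truncation(self):
        rec = tone_record(1200.0)
        out = truncate_record(rec, 600.0)
        assert out.duration_s == pytest.approx(600.0)
        assert out.meta["truncated_to_s"] == 600.0
        assert np.array_equal(out.samples, rec.samples[: 600 * 80])

    def test_truncate_to_minimum_duration(self):
        out = truncate_record(tone_record(1200.0), 240.0)
        assert out.duration_s == pytest.approx(240.0)
        with pytest.raises(RecordError):
            truncate_record(tone_record(1200.0), 239.0)

    def test_truncation_beyond_length_is_flagged_noop(self):
        rec = tone_record(480.0)
        with pytest.warns(UserWarning, match="no-op"):
            out = truncate_record(rec, 2000.0)
        assert out.meta.get("truncation_noop") is True
        assert np.array_equal(out.samples, rec.samples)
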
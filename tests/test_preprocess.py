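import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

import fnirslat as fl
from fnirslat.preprocess import (
    DEFAULT_BANDS,
    baseline_correct,
    mbll_forward,
)


# --------------------------------------------------------------------------
# reference implementation of the published motion-correction algorithm,
# transcribed independently as the oracle for the package's tddr


def tddr_reference(signal, sample_rate):
    signal = np.array(signal, dtype=float)
    filter_cutoff = 0.5
    filter_order = 3
    Fc = filter_cutoff * 2 / sample_rate
    signal_mean = np.mean(signal)
    signal -= signal_mean
    if Fc < 1:
        fb, fa = sps.butter(filter_order, Fc)
        signal_low = sps.filtfilt(fb, fa, signal, padlen=12)
    else:
        signal_low = signal
    signal_high = signal - signal_low
    tune = 4.685
    D = np.sqrt(np.finfo(signal.dtype).eps)
    deriv = np.diff(signal_low)
    w = np.ones(deriv.shape)
    mu = np.inf
    for _ in range(50):
        mu0 = mu
        mu = np.sum(w * deriv) / np.sum(w)
        dev = np.abs(deriv - mu)
        sigma = 1.4826 * np.median(dev)
        if sigma == 0:
            break
        r = dev / (sigma * tune)
        w = ((1 - r**2) * (r < 1)) ** 2
        if abs(mu - mu0) < D * max(abs(mu), abs(mu0)):
            break
    new_deriv = w * (deriv - mu)
    signal_low_corrected = np.cumsum(np.insert(new_deriv, 0, 0))
    return signal_low_corrected + signal_high + signal_mean


class TestTddr:
    fs = 5.4

    def test_matches_reference_implementation(self, rng):
        x = np.cumsum(rng.normal(size=600)) * 0.01 + rng.normal(size=600)
        assert np.allclose(fl.tddr(x, self.fs), tddr_reference(x, self.fs), atol=1e-10)

    def test_clean_noise_passes_through(self, rng):
        # above the 0.5 Hz split the signal is untouched, so a clean
        # broadband signal survives nearly unchanged
        x = rng.normal(size=800)
        y = fl.tddr(x, 10.0)
        assert np.corrcoef(x, y)[0, 1] > 0.95

    def test_baseline_step_suppressed(self, rng):
        """A motion step on a realistic oscillatory background is removed
        almost entirely; its low-frequency footprint is what the robust
        derivative reweighting targets."""
        t = np.arange(1600) / self.fs
        bg = (
            0.3 * np.sin(2 * np.pi * 0.095 * t)
            + 0.15 * np.sin(2 * np.pi * 0.22 * t + 1.0)
            + 0.05 * rng.normal(size=t.size)
        )
        step = 10.0 * bg.std() * (t >= t[800])
        y = fl.tddr(bg + step, self.fs)
        in_height = (bg + step)[900:].mean() - (bg + step)[:700].mean()
        out_height = y[900:].mean() - y[:700].mean()
        assert abs(out_height) < 0.2 * abs(in_height)
        assert np.allclose(y, tddr_reference(bg + step, self.fs), atol=1e-10)

    def test_motion_transient_attenuated(self, rng):
        # a ~1 s transient is only partly low-frequency, so it is
        # attenuated rather than removed (high frequencies pass through)
        t = np.arange(1600) / self.fs
        bg = 0.3 * np.sin(2 * np.pi * 0.095 * t) + 0.05 * rng.normal(size=t.size)
        tr = 10.0 * bg.std() * np.exp(-np.abs(t - t[800]) / 1.0)
        y = fl.tddr(bg + tr, self.fs)
        peak_out = np.abs((y - fl.tddr(bg, self.fs))[780:830]).max()
        assert peak_out < 0.6 * tr.max()

    def test_constant_and_zero_signals(self):
        z = np.zeros(100)
        assert np.array_equal(fl.tddr(z, self.fs), z)
        c = np.full(100, 3.5)
        assert np.array_equal(fl.tddr(c, self.fs), c)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            fl.tddr(np.array([1.0, 2.0]), self.fs)


class TestBandpass:
    fs = 5.4

    def test_inband_sinusoid_preserved(self):
        t = np.arange(0, 400, 1 / self.fs)
        x = np.sin(2 * np.pi * 1.0 * t)
        y = fl.bandpass(x, DEFAULT_BANDS["cardiac"], self.fs)
        mid = slice(200, -200)
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.1)

    def test_out_of_band_drift_attenuated(self):
        t = np.arange(0, 400, 1 / self.fs)
        x = np.sin(2 * np.pi * 0.01 * t)
        y = fl.bandpass(x, DEFAULT_BANDS["cardiac"], self.fs)
        assert np.abs(y).max() < 0.1  # >= 20 dB down

    def test_zero_in_zero_out(self):
        assert np.allclose(fl.bandpass(np.zeros(500), DEFAULT_BANDS["mayer"], self.fs), 0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="cardiac"):
            fl.bandpass(np.zeros(500), DEFAULT_BANDS["cardiac"], 2.0)


class TestDelays:
    fs = 5.4

    def _brute_force_lag(self, x, ref, max_lag):
        """Integer-lag scan oracle."""
        best, best_val = 0, -np.inf
        for lag in range(-max_lag, max_lag + 1):
            shifted = np.roll(x, -lag)
            val = np.dot(shifted, ref)
            if val > best_val:
                best, best_val = lag, val
        return best

    def test_integer_shift_recovered_within_half_sample(self, rng):
        band = DEFAULT_BANDS["mayer"]
        t = np.arange(0, 600, 1 / self.fs)
        base = np.sin(2 * np.pi * 0.1 * t) + 0.05 * rng.normal(size=t.size)
        shifted = np.roll(base, 2)
        out = fl.estimate_delays(np.vstack([base, shifted]), band, self.fs, reference=0)
        measured = out["delays"][1] - out["delays"][0]
        assert measured == pytest.approx(2 / self.fs, abs=0.5 / self.fs)
        oracle = self._brute_force_lag(shifted, base, 8)
        assert round(measured * self.fs) == -oracle if oracle < 0 else True

    def test_identical_channel_zero_delay(self):
        t = np.arange(0, 600, 1 / self.fs)
        base = np.sin(2 * np.pi * 0.1 * t)
        out = fl.estimate_delays(np.vstack([base, base]), DEFAULT_BANDS["mayer"], self.fs)
        assert np.allclose(out["delays"], 0.0, atol=1e-6)

    def test_antiphase_half_period(self):
        band = DEFAULT_BANDS["mayer"]
        f0 = 0.1
        t = np.arange(0, 600, 1 / self.fs)
        base = np.sin(2 * np.pi * f0 * t)
        anti = -base
        out = fl.estimate_delays(
            np.vstack([base, anti]), band, self.fs,
            max_lag_s=0.5 / f0, reference=0,
        )
        assert abs(out["delays"][1]) == pytest.approx(0.5 / f0, rel=0.15)

    def test_flat_channel_flagged_zero(self):
        t = np.arange(0, 600, 1 / self.fs)
        base = np.sin(2 * np.pi * 0.1 * t)
        with pytest.warns(RuntimeWarning):
            out = fl.estimate_delays(
                np.vstack([base, np.zeros_like(base)]),
                DEFAULT_BANDS["mayer"], self.fs,
            )
        assert out["delays"][1] == 0.0
        assert out["flat"][1]


class TestShiftByDelay:
    def test_zero_delay_identity(self, rng):
        x = rng.normal(size=100)
        assert np.array_equal(fl.shift_by_delay(x, 0.0, 5.4), x)

    def test_roundtrip_smooth_signal(self):
        # information at the padded edges is genuinely lost, so the
        # round-trip bound applies to the interior
        t = np.arange(0, 200, 1 / 5.4)
        x = np.sin(2 * np.pi * 0.08 * t)
        y = fl.shift_by_delay(fl.shift_by_delay(x, 0.37, 5.4), -0.37, 5.4)
        interior = slice(3, -3)
        assert np.abs(y - x)[interior].max() < 0.01 * np.ptp(x)

    def test_integer_delay_equals_roll_with_edge_padding(self, rng):
        x = np.cumsum(rng.normal(size=50))
        y = fl.shift_by_delay(x, 3 / 5.4, 5.4)
        expected = np.concatenate([x[3:], np.full(3, x[-1])])
        assert np.allclose(y, expected, atol=1e-9)

    def test_excessive_delay_rejected(self):
        with pytest.raises(ValueError):
            fl.shift_by_delay(np.zeros(10), 100.0, 5.4)


class TestMbll:
    wl = (745.0, 850.0)

    def test_constant_intensity_zero_concentration(self):
        inten = np.full((2, 50), 1e5)
        hbo, hbr = fl.mbll(inten, self.wl, 3.0)
        assert np.allclose(hbo, 0) and np.allclose(hbr, 0)

    def test_forward_inverse_roundtrip(self, rng):
        hbo = 0.5 * np.sin(np.linspace(0, 6, 400))
        hbr = -0.2 * np.sin(np.linspace(0, 6, 400)) + 0.05 * rng.normal(size=400)
        od = mbll_forward(hbo, hbr, self.wl, 3.0)
        inten = 2e5 * np.exp(-od)
        rec_hbo, rec_hbr = fl.mbll(inten, self.wl, 3.0)
        # the temporal-mean reference leaves only a constant offset
        assert np.allclose(rec_hbo - rec_hbo.mean(), hbo - hbo.mean(), atol=1e-9)
        assert np.allclose(rec_hbr - rec_hbr.mean(), hbr - hbr.mean(), atol=1e-9)

    def test_doubling_dpf_halves_concentrations(self, rng):
        inten = 1e5 * np.exp(-0.01 * rng.normal(size=(2, 100)))
        hbo1, hbr1 = fl.mbll(inten, self.wl, 3.0, dpf=(6.0, 6.0))
        hbo2, hbr2 = fl.mbll(inten, self.wl, 3.0, dpf=(12.0, 12.0))
        assert np.allclose(hbo2, hbo1 / 2) and np.allclose(hbr2, hbr1 / 2)

    def test_singular_extinction_rejected(self):
        ext = {745.0: (1.0, 2.0), 850.0: (2.0, 4.0)}
        with pytest.raises(ValueError, match="singular"):
            fl.mbll(np.full((2, 10), 1.0e5), self.wl, 3.0, extinction=ext)

    def test_nonpositive_intensity_rejected(self):
        bad = np.ones((2, 10))
        bad[0, 3] = 0.0
        with pytest.raises(ValueError):
            fl.mbll(bad, self.wl, 3.0)


class TestLatentCommonSignal:
    def test_identical_channels_return_standardized_series(self, rng):
        s = np.cumsum(rng.normal(size=500))
        out = fl.latent_common_signal(np.tile(s, (4, 1)))
        z = (s - s.mean()) / s.std()
        assert np.allclose(out, z, atol=1e-8)

    def test_recovers_common_factor_at_snr_10(self, rng):
        common = np.sin(np.linspace(0, 40, 1500))
        chans = np.stack(
            [common + np.sqrt(0.1) * common.std() * rng.normal(size=1500)
             for _ in range(5)]
        )
        out = fl.latent_common_signal(chans)
        assert abs(np.corrcoef(out, common)[0, 1]) > 0.95

    def test_orthogonal_channels_weak_factor(self, rng):
        n, k = 4000, 5
        chans = rng.normal(size=(k, n))
        z = (chans - chans.mean(1, keepdims=True)) / chans.std(1, keepdims=True)
        corr = z @ z.T / n
        explained = np.linalg.eigvalsh(corr)[-1] / k
        assert explained == pytest.approx(1 / k, rel=0.3)

    def test_flat_channel_excluded_with_warning(self, rng):
        s = np.cumsum(rng.normal(size=300))
        chans = np.vstack([s, s * 1.01, np.zeros(300)])
        with pytest.warns(RuntimeWarning):
            out = fl.latent_common_signal(chans)
        assert np.isfinite(out).all()


class TestRegression:
    def test_target_in_span_gives_null_residual(self, rng):
        X = rng.normal(size=(3, 400))
        y = 2.0 * X[0] - 1.5 * X[2] + 4.0
        resid = fl.regress_out(y, X)
        assert np.sqrt(np.mean(resid**2)) < 1e-8 * np.sqrt(np.mean(y**2))

    def test_residual_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(4, 300))
        y = rng.normal(size=300)
        design = np.column_stack([np.ones(300), X.T])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert np.allclose(fl.regress_out(y, X), y - design @ beta, atol=1e-10)

    def test_orthogonal_regressors_leave_demeaned_target(self):
        n = 1000
        t = np.arange(n)
        y = np.sin(2 * np.pi * 5 * t / n) + 2.0
        X = np.cos(2 * np.pi * 5 * t / n)[None, :]
        resid = fl.regress_out(y, X)
        assert np.allclose(resid, y - y.mean(), atol=1e-8)

    def test_collinear_regressors_warn_not_fail(self, rng):
        x = rng.normal(size=200)
        with pytest.warns(RuntimeWarning):
            resid = fl.regress_out(rng.normal(size=200), np.vstack([x, 2 * x]))
        assert np.isfinite(resid).all()


class TestCbsi:
    def test_already_anticorrelated_is_fixed_point(self, rng):
        x = np.sin(np.linspace(0, 20, 500))
        alpha = 2.0
        y = -x / alpha
        assert np.allclose(fl.cbsi(x, y), x, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_corrected_pair_correlation_is_minus_one(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=300), r.normal(size=300)
        x0 = fl.cbsi(x, y)
        alpha = x.std() / y.std()
        y0 = -x0 / alpha
        assert np.corrcoef(x0, y0)[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_independent_noise_variance_reduced(self, rng):
        x, y = rng.normal(size=5000), rng.normal(size=5000)
        assert fl.cbsi(x, y).var() < x.var()

    def test_zero_variance_hbr_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            fl.cbsi(np.sin(np.arange(10.0)), np.zeros(10))


class TestPipeline:
    def test_noise_free_recording_retains_task_locked_rise(self, noise_free_cohort):
        recs, _, truth = noise_free_cohort
        clean = fl.run_pipeline(recs[0], motion_correction=False)
        slopes = fl.slope_matrix(fl.epoch(clean))
        contra = [
            clean.index_of(c.id)
            for c in clean.montage.long_channels
            if c.hemisphere != recs[0].lesion_side
        ]
        assert np.mean(slopes[:, contra]) > 0

    def test_mayer_only_recording_gives_null_slopes(self):
        cfg = fl.SimConfig(
            n_participants=1, seed=13, hrf_amplitude=0.0,
            band_amplitudes={"cardiac": 0.0, "respiration": 0.0, "mayer": 0.6},
            motion_rate=0.0, od_noise_sd=0.0, trial_noise_sd=0.0,
            m1lat_scale=0.0, pair_mean=0.0, short_hrf_fraction=0.0,
        )
        recs, _, _ = fl.generate_cohort(cfg)
        clean = fl.run_pipeline(recs[0])
        slopes = fl.slope_matrix(fl.epoch(clean))
        assert abs(np.mean(slopes)) < 3 * np.std(slopes) / np.sqrt(slopes.size) + 1e-3

    def test_onset_sample_zero_after_baseline_correction(self, default_cohort):
        recs, _, _ = default_cohort
        clean = fl.run_pipeline(recs[0])
        onsets = np.round(clean.events * clean.fs).astype(int)
        assert np.allclose(clean.hbo[:, onsets], 0.0, atol=1e-12)

    def test_pipeline_deterministic_and_shape_preserving(self, default_cohort):
        recs, _, _ = default_cohort
        a = fl.run_pipeline(recs[0])
        b = fl.run_pipeline(recs[0])
        assert np.array_equal(a.hbo, b.hbo)
        assert a.hbo.shape == (16, recs[0].n_samples)
        assert a.fs == recs[0].fs

    def test_stage_log_records_every_stage(self, default_cohort):
        recs, _, _ = default_cohort
        clean = fl.run_pipeline(recs[0])
        stages = [entry["stage"] for entry in clean.stage_log]
        for name in ("tddr", "delays", "mbll", "latent_common_regression",
                     "short_channel_regression", "bold_bandpass", "cbsi",
                     "baseline_correction"):
            assert name in stages

    def test_event_outside_recording_rejected(self, default_cohort):
        recs, _, _ = default_cohort
        rec = recs[0]
        bad = fl.RawRecording(
            montage=rec.montage, channel_ids=rec.channel_ids,
            intensity=rec.intensity, fs=rec.fs,
            events=np.array([1e6]), task_s=rec.task_s,
            participant_id=rec.participant_id, lesion_side=rec.lesion_side,
        )
        with pytest.raises(ValueError):
            fl.run_pipeline(bad)


def test_baseline_correct_sets_onset_to_zero(rng):
    x = rng.normal(size=(3, 200)).cumsum(axis=1)
    out = baseline_correct(x, np.array([5.0, 20.0]), 5.4)
    onsets = np.round(np.array([5.0, 20.0]) * 5.4).astype(int)
    assert np.allclose(out[:, onsets], 0.0)
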
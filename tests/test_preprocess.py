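"""Preprocessing stages against closed-form and brute-force oracles."""

import numpy as np
import pytest

from isasync import synth
from isasync.preprocess import (
    InsufficientDataError,
    bandpass_fir,
    csd_matrices,
    detrend_zero_mean,
    downsample,
    fir_length,
    hilbert_phase,
    preprocess_recording,
    surface_laplacian,
)


def fft_amplitude(x, freq, fs):
    """Tone amplitude at ``freq`` by least-squares projection on the
    quadrature pair (oracle helper; immune to FFT bin scalloping)."""
    t = np.arange(len(x)) / fs
    design = np.column_stack([np.cos(2 * np.pi * freq * t), np.sin(2 * np.pi * freq * t)])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return float(np.hypot(*coef))


class TestDetrend:
    def test_pure_line_maps_to_zero(self):
        t = np.arange(100.0)
        assert np.allclose(detrend_zero_mean(3.0 + 0.5 * t), 0.0, atol=1e-9)

    def test_integer_period_sinusoid_unchanged(self):
        # window-symmetric cosine over 40 full periods: zero mean and,
        # by even symmetry about the window center, exactly zero LS slope
        t = np.arange(0, 1000, 0.5)
        x = np.cos(2 * np.pi * 0.04 * (t - t.mean()))
        assert np.allclose(detrend_zero_mean(x), x, atol=1e-6)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.standard_normal(257)
        t = np.arange(x.size, dtype=float)
        design = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.solve(design.T @ design, design.T @ x)
        assert np.allclose(detrend_zero_mean(x), x - design @ beta, atol=1e-10)

    def test_output_statistics(self, rng):
        y = detrend_zero_mean(rng.standard_normal(500) + 5.0)
        assert abs(y.mean()) < 1e-10 * y.std()

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            detrend_zero_mean(np.array([1.0, 2.0]))


class TestDownsample:
    def test_slow_sinusoid_preserved(self):
        fs = 256.0
        t = np.arange(0, 400, 1 / fs)
        x = np.sin(2 * np.pi * 0.05 * t)
        y = downsample(x, fs, 8.0)
        assert y.size == int(np.ceil(x.size * 8 / 256))
        amp = fft_amplitude(y[80:-80], 0.05, 8.0)
        assert abs(amp - 1.0) < 0.01

    def test_dc_preserved(self):
        # interior only: one anti-alias filter length at each end is
        # edge-contaminated (later discarded by the valid mask anyway)
        y = downsample(np.full(2560, 3.7), 256.0, 8.0)
        assert np.allclose(y[35:-35], 3.7, atol=1e-6)

    def test_out_of_band_tone_attenuated(self):
        fs = 256.0
        t = np.arange(0, 400, 1 / fs)
        x = np.sin(2 * np.pi * 0.05 * t) + np.sin(2 * np.pi * 3.9 * t)
        y = downsample(x, fs, 8.0)
        hi = fft_amplitude(y[80:-80], 3.9, 8.0)
        assert hi < 10 ** (-20 / 20)  # > 20 dB down

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            downsample(np.zeros(100), 100.0, 8.0)


class TestBandpass:
    FS = 8.0

    def test_center_tone_amplitude_and_phase(self):
        band = (0.03, 0.04)
        t = np.arange(0, 6000, 1 / self.FS)
        x = np.cos(2 * np.pi * 0.035 * t)
        y = bandpass_fir(x, band, self.FS)
        ntaps = fir_length(self.FS)
        sl = slice(ntaps, x.size - ntaps)
        amp = fft_amplitude(y[sl], 0.035, self.FS)
        assert abs(amp - 1.0) < 0.05
        # zero phase: peak positions align
        assert np.max(np.abs(np.angle(np.exp(1j * (
            hilbert_phase(y)[sl] - hilbert_phase(x)[sl]))))) < 0.01

    def test_stopband_attenuation(self):
        band = (0.03, 0.04)
        t = np.arange(0, 6000, 1 / self.FS)
        x = np.cos(2 * np.pi * 0.12 * t)  # 3x the upper edge
        y = bandpass_fir(x, band, self.FS)
        ntaps = fir_length(self.FS)
        amp = fft_amplitude(y[ntaps:-ntaps], 0.12, self.FS)
        assert amp < 10 ** (-40 / 20)

    def test_zeros_map_to_zeros(self):
        y = bandpass_fir(np.zeros(8000), (0.03, 0.04), self.FS)
        assert np.allclose(y, 0.0)

    def test_signal_shorter_than_filter(self):
        with pytest.raises(InsufficientDataError):
            bandpass_fir(np.ones(100), (0.03, 0.04), self.FS)


class TestHilbertPhase:
    def test_cosine_phase_slope(self):
        fs = 8.0
        t = np.arange(0, 4000, 1 / fs)
        ph = hilbert_phase(np.cos(2 * np.pi * 0.04 * t))
        sl = slice(400, -400)
        slope = np.polyfit(t[sl], np.unwrap(ph)[sl], 1)[0]
        assert abs(slope - 2 * np.pi * 0.04) < 0.01 * 2 * np.pi * 0.04

    def test_sine_lags_cosine_by_half_pi(self):
        fs = 8.0
        t = np.arange(0, 4000, 1 / fs)
        pc = hilbert_phase(np.cos(2 * np.pi * 0.04 * t))
        ps = hilbert_phase(np.sin(2 * np.pi * 0.04 * t))
        d = np.angle(np.exp(1j * (pc[400:-400] - ps[400:-400])))
        assert np.allclose(d, np.pi / 2, atol=0.02)

    def test_amplitude_modulation_leaves_phase_slope(self):
        fs = 8.0
        t = np.arange(0, 4000, 1 / fs)
        carrier = np.cos(2 * np.pi * 0.05 * t)
        am = (1 + 0.5 * np.sin(2 * np.pi * 0.002 * t)) * carrier
        sl = slice(400, -400)
        s0 = np.polyfit(t[sl], np.unwrap(hilbert_phase(carrier))[sl], 1)[0]
        s1 = np.polyfit(t[sl], np.unwrap(hilbert_phase(am))[sl], 1)[0]
        assert abs(s1 - s0) < 0.02 * s0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            hilbert_phase(np.zeros(100))

    def test_range_contract(self, rng):
        ph = hilbert_phase(rng.standard_normal(512))
        assert np.all(ph > -np.pi) and np.all(ph <= np.pi)


def csd_oracle(v, montage, m=4, lam=1e-5, order=50):
    """Independent spherical-spline solve (different algebra: explicit
    Legendre recursion and Sherman-style elimination of the constant)."""
    n = len(montage)
    x = np.clip(montage @ montage.T, -1.0, 1.0)
    # Legendre values by upward recursion
    p_prev, p_cur = np.ones_like(x), x.copy()
    g = np.zeros_like(x)
    h = np.zeros_like(x)
    for deg in range(1, order + 1):
        if deg == 1:
            p = x
        else:
            p = ((2 * deg - 1) * x * p_cur - (deg - 1) * p_prev) / deg
            p_prev, p_cur = p_cur, p
        g += (2 * deg + 1) / (deg * (deg + 1)) ** m * p
        h += (2 * deg + 1) / (deg * (deg + 1)) ** (m - 1) * p
    g /= 4 * np.pi
    h /= 4 * np.pi
    gi = np.linalg.inv(g + lam * np.eye(n))
    ones = np.ones(n)
    c0 = (ones @ gi @ v) / (ones @ gi @ ones)
    c = gi @ (v - c0 * ones)
    return h @ c


class TestSurfaceLaplacian:
    def test_constant_field_maps_to_zero(self):
        montage = synth.make_montage(16, seed=1)
        data = np.full((16, 50), 5.0)
        out = surface_laplacian(data, montage)
        assert np.max(np.abs(out)) < 1e-6 * 5.0

    def test_reference_offset_invariance(self, rng):
        montage = synth.make_montage(12, seed=1)
        x = rng.standard_normal((12, 40))
        offset = rng.standard_normal(40)
        out1 = surface_laplacian(x, montage)
        out2 = surface_laplacian(x + offset[None, :], montage)
        assert np.max(np.abs(out1 - out2)) < 1e-8 * x.std()

    def test_matches_independent_spline_oracle(self, rng):
        montage = synth.make_montage(8, seed=3)
        v = rng.standard_normal(8)
        ours = surface_laplacian(v[:, None], montage)[:, 0]
        theirs = csd_oracle(v, montage)
        assert np.allclose(ours, theirs, atol=1e-8 * np.abs(theirs).max())

    def test_duplicate_positions_rejected(self):
        montage = synth.make_montage(6, seed=0)
        montage[3] = montage[1]
        with pytest.raises(ValueError, match="duplicate"):
            csd_matrices(montage)

    def test_needs_four_channels(self):
        with pytest.raises(ValueError):
            surface_laplacian(np.zeros((3, 10)), synth.make_montage(3, 0))


class TestPreprocessRecording:
    def test_constant_lag_recovered_without_jitter(self):
        spec = synth.CohortSpec(
            n_expert=1, n_novice=1, n_channels=8, fs=8.0, duration=1800.0,
            n_sessions=1, bands=(0.05,), kappa_expert=1e6, kappa_novice=1e6,
            noise_sd=0.0, drift_slope=0.0, seed=2,
        )
        part = synth.make_participants(spec)[0]
        rec, truth = synth.generate_recording(spec, part)
        eeg_pt, gsr_pt = preprocess_recording(rec, spec.bands, apply_csd=False)
        m = eeg_pt.valid_mask[0]
        for c in range(8):
            d = np.angle(
                np.exp(1j * (eeg_pt.phases[c, m, 0] - gsr_pt.phases[0, m, 0]))
            )
            err = np.angle(np.exp(1j * (d - truth.lag[c, 0])))
            assert np.abs(err).max() < 0.05

    def test_drift_removed_by_detrending(self):
        base = dict(
            n_expert=1, n_novice=1, n_channels=8, fs=8.0, duration=1800.0,
            n_sessions=1, bands=(0.05,), kappa_expert=1e6, kappa_novice=1e6,
            noise_sd=0.0, seed=4,
        )
        part = synth.make_participants(synth.CohortSpec(**base))[0]
        rec0, _ = synth.generate_recording(
            synth.CohortSpec(drift_slope=0.0, **base), part
        )
        rec1, _ = synth.generate_recording(
            synth.CohortSpec(drift_slope=0.5, **base), part
        )
        pt0, _ = preprocess_recording(rec0, (0.05,), apply_csd=False)
        pt1, _ = preprocess_recording(rec1, (0.05,), apply_csd=False)
        m = pt0.valid_mask[0]
        d = np.angle(np.exp(1j * (pt0.phases[:, m, 0] - pt1.phases[:, m, 0])))
        assert np.abs(d).max() < 1e-3

    def test_empty_band_list(self, tiny_cohort):
        rec, _ = tiny_cohort[0]
        eeg_pt, gsr_pt = preprocess_recording(rec, (), apply_csd=False)
        assert eeg_pt.phases.shape[2] == 0
        assert gsr_pt.phases.shape[2] == 0

    def test_phase_range_and_mask_contract(self, tiny_entries):
        eeg_pt, gsr_pt = tiny_entries[0]["sessions"][0]
        assert np.all(eeg_pt.phases > -np.pi) and np.all(eeg_pt.phases <= np.pi)
        n = eeg_pt.phases.shape[1]
        ntaps = fir_length(eeg_pt.fs)
        assert not eeg_pt.valid_mask[0, : ntaps].any()
        assert not eeg_pt.valid_mask[0, n - ntaps :].any()
        assert eeg_pt.valid_mask[0].sum() == n - 2 * ntaps

    def test_stage_name_attached_to_errors(self, tiny_cohort):
        rec, _ = tiny_cohort[0]
        short = type(rec)(
            eeg=rec.eeg[:, :100],
            gsr=rec.gsr[:100],
            fs=rec.fs,
            montage=rec.montage,
            ch_names=rec.ch_names,
            participant=rec.participant,
        )
        with pytest.raises(Exception, match="stage bandpass"):
            preprocess_recording(short, (0.05,), apply_csd=False)
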
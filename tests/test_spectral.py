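"""Wavelet transform correctness, significance, cross-spectra, coherence."""

import math

import numpy as np
import pytest
from scipy import special

from paleodendro import spectral


def brute_force_cwt(x, family, voices=16, s0=2.0):
    """Independent oracle: time-domain circular convolution against the
    naively-built (O(N^2) DFT) discrete wavelet kernel."""
    x = np.asarray(x, float)
    n = x.size
    xn = (x - x.mean()) / np.std(x)
    nf = int(2 ** math.ceil(math.log2(n)))
    xp = np.zeros(nf)
    xp[:n] = xn
    k = np.arange(nf)
    omega = 2 * np.pi * np.where(k <= nf // 2, k, k - nf) / nf
    if family == "morlet":
        w0 = 6.0
        ff = 4 * np.pi / (w0 + math.sqrt(2 + w0 * w0))
    else:
        ff = 2 * np.pi / math.sqrt(2.5)
    dj = 1.0 / voices
    jmax = int(math.floor(math.log2(n / (ff * s0)) / dj))
    scales = s0 * 2.0 ** (dj * np.arange(jmax + 1))
    out = np.empty((len(scales), n), complex)
    m_idx = np.arange(nf)
    for j, s in enumerate(scales):
        sw = s * omega
        if family == "morlet":
            ph = np.where(sw > 0,
                          np.pi ** -0.25 * np.exp(-0.5 * (sw - 6.0) ** 2),
                          0.0).astype(complex)
        else:
            ph = ((sw ** 2) * np.exp(-0.5 * sw ** 2)
                  / math.sqrt(special.gamma(2.5))).astype(complex)
        spec_kernel = np.conj(ph) * math.sqrt(2 * np.pi * s)
        # naive inverse DFT of the sampled spectrum -> time-domain kernel
        kern = np.array([
            np.sum(spec_kernel * np.exp(2j * np.pi * k * m / nf)) / nf
            for m in m_idx
        ])
        # circular convolution in the time domain
        for t in range(n):
            out[j, t] = np.sum(xp * kern[(t - m_idx) % nf])
    return scales, out


class TestCWT:
    @pytest.mark.parametrize("family", ["morlet", "dog"])
    def test_fft_equals_time_domain_convolution(self, family, rng):
        x = rng.normal(size=64)
        spec = spectral.cwt(x, family)
        scales, oracle = brute_force_cwt(x, family)
        np.testing.assert_allclose(spec.scales, scales)
        if family == "dog":
            oracle = oracle.real
        denom = np.abs(oracle).max(axis=1, keepdims=True)
        err = np.abs(spec.coefficients - oracle) / denom
        assert err.max() < 1e-8

    def test_constant_series_zero_power(self):
        spec = spectral.cwt(np.full(64, 3.3))
        np.testing.assert_array_equal(spec.power, 0.0)

    def test_pure_cosine_peak_at_its_period(self):
        t = np.arange(238.)
        spec = spectral.cwt(np.cos(2 * np.pi * t / 30))
        peak = spec.fourier_periods[spec.power.mean(axis=1).argmax()]
        assert abs(math.log2(peak / 30)) < 1 / 32

    def test_power_invariant_to_offset_and_scale(self, rng):
        x = rng.normal(size=128)
        p0 = spectral.cwt(x).power
        p1 = spectral.cwt(x + 100.0).power
        p2 = spectral.cwt(5.0 * x).power
        np.testing.assert_allclose(p0, p1, atol=1e-10)
        np.testing.assert_allclose(p0, p2, atol=1e-10)

    def test_dog_coefficients_antisymmetric_in_input(self, rng):
        x = rng.normal(size=64)
        a = spectral.cwt(x, "dog").coefficients
        b = spectral.cwt(-x, "dog").coefficients
        np.testing.assert_allclose(a, -b, atol=1e-10)

    def test_coi_symmetric_and_ramped(self):
        spec = spectral.cwt(np.random.default_rng(0).normal(size=100))
        np.testing.assert_allclose(spec.coi, spec.coi[::-1])
        mid = len(spec.coi) // 2
        assert np.all(np.diff(spec.coi[:mid]) > 0)
        ff = 4 * np.pi / (6 + math.sqrt(38.0))
        assert spec.coi[1] == pytest.approx(ff / math.sqrt(2))

    def test_parseval_within_10pct_for_red_series(self):
        x = spectral.ar1_surrogates(0.7, 300, 1,
                                    np.random.default_rng(1))[0]
        spec = spectral.cwt(x)
        dj = 1 / 16
        c_delta = 0.776        # Morlet(6) reconstruction constant
        recon = dj * np.sum(spec.power / spec.scales[:, None]) / (
            c_delta * x.size)
        assert abs(recon - 1.0) < 0.10

    def test_input_validation(self):
        with pytest.raises(spectral.SpectralError):
            spectral.cwt(np.ones(8))
        with pytest.raises(spectral.SpectralError):
            spectral.cwt(np.r_[np.ones(20), np.nan])


class TestAR1:
    def test_white_noise_near_zero(self):
        x = np.random.default_rng(0).normal(size=10000)
        assert abs(spectral.ar1_estimate(x)) < 0.05

    def test_recovers_phi(self):
        x = spectral.ar1_surrogates(0.7, 10000, 1,
                                    np.random.default_rng(3))[0]
        assert spectral.ar1_estimate(x) == pytest.approx(0.7, abs=0.05)

    def test_constant_errors(self):
        with pytest.raises(spectral.SpectralError):
            spectral.ar1_estimate(np.ones(50))

    def test_negative_estimates_floored(self):
        x = np.array([1.0, -1.0] * 20)
        assert spectral.ar1_estimate(x) == 0.0


class TestSignificance:
    def test_white_background_is_flat_unity(self):
        spec = spectral.cwt(np.random.default_rng(0).normal(size=64))
        bg = spectral._ar1_background(0.0, spec.fourier_periods, 64, 1.0)
        np.testing.assert_allclose(bg, 1.0)

    def test_montecarlo_agrees_with_theoretical(self):
        x = spectral.ar1_surrogates(0.5, 200, 1,
                                    np.random.default_rng(5))[0]
        spec = spectral.cwt(x)
        mt = spectral.rednoise_significance(spec, alpha=0.5,
                                            method="theoretical").copy()
        mm = spectral.rednoise_significance(spec, alpha=0.5,
                                            method="montecarlo",
                                            n_sim=1000, seed=9)
        agree = (mt == mm)[spec.in_coi()].mean()
        assert agree > 0.9

    def test_small_nsim_records_warning(self):
        x = spectral.ar1_surrogates(0.3, 64, 1, np.random.default_rng(0))[0]
        spec = spectral.cwt(x)
        spectral.rednoise_significance(spec, method="montecarlo", n_sim=50,
                                       seed=0)
        assert "warning" in spec.wavelet

    def test_zero_power_cells_never_flagged(self):
        spec = spectral.cwt(np.full(64, 2.0))
        mask = spectral.rednoise_significance(spec, alpha=0.0)
        assert not mask.any()


class TestCrossSpectra:
    def test_xwt_identity_and_negation(self, rng):
        x = rng.normal(size=128)
        sx = spectral.cwt(x)
        sy = spectral.cwt(x)
        out = spectral.xwt(sx, sy)
        np.testing.assert_allclose(out["phase"], 0.0, atol=1e-10)
        np.testing.assert_allclose(out["cross_power"], sx.power, rtol=1e-10)
        sneg = spectral.cwt(-x)
        phase = spectral.xwt(sx, sneg)["phase"]
        np.testing.assert_allclose(np.abs(phase), np.pi, atol=1e-8)

    def test_xwt_quarter_period_lag_gives_half_pi_phase(self):
        t = np.arange(256.)
        period = 32.0
        x = np.cos(2 * np.pi * t / period)
        y = np.cos(2 * np.pi * (t - period / 4) / period)
        sx, sy = spectral.cwt(x), spectral.cwt(y)
        out = spectral.xwt(sx, sy)
        j = np.argmin(np.abs(sx.fourier_periods - period))
        mid = slice(64, 192)
        np.testing.assert_allclose(np.abs(out["phase"][j, mid]), np.pi / 2,
                                   atol=0.1)

    def test_grid_mismatch_rejected(self, rng):
        sx = spectral.cwt(rng.normal(size=64))
        sy = spectral.cwt(rng.normal(size=128))
        with pytest.raises(spectral.SpectralError):
            spectral.xwt(sx, sy)


class TestCoherence:
    def test_identity_coherence_is_one(self, rng):
        x = rng.normal(size=128)
        sx, sy = spectral.cwt(x), spectral.cwt(x)
        coh = spectral.coherence(sx, sy, n_sim=0)
        np.testing.assert_allclose(coh.coherence, 1.0, atol=1e-6)

    def test_smoothing_cannot_be_disabled(self, rng):
        sx = spectral.cwt(rng.normal(size=64))
        with pytest.raises(spectral.SpectralError):
            spectral.coherence(sx, sx, smoothing=False)

    def test_dog_spectra_refused(self, rng):
        s = spectral.cwt(rng.normal(size=64), "dog")
        with pytest.raises(spectral.SpectralError):
            spectral.coherence(s, s)

    def test_independent_pair_low_mean_coherence(self):
        rng = np.random.default_rng(8)
        sx = spectral.cwt(spectral.ar1_surrogates(0.3, 200, 1, rng)[0])
        sy = spectral.cwt(spectral.ar1_surrogates(0.3, 200, 1, rng)[0])
        coh = spectral.coherence(sx, sy, n_sim=100, seed=1)
        mc = coh.mean_coherence_by_period
        valid = ~np.isnan(mc)
        assert np.nanmean(mc[valid]) < 0.5
        # false-positive per-period flags stay near the nominal level
        assert coh.period_significant[valid].mean() <= 0.2
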
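"""Continuous wavelet transform, red-noise significance, cross-wavelet
power and wavelet coherence.

The transform follows the standard FFT formulation: with the series
zero-padded to the next power of two,

    W(s, t) = sum_k  x_hat_k  conj(psi_hat(s w_k))  sqrt(2 pi s / dt)  e^{i w_k t}

on a dyadic scale grid ``s_j = s0 * 2**(j / voices)``.  Two mother
wavelets are supported:

* Morlet with omega0 = 6 (complex; Fourier period
  ``4 pi s / (omega0 + sqrt(2 + omega0**2))`` ~ 1.033 s), the default for
  oscillation detection;
* DOG(2), the second derivative of a Gaussian / Mexican hat (real;
  Fourier period ``2 pi s / sqrt(m + 1/2)``), whose coefficients can be
  compared year-by-year with the series itself because positive and
  negative excursions appear as separate peaks.

The input is mean-removed and variance-normalized, so power is in units
of the series variance.  Significance is evaluated against an AR(1)
("red noise") null: either the theoretical chi-square test on the
discrete AR(1) spectrum, or a Monte-Carlo per-scale quantile over AR(1)
surrogates.  The cone of influence (COI) marks the edge region where the
wavelet's e-folding time sqrt(2)*s reaches past the series boundary.

Wavelet coherence (Morlet only) is the smoothed, normalized cross
spectrum: Gaussian smoothing in time with standard deviation equal to the
scale, then a boxcar across 0.6 octave in scale; its significance is
Monte-Carlo over AR(1) surrogate pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, special, stats

__all__ = [
    "WaveletSpectrum",
    "CoherenceSpectrum",
    "cwt",
    "ar1_estimate",
    "ar1_surrogates",
    "rednoise_significance",
    "xwt",
    "coherence",
]

MORLET_OMEGA0 = 6.0
DOG_M = 2


class SpectralError(ValueError):
    pass


def _fourier_factor(family: str) -> float:
    if family == "morlet":
        w0 = MORLET_OMEGA0
        return 4.0 * math.pi / (w0 + math.sqrt(2.0 + w0 * w0))
    if family == "dog":
        return 2.0 * math.pi / math.sqrt(DOG_M + 0.5)
    raise SpectralError(f"unknown wavelet family {family!r}")


def _psi_hat(family: str, s_omega: np.ndarray) -> np.ndarray:
    """Mother wavelet in the Fourier domain (unit-energy normalization)."""
    if family == "morlet":
        out = np.pi ** -0.25 * np.exp(
            -0.5 * (s_omega - MORLET_OMEGA0) ** 2, where=s_omega > 0,
            out=np.zeros_like(s_omega))
        return out * (s_omega > 0)
    if family == "dog":
        m = DOG_M
        norm = -((1j) ** m) / math.sqrt(special.gamma(m + 0.5))
        return norm * (s_omega ** m) * np.exp(-0.5 * s_omega ** 2)
    raise SpectralError(f"unknown wavelet family {family!r}")


@dataclass
class WaveletSpectrum:
    """Time x scale wavelet decomposition of one series."""

    times: np.ndarray              # yr (relative axis of the input)
    scales: np.ndarray             # yr
    fourier_periods: np.ndarray    # yr, strictly increasing
    coefficients: np.ndarray       # [scale, time], complex (Morlet) / real (DOG)
    power: np.ndarray              # |W|^2 in units of input variance
    coi: np.ndarray                # per-time e-folding Fourier period, yr
    wavelet: dict = field(default_factory=dict)
    voices_per_octave: int = 16
    ar1_alpha: float | None = None # lag-1 coefficient estimated from input
    signif_mask: np.ndarray | None = None
    signif_level: float | None = None
    dt: float = 1.0
    data: np.ndarray | None = None # normalized input (kept for surrogates)
    variance: float = 1.0          # original variance removed by normalization

    @property
    def family(self) -> str:
        return self.wavelet.get("family", "morlet")

    def in_coi(self) -> np.ndarray:
        """Boolean [scale, time] mask of cells inside the cone of influence."""
        return self.fourier_periods[:, None] < self.coi[None, :]


def cwt(x: np.ndarray, wavelet: str = "morlet", voices_per_octave: int = 16,
        s0: float | None = None, pad: bool = True, dt: float = 1.0,
        times: np.ndarray | None = None) -> WaveletSpectrum:
    """Continuous wavelet transform of an annual series.

    The series is mean-removed and normalized to unit variance before the
    transform, so returned power is in units of sigma^2.  Scales run from
    ``s0`` (default 2*dt) dyadically with ``voices_per_octave`` sub-octave
    steps up to the largest scale whose Fourier period fits in the series.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise SpectralError("input must be one-dimensional")
    n = x.size
    if n < 16:
        raise SpectralError("series too short for a CWT (need >= 16)")
    if not np.all(np.isfinite(x)):
        raise SpectralError("input contains non-finite values")
    variance = float(np.var(x))
    if variance == 0:
        xn = x - x.mean()           # all zeros; power will be exactly 0
    else:
        xn = (x - x.mean()) / math.sqrt(variance)

    family = wavelet.lower()
    ff = _fourier_factor(family)
    if s0 is None:
        s0 = 2.0 * dt
    dj = 1.0 / voices_per_octave
    jmax = int(math.floor(math.log2(n * dt / (ff * s0)) / dj))
    if jmax < 1:
        raise SpectralError("series too short for the requested s0")
    scales = s0 * 2.0 ** (dj * np.arange(jmax + 1))
    periods = ff * scales

    n_fft = int(2 ** math.ceil(math.log2(n))) if pad else n
    xp = np.zeros(n_fft)
    xp[:n] = xn
    x_hat = np.fft.fft(xp)
    # angular frequencies with a *positive* Nyquist bin, so the analytic
    # (Heaviside) Morlet keeps its contribution there
    k = np.arange(n_fft)
    omega = 2.0 * np.pi * np.where(k <= n_fft // 2, k, k - n_fft) / (n_fft * dt)

    psi = _psi_hat(family, scales[:, None] * omega[None, :])
    norm = np.sqrt(2.0 * np.pi * scales[:, None] / dt)
    w = np.fft.ifft(x_hat[None, :] * np.conj(psi) * norm, axis=1)[:, :n]
    if family == "dog":
        w = w.real
    power = np.abs(w) ** 2

    # COI: e-folding time sqrt(2)*s mapped to Fourier period, ramping
    # symmetrically from both edges.
    t_idx = np.arange(n, dtype=float)
    dist = np.minimum(t_idx, n - 1 - t_idx) * dt
    coi = ff / math.sqrt(2.0) * np.maximum(dist, 1e-9)

    alpha = ar1_estimate(x) if variance > 0 else None
    return WaveletSpectrum(
        times=np.arange(n, dtype=float) * dt if times is None
              else np.asarray(times, float),
        scales=scales, fourier_periods=periods, coefficients=w, power=power,
        coi=coi,
        wavelet={"family": family,
                 "param": MORLET_OMEGA0 if family == "morlet" else DOG_M},
        voices_per_octave=voices_per_octave, ar1_alpha=alpha, dt=dt,
        data=xn, variance=variance,
    )


def ar1_estimate(x: np.ndarray) -> float:
    """Lag-1 autocorrelation of a series (red-noise coefficient).

    Negative estimates are floored at 0 — the red-noise null is defined
    for persistence, not anti-persistence.
    """
    x = np.asarray(x, float)
    if x.size < 16:
        raise SpectralError("AR(1) estimate needs >= 16 values")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise SpectralError("AR(1) estimate undefined for constant input")
    r1 = float(xc[:-1] @ xc[1:]) / denom
    return max(0.0, r1)


def ar1_surrogates(alpha: float, n: int, n_sim: int,
                   rng: np.random.Generator) -> np.ndarray:
    """``n_sim`` unit-variance AR(1) paths of length ``n`` (rows)."""
    innov_sd = math.sqrt(max(1.0 - alpha * alpha, 1e-12))
    eps = rng.normal(0.0, innov_sd, size=(n_sim, n + 1))
    eps[:, 0] = rng.normal(0.0, 1.0, size=n_sim)   # stationary start
    out = np.empty((n_sim, n + 1))
    out[:, 0] = eps[:, 0]
    for t in range(1, n + 1):
        out[:, t] = alpha * out[:, t - 1] + eps[:, t]
    return out[:, 1:]


def _ar1_background(alpha: float, periods: np.ndarray, n: int,
                    dt: float) -> np.ndarray:
    """Discrete AR(1) spectrum at the scales' Fourier frequencies (mean 1)."""
    freq = dt / periods                      # cycles per sample
    return (1.0 - alpha ** 2) / (1.0 + alpha ** 2
                                 - 2.0 * alpha * np.cos(2.0 * np.pi * freq))


def rednoise_significance(spec: WaveletSpectrum, alpha: float | None = None,
                          level: float = 0.05, method: str = "theoretical",
                          n_sim: int = 1000,
                          seed: int | None = None) -> np.ndarray:
    """Flag wavelet power exceeding the AR(1) red-noise null.

    ``method="theoretical"``: the null power at each scale is the discrete
    AR(1) spectrum at that scale's Fourier frequency times the
    chi-square(nu) (1-level) quantile over nu, with nu = 2 for the complex
    Morlet and nu = 1 for the real DOG.  ``method="montecarlo"``: the
    per-scale (1-level) quantile of power over ``n_sim`` AR(1) surrogates
    with the same alpha and unit variance, deterministic given ``seed``.

    The mask is stored on the spectrum and returned; cells with exactly
    zero power are never flagged.
    """
    if not (0.0 < level < 1.0):
        raise SpectralError("level must be in (0, 1)")
    if alpha is None:
        alpha = spec.ar1_alpha
        if alpha is None:
            raise SpectralError("no AR(1) alpha available")
    n = spec.times.size
    warning = None
    if method == "theoretical":
        dof = 2 if spec.family == "morlet" else 1
        pk = _ar1_background(alpha, spec.fourier_periods, n, spec.dt)
        thresh = pk * stats.chi2.ppf(1.0 - level, dof) / dof
        mask = spec.power > thresh[:, None]
    elif method == "montecarlo":
        if n_sim < 100:
            warning = f"montecarlo with n_sim={n_sim} < 100 is unreliable"
        rng = np.random.default_rng(seed)
        sims = ar1_surrogates(alpha, n, n_sim, rng)
        pool = np.empty((len(spec.scales), n_sim * n))
        for i in range(n_sim):
            sp = cwt(sims[i], wavelet=spec.family,
                     voices_per_octave=spec.voices_per_octave,
                     s0=float(spec.scales[0]), dt=spec.dt)
            pool[:, i * n:(i + 1) * n] = sp.power
        thresh = np.quantile(pool, 1.0 - level, axis=1)
        mask = spec.power > thresh[:, None]
    else:
        raise SpectralError(f"unknown method {method!r}")
    mask &= spec.power > 0
    spec.signif_mask = mask
    spec.signif_level = level
    spec.wavelet["signif_method"] = method
    if warning:
        spec.wavelet["warning"] = warning
    return mask


def _check_grids(a: WaveletSpectrum, b: WaveletSpectrum) -> None:
    if (a.times.size != b.times.size
            or a.scales.size != b.scales.size
            or not np.allclose(a.scales, b.scales)
            or not np.allclose(a.times, b.times)):
        raise SpectralError("spectra are not on matching time/scale grids")


def xwt(spec_x: WaveletSpectrum, spec_y: WaveletSpectrum) -> dict:
    """Cross-wavelet transform W^XY = W^X conj(W^Y).

    Returns cross-power |W^XY| and its phase (rad).  With the usual arrow
    convention, phase 0 (arrow right) is positive correlation, phase pi
    (left) negative, and +/- pi/2 (up/down) a quarter-period lead/lag.
    """
    _check_grids(spec_x, spec_y)
    wxy = spec_x.coefficients * np.conj(spec_y.coefficients)
    return {"wxy": wxy, "cross_power": np.abs(wxy), "phase": np.angle(wxy)}


def _smooth(mat: np.ndarray, scales: np.ndarray, dt: float, dj: float,
            scale_octaves: float = 0.6) -> np.ndarray:
    """Coherence smoothing: Gaussian in time (std = scale), boxcar in scale."""
    out = np.empty_like(mat)
    for j, s in enumerate(scales):
        sigma = s / dt
        if np.iscomplexobj(mat):
            out[j] = (ndimage.gaussian_filter1d(mat[j].real, sigma,
                                                mode="reflect")
                      + 1j * ndimage.gaussian_filter1d(mat[j].imag, sigma,
                                                       mode="reflect"))
        else:
            out[j] = ndimage.gaussian_filter1d(mat[j], sigma, mode="reflect")
    width = max(1, int(round(scale_octaves / dj)))
    kernel = np.ones(width) / width
    if np.iscomplexobj(mat):
        out = (ndimage.convolve1d(out.real, kernel, axis=0, mode="nearest")
               + 1j * ndimage.convolve1d(out.imag, kernel, axis=0,
                                         mode="nearest"))
    else:
        out = ndimage.convolve1d(out, kernel, axis=0, mode="nearest")
    return out


@dataclass
class CoherenceSpectrum:
    """Smoothed squared wavelet coherence between two series."""

    times: np.ndarray
    scales: np.ndarray
    fourier_periods: np.ndarray
    coherence: np.ndarray          # R^2 in [0, 1]
    phase: np.ndarray              # rad, (-pi, pi]
    cross_power: np.ndarray
    coi: np.ndarray
    signif_mask: np.ndarray | None = None
    cross_signif_mask: np.ndarray | None = None
    mean_coherence_by_period: np.ndarray | None = None
    period_significant: np.ndarray | None = None
    level: float = 0.05


def coherence(spec_x: WaveletSpectrum, spec_y: WaveletSpectrum,
              level: float = 0.05, n_sim: int = 300,
              seed: int | None = None, smoothing: bool = True,
              scale_octaves: float = 0.6) -> CoherenceSpectrum:
    """Squared wavelet coherence with Monte-Carlo AR(1) significance.

    R^2 = |S(W^XY / s)|^2 / ( S(|W^X|^2 / s) S(|W^Y|^2 / s) ), with the
    smoothing operator S of :func:`_smooth`.  Significance (per cell and
    for the COI-interior period-mean profile) is the (1-level) quantile
    over ``n_sim`` pairs of independent AR(1) surrogates matched to the
    two inputs' lag-1 coefficients.  Morlet spectra only: the smoothing
    kernel is defined for the Morlet, and unsmoothed coherence is
    identically 1.
    """
    _check_grids(spec_x, spec_y)
    if spec_x.family != "morlet" or spec_y.family != "morlet":
        raise SpectralError("coherence is defined for Morlet spectra only")
    if not smoothing:
        raise SpectralError(
            "smoothing disabled: unsmoothed coherence is identically 1"
        )
    dj = 1.0 / spec_x.voices_per_octave

    def _r2_phase(wx: np.ndarray, wy: np.ndarray):
        scales = spec_x.scales[:, None]
        sxy = _smooth(wx * np.conj(wy) / scales, spec_x.scales, spec_x.dt,
                      dj, scale_octaves)
        sxx = _smooth(np.abs(wx) ** 2 / scales, spec_x.scales, spec_x.dt,
                      dj, scale_octaves)
        syy = _smooth(np.abs(wy) ** 2 / scales, spec_x.scales, spec_x.dt,
                      dj, scale_octaves)
        denom = sxx * syy
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.abs(sxy) ** 2 / np.where(denom > 0, denom, np.inf)
        return np.clip(r2, 0.0, 1.0), np.angle(sxy)

    r2, phase = _r2_phase(spec_x.coefficients, spec_y.coefficients)
    cross = np.abs(spec_x.coefficients * np.conj(spec_y.coefficients))
    incoi = spec_x.in_coi()

    def _coi_mean(mat: np.ndarray) -> np.ndarray:
        out = np.full(len(spec_x.scales), np.nan)
        for j in range(len(spec_x.scales)):
            sel = incoi[j]
            if sel.any():
                out[j] = float(mat[j, sel].mean())
        return out

    mean_coh = _coi_mean(r2)

    sig_cell = sig_cross = sig_period = None
    if n_sim and n_sim > 0:
        rng = np.random.default_rng(seed)
        ax = spec_x.ar1_alpha or 0.0
        ay = spec_y.ar1_alpha or 0.0
        n = spec_x.times.size
        nsc = len(spec_x.scales)
        coh_pool = np.empty((nsc, 0))
        cross_pool = np.empty((nsc, 0))
        mean_pool = np.empty((n_sim, nsc))
        coh_cells = []
        cross_cells = []
        for i in range(n_sim):
            sx = cwt(ar1_surrogates(ax, n, 1, rng)[0], "morlet",
                     spec_x.voices_per_octave, float(spec_x.scales[0]),
                     dt=spec_x.dt)
            sy = cwt(ar1_surrogates(ay, n, 1, rng)[0], "morlet",
                     spec_x.voices_per_octave, float(spec_x.scales[0]),
                     dt=spec_x.dt)
            r2s, _ = _r2_phase(sx.coefficients, sy.coefficients)
            coh_cells.append(r2s)
            cross_cells.append(np.abs(sx.coefficients
                                      * np.conj(sy.coefficients)))
            mean_pool[i] = _coi_mean(r2s)
        coh_pool = np.stack(coh_cells)      # [sim, scale, time]
        cross_pool = np.stack(cross_cells)
        q = 1.0 - level
        coh_thresh = np.quantile(
            coh_pool.transpose(1, 0, 2).reshape(nsc, -1), q, axis=1)
        cross_thresh = np.quantile(
            cross_pool.transpose(1, 0, 2).reshape(nsc, -1), q, axis=1)
        sig_cell = r2 > coh_thresh[:, None]
        sig_cross = cross > cross_thresh[:, None]
        mean_thresh = np.full(nsc, np.nan)
        has_coi = ~np.isnan(mean_pool).all(axis=0)
        mean_thresh[has_coi] = np.nanquantile(mean_pool[:, has_coi], q,
                                              axis=0)
        with np.errstate(invalid="ignore"):
            sig_period = mean_coh > mean_thresh

    return CoherenceSpectrum(
        times=spec_x.times, scales=spec_x.scales,
        fourier_periods=spec_x.fourier_periods, coherence=r2, phase=phase,
        cross_power=cross, coi=spec_x.coi, signif_mask=sig_cell,
        cross_signif_mask=sig_cross, mean_coherence_by_period=mean_coh,
        period_significant=sig_period, level=level,
    )
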
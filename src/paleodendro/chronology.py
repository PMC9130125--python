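"""Detrending, ring-width index chronologies, and signal-strength diagnostics.

Each aligned series is detrended with a cubic smoothing spline whose
frequency response is 50% at a wavelength of ``cutoff_frac`` times the
series length (default 0.67, the dominant dendro convention).  The ring
width index RWI = width / fitted expected width is a dimensionless index
around 1: < 1 means less growth than expected, > 1 more.  Per-year RWI
values are combined across series with a Tukey biweight robust mean, and
chronology quality is summarised by rbar (mean pairwise inter-series
correlation) and the subsample signal strength

    SSS(n) = n (1 + (N-1) rbar) / ( N (1 + (n-1) rbar) )

which estimates the fraction of the full-chronology common signal captured
where only n of the N series are present.  The first year at which SSS
reaches a cutoff (default 0.5) marks the usable start of the chronology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy import stats

from .dendro_io import RingWidthSeries

__all__ = [
    "DetrendFit",
    "Chronology",
    "spline_detrend",
    "to_rwi",
    "tukey_biweight_mean",
    "average_chronology",
    "subsample_signal_strength",
    "rbar",
    "normality_diagnostic",
]

_FIT_EPS = 1e-6        # floor for fitted widths, mm
SSS_CUTOFF = 0.5


class ChronologyError(ValueError):
    pass


@dataclass
class DetrendFit:
    """Fitted expected widths for one series."""

    first_year: int
    fitted: np.ndarray
    cutoff_years: float            # 50%-response wavelength of the spline
    method: str = "smoothing_spline"


def spline_detrend(series: RingWidthSeries,
                   cutoff_frac: float = 0.67) -> DetrendFit:
    """Cubic smoothing spline with a 50% frequency cutoff.

    The roughness penalty lambda is set from the requested cutoff
    wavelength p by the spline frequency-response relation
    ``lambda = (p / 2 pi)**4`` (for unit annual spacing the smoother's
    amplitude response is ``1 / (1 + lambda * omega**4)``, which equals 1/2
    at wavelength p).  Fitted values are floored at a small positive
    epsilon so the index is always defined.
    """
    n = len(series)
    if n < 10:
        raise ChronologyError(f"series {series.series_id!r}: length {n} < 10")
    if not (0 < cutoff_frac):
        raise ChronologyError("cutoff_frac must be positive")
    p = cutoff_frac * n
    lam = (p / (2.0 * math.pi)) ** 4
    x = np.arange(n, dtype=float)
    fit = make_smoothing_spline(x, series.widths, lam=lam)(x)
    return DetrendFit(first_year=series.first_year,
                      fitted=np.maximum(fit, _FIT_EPS),
                      cutoff_years=p)


@dataclass
class IndexedRWI:
    """Per-year ring width index of one series."""

    series_id: str
    first_year: int
    rwi: np.ndarray

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.rwi))


def to_rwi(series: RingWidthSeries, fit: DetrendFit) -> IndexedRWI:
    """Ring width index: measured width over fitted expected width."""
    if fit.first_year != series.first_year or len(fit.fitted) != len(series):
        raise ChronologyError("fit is not aligned to the series")
    return IndexedRWI(series_id=series.series_id,
                      first_year=series.first_year,
                      rwi=series.widths / fit.fitted)


def tukey_biweight_mean(values: np.ndarray, c: float = 9.0,
                        tol: float = 1e-8, max_iter: int = 50) -> float:
    """Tukey biweight robust location estimate (dendro-standard c = 9).

    Iterates the weighted mean with weights ``(1 - u^2)^2`` for
    ``|u| < 1``, ``u = (x - loc) / (c * MAD)``, from the median.  Falls
    back to the median when the MAD is zero.
    """
    x = np.asarray(values, float)
    loc = float(np.median(x))
    mad = float(np.median(np.abs(x - loc)))
    if mad == 0.0:
        return loc
    for _ in range(max_iter):
        u = (x - loc) / (c * mad)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() == 0.0:
            return loc
        new = float(np.sum(w * x) / w.sum())
        if abs(new - loc) < tol:
            return new
        loc = new
    return loc


@dataclass
class Chronology:
    """Master RWI chronology with depth and signal-strength diagnostics."""

    years: np.ndarray
    rwi: np.ndarray
    sample_depth: np.ndarray
    rbar: float
    sss: np.ndarray
    sss_year: int | None           # first year with SSS >= cutoff
    n_total: int
    sss_cutoff: float = SSS_CUTOFF

    def __len__(self) -> int:
        return len(self.years)


def subsample_signal_strength(rbar_value: float, n: int, N: int) -> float:
    """Fraction of the N-series common signal captured by n series."""
    if not (0.0 <= rbar_value <= 1.0):
        raise ChronologyError("rbar must be in [0, 1]")
    if not (1 <= n <= N):
        raise ChronologyError("need 1 <= n <= N")
    return (n * (1.0 + (N - 1) * rbar_value)) / (N * (1.0 + (n - 1) * rbar_value))


def rbar(indexed: list[IndexedRWI], min_overlap: int = 10) -> float:
    """Mean pairwise Pearson correlation of RWI over common years."""
    if len(indexed) < 2:
        raise ChronologyError("rbar needs >= 2 series")
    cors = []
    for i, a in enumerate(indexed):
        for b in indexed[i + 1:]:
            lo = max(a.first_year, b.first_year)
            hi = min(a.first_year + len(a.rwi), b.first_year + len(b.rwi))
            if hi - lo < min_overlap:
                continue
            xa = a.rwi[lo - a.first_year: hi - a.first_year]
            xb = b.rwi[lo - b.first_year: hi - b.first_year]
            if np.std(xa) == 0 or np.std(xb) == 0:
                continue
            cors.append(float(np.corrcoef(xa, xb)[0, 1]))
    if not cors:
        raise ChronologyError(
            f"no series pair overlaps by >= {min_overlap} years"
        )
    return float(np.mean(cors))


def average_chronology(indexed: list[IndexedRWI],
                       method: str = "biweight",
                       rbar_min_overlap: int = 10,
                       sss_cutoff: float = SSS_CUTOFF) -> Chronology:
    """Combine per-series RWI into a master chronology.

    Per year, the Tukey biweight robust mean is used where at least four
    series contribute; thinner years fall back to the arithmetic mean
    (the biweight is unstable at tiny n).  ``method="mean"`` forces the
    arithmetic mean everywhere.  SSS is computed per year from the
    whole-chronology rbar and that year's sample depth.
    """
    if not indexed:
        raise ChronologyError("no indexed series")
    if method not in ("biweight", "mean"):
        raise ChronologyError(f"unknown method {method!r}")
    lo = min(s.first_year for s in indexed)
    hi = max(s.first_year + len(s.rwi) for s in indexed)
    years = np.arange(lo, hi)
    n_years = len(years)
    columns: list[list[float]] = [[] for _ in range(n_years)]
    for s in indexed:
        for j, v in enumerate(s.rwi):
            columns[s.first_year - lo + j].append(float(v))
    depth = np.array([len(c) for c in columns])
    if np.any(depth == 0):
        # aligned set with interior gaps: keep only covered years
        covered = depth > 0
        years = years[covered]
        columns = [c for c, ok in zip(columns, covered) if ok]
        depth = depth[covered]
    values = np.empty(len(years))
    for j, col in enumerate(columns):
        arr = np.asarray(col)
        if method == "biweight" and len(arr) >= 4:
            values[j] = tukey_biweight_mean(arr)
        else:
            values[j] = arr.mean()

    n_total = len(indexed)
    if n_total >= 2:
        try:
            rb = rbar(indexed, min_overlap=rbar_min_overlap)
        except ChronologyError:
            rb = math.nan
    else:
        rb = math.nan
    rb_eff = min(max(rb, 0.0), 1.0) if not math.isnan(rb) else 0.0
    sss = np.array([subsample_signal_strength(rb_eff, int(n), n_total)
                    for n in depth])
    above = np.flatnonzero(sss >= sss_cutoff)
    sss_year = int(years[above[0]]) if above.size else None
    return Chronology(years=years, rwi=values, sample_depth=depth, rbar=rb,
                      sss=sss, sss_year=sss_year, n_total=n_total,
                      sss_cutoff=sss_cutoff)


def normality_diagnostic(values: np.ndarray) -> dict:
    """Shapiro–Wilk test plus quantile pairs for a probability plot.

    Advisory: a strongly non-Gaussian chronology warns that wavelet
    red-noise significance may be miscalibrated, but does not block the
    transform.
    """
    x = np.asarray(values, float)
    if x.size < 20:
        raise ChronologyError("normality diagnostic needs >= 20 values")
    if np.std(x) == 0:
        return {"statistic": math.nan, "p": math.nan, "qq_points": None,
                "degenerate": True}
    stat, p = stats.shapiro(x)
    (theo, ordered), _ = stats.probplot(x, dist="norm")
    return {"statistic": float(stat), "p": float(p),
            "qq_points": np.column_stack([theo, ordered]),
            "degenerate": False}
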
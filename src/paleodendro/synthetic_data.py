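"""Synthetic fossil-forest and paleosol generators.

The forest generator produces ring-width series with the statistical
structure the downstream analysis assumes: a negative-exponential age
trend, a shared oscillatory climate signal coupled into log-width, lag-1
autocorrelated (red) tree-level noise, multiplicative marker years
(anomalously narrow or wide rings shared across trees), and known
inter-tree start-year offsets.  Because every ingredient is known, every
downstream stage — cross-dating, chronology building, wavelet detection,
the growth-suppression statistic — can be tested as a parameter-recovery
problem.

Width model (all multiplicative, so widths stay positive)::

    width(t) = max(floor, w0 * exp(-decay * age)) *
               exp(signal_gain * C(year) + eps(age)) * marker(year)

where ``C`` is a sum of (optionally interval-gated) sinusoids shared by
all trees, and ``eps`` is per-radius AR(1) noise with Gaussian innovations
of standard deviation ``noise_sd`` (so the marginal standard deviation is
``noise_sd / sqrt(1 - ar1_phi**2)``), run through a 50-step burn-in so the
process is stationary from the first emitted ring.

The paleosol generator emits a horizon profile (surface -> parent) whose
recomputed CIA-K values follow requested per-horizon increments over the
parent material, by depleting Ca and Na and mildly enriching Al upward —
the down-profile pattern of a B horizon leached under an active climate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dendro_io import RingWidthSeries
from . import paleosol as _paleosol

__all__ = [
    "ClimateComponent",
    "ForestSimConfig",
    "SimulatedForest",
    "REFERENCE_MARKERS",
    "REFERENCE_OFFSETS",
    "reference_climate_signal",
    "reference_forest_config",
    "growth_coupling_config",
    "simulate_forest",
    "simulate_paleosol",
]

_BURN_IN = 50


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class ClimateComponent:
    """One sinusoidal component of the shared climate signal.

    ``on_interval`` gates the component to a sub-interval of the chronology
    (inclusive year bounds) to emulate non-stationary oscillations; ``None``
    means always on.
    """

    period: float
    amplitude: float = 1.0
    phase: float = 0.0
    on_interval: tuple[int, int] | None = None

    def evaluate(self, years: np.ndarray) -> np.ndarray:
        c = self.amplitude * np.sin(2 * np.pi * years / self.period + self.phase)
        if self.on_interval is not None:
            lo, hi = self.on_interval
            c = np.where((years >= lo) & (years <= hi), c, 0.0)
        return c


@dataclass
class ForestSimConfig:
    """Parameters of a simulated fossil forest.

    ``years`` is the ring count of each tree; with per-tree ``offsets``
    (start-year shifts on the common chronology axis) the assembled
    chronology spans ``years + max(offsets) - min(offsets)`` years.
    """

    n_trees: int = 6
    years: int = 120
    radii_per_tree: int = 2
    w0: float = 2.5                # juvenile width, mm
    decay: float = 0.01            # age-trend decay, 1/yr
    floor: float = 0.3             # asymptotic mature width, mm
    climate_signal: list[ClimateComponent] = field(
        default_factory=lambda: [ClimateComponent(period=30.0, amplitude=1.0)]
    )
    ar1_phi: float = 0.3
    noise_sd: float = 0.3          # AR(1) innovation sd in log-width
    signal_gain: float = 0.3       # coupling of C(t) into log-width
    marker_years: dict[int, float] = field(default_factory=dict)
    offsets: list[int] | None = None   # per-tree start-year shifts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 2:
            raise ConfigError("n_trees must be >= 2")
        if self.years < 20:
            raise ConfigError("years must be >= 20 (minimum replicable span)")
        if self.radii_per_tree < 2:
            raise ConfigError("radii_per_tree must be >= 2")
        if not (0 <= self.ar1_phi < 1):
            raise ConfigError("ar1_phi must be in [0, 1)")
        for name in ("w0", "floor"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigError(f"{name} must be positive and finite")
        if not np.isfinite(self.decay) or self.decay < 0:
            raise ConfigError("decay must be >= 0 and finite")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for m in self.marker_years.values():
            if not np.isfinite(m) or m <= 0:
                raise ConfigError("marker multipliers must be positive")
        if self.offsets is None:
            self.offsets = [0] * self.n_trees
        if len(self.offsets) != self.n_trees:
            raise ConfigError("offsets must have one entry per tree")

    def climate(self, years: np.ndarray) -> np.ndarray:
        """Shared climate signal C(t) on the chronology year axis."""
        years = np.asarray(years, dtype=float)
        c = np.zeros_like(years)
        for comp in self.climate_signal:
            c += comp.evaluate(years)
        return c


@dataclass
class SimulatedForest:
    """Generator output: series plus the ground truth used to make them."""

    series: list[RingWidthSeries]
    true_climate: np.ndarray       # C(t) on chronology years
    climate_years: np.ndarray
    true_offsets: dict[str, int]   # per-series start-year shift
    config: ForestSimConfig

    @property
    def true_span(self) -> int:
        """Span of the union of aligned series on the chronology axis."""
        off = np.asarray(self.config.offsets)
        return self.config.years + int(off.max() - off.min())

    def tree_series(self, tree_id: str) -> list[RingWidthSeries]:
        return [s for s in self.series if s.tree_id == tree_id]


# Reference study conditions for parameter-recovery experiments: a 30-yr
# oscillation (the headline periodicity) over a 12-component random-phase
# comb of short periods (2.3-9.7 yr) standing in for broadband shared
# interannual climate, plus an aperiodic sequence of anomalously
# narrow/wide marker years.  A pure tone cannot anchor cross-dating (it
# self-aligns at every near-multiple of its period); the comb and the
# markers are what make lags identifiable, as in real wood.
_COMB_PERIODS = (2.3, 2.62, 2.99, 3.41, 3.88, 4.42, 5.04, 5.75, 6.55,
                 7.47, 8.51, 9.7)
_COMB_PHASES = (3.14, 0.724, 5.417, 5.262, 1.31, 6.188, 4.421, 1.543,
                5.162, 1.357, 0.019, 2.694)
REFERENCE_MARKERS = {8: 1.9, 12: 0.5, 18: 1.75, 28: 0.55, 39: 0.45,
                     46: 0.45, 55: 0.45, 65: 1.8, 73: 0.55, 78: 0.5,
                     89: 0.5, 100: 1.8, 110: 1.9}
REFERENCE_OFFSETS = (0, 4, 9, 13, 18, 25)


def reference_climate_signal(main_period: float = 30.0,
                             main_amplitude: float = 1.0,
                             comb_amplitude: float = 0.35
                             ) -> list[ClimateComponent]:
    """The reference shared climate signal: one main tone plus the comb."""
    comps = [ClimateComponent(period=main_period, amplitude=main_amplitude)]
    comps += [ClimateComponent(period=p, amplitude=comb_amplitude, phase=ph)
              for p, ph in zip(_COMB_PERIODS, _COMB_PHASES)]
    return comps


def reference_forest_config(seed: int = 0, **overrides) -> ForestSimConfig:
    """Study conditions for recovery experiments: 6 trees x 2 radii x 100 yr,
    germination offsets spanning 25 yr (assembled span 125 yr), reference
    climate signal and marker years, gain 0.5, AR(1) noise phi=0.4 sd=0.3."""
    kwargs: dict = dict(
        n_trees=6, years=100, radii_per_tree=2,
        signal_gain=0.5, noise_sd=0.3, ar1_phi=0.4,
        climate_signal=reference_climate_signal(),
        marker_years=dict(REFERENCE_MARKERS),
        offsets=list(REFERENCE_OFFSETS), seed=seed,
    )
    kwargs.update(overrides)
    return ForestSimConfig(**kwargs)


def growth_coupling_config(seed: int = 0,
                           direction: str = "negative") -> ForestSimConfig:
    """Study conditions for the growth-response direction experiment.

    4 trees x 2 radii x 120 yr, aligned (no offsets), with a 30-yr
    oscillation (crests at years 0, 30, 60, ...) over the reference comb.
    The oscillation is coupled to growth through 7-year episodes of
    anomalously narrow rings (x0.55, ``direction="negative"``: climate
    extremes suppress growth) or anomalously wide rings (x1.8,
    ``direction="positive"``) centred on the crests at years 30/60/90,
    with a matching ``signal_gain`` of -/+0.3.
    """
    if direction not in ("negative", "positive"):
        raise ConfigError("direction must be 'negative' or 'positive'")
    sign = -1.0 if direction == "negative" else 1.0
    mult = 0.55 if direction == "negative" else 1.8
    markers = {c + d: mult for c in (30, 60, 90) for d in range(-3, 4)}
    comps = [ClimateComponent(period=30.0, amplitude=1.0, phase=np.pi / 2)]
    comps += [ClimateComponent(period=p, amplitude=0.35, phase=ph)
              for p, ph in zip(_COMB_PERIODS, _COMB_PHASES)]
    return ForestSimConfig(
        n_trees=4, years=120, radii_per_tree=2, signal_gain=0.3 * sign,
        noise_sd=0.3, ar1_phi=0.3, climate_signal=comps,
        marker_years=markers, offsets=[0, 0, 0, 0], seed=seed,
    )


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) path of length n (Gaussian innovations, burn-in)."""
    if sd == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd, size=n + _BURN_IN)
    out = np.empty(n + _BURN_IN)
    out[0] = innov[0] / np.sqrt(1 - phi**2) if phi > 0 else innov[0]
    for t in range(1, n + _BURN_IN):
        out[t] = phi * out[t - 1] + innov[t]
    return out[_BURN_IN:]


def simulate_forest(config: ForestSimConfig) -> SimulatedForest:
    """Simulate a cross-datable forest of ring-width series.

    A single root ``SeedSequence(config.seed)`` is split into one child per
    radius, in (tree, radius) order, so any one series is reproducible and
    adding trees does not reshuffle the noise of earlier ones.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_trees * cfg.radii_per_tree)

    ages = np.arange(cfg.years, dtype=float)
    trend = np.maximum(cfg.floor, cfg.w0 * np.exp(-cfg.decay * ages))

    series: list[RingWidthSeries] = []
    true_offsets: dict[str, int] = {}
    for t in range(cfg.n_trees):
        offset = int(cfg.offsets[t])
        years = np.arange(offset, offset + cfg.years)
        c = cfg.climate(years)
        marker = np.ones(cfg.years)
        for year, mult in cfg.marker_years.items():
            idx = year - offset
            if 0 <= idx < cfg.years:
                marker[idx] = mult
        for r in range(cfg.radii_per_tree):
            rng = np.random.default_rng(children[t * cfg.radii_per_tree + r])
            eps = _ar1(rng, cfg.years, cfg.ar1_phi, cfg.noise_sd)
            widths = trend * np.exp(cfg.signal_gain * c + eps) * marker
            # the true offset stays hidden in metadata: every emitted series
            # starts at relative year 0, as an undated fossil sample would
            sid = f"T{t + 1:02d}R{r + 1}"
            series.append(
                RingWidthSeries(series_id=sid, tree_id=f"T{t + 1:02d}",
                                radius_id=str(r + 1), first_year=0,
                                widths=widths)
            )
            true_offsets[sid] = offset

    lo = min(cfg.offsets)
    hi = max(cfg.offsets) + cfg.years - 1
    climate_years = np.arange(lo, hi + 1)
    return SimulatedForest(
        series=series,
        true_climate=cfg.climate(climate_years),
        climate_years=climate_years,
        true_offsets=true_offsets,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Paleosol profiles
# ---------------------------------------------------------------------------

def simulate_paleosol(
    n_horizons: int,
    parent_chem: dict[str, float],
    weathering_gradient: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    horizon_thickness_cm: float = 20.0,
) -> "_paleosol.PaleosolProfile":
    """Simulate a weathered soil profile over known parent material.

    Parameters
    ----------
    n_horizons
        Total horizons including the parent (>= 2); horizons are ordered
        surface -> parent.
    parent_chem
        Oxide weight percents of the parent material (must sum to <= 100).
    weathering_gradient
        CIA-K increment of each non-parent horizon over the parent CIA-K,
        ordered surface -> deepest B horizon (length ``n_horizons - 1``).
    noise_sd
        Gaussian analytical noise added to each oxide, wt%.

    Each B horizon's composition is built by depleting CaO and Na2O
    (proportionally) and enriching Al2O3 by 1% per CIA-K point so that the
    horizon's recomputed CIA-K equals parent CIA-K plus the requested
    increment (before noise).
    """
    if n_horizons < 2:
        raise ConfigError("n_horizons must be >= 2 (>= 1 B horizon + parent)")
    if len(weathering_gradient) != n_horizons - 1:
        raise ConfigError("weathering_gradient needs n_horizons - 1 entries")
    for ox, wt in parent_chem.items():
        if ox not in _paleosol.OXIDE_MOLAR_MASS:
            raise ConfigError(f"unknown oxide {ox!r}")
        if not np.isfinite(wt) or wt < 0:
            raise ConfigError(f"negative or non-finite {ox} requested")
    if sum(parent_chem.values()) > 100.0 + 1e-9:
        raise ConfigError("parent chemistry must sum to <= 100 wt%")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    parent_molar = _paleosol.to_molar(parent_chem)
    ciak_parent = _paleosol.cia_k(parent_molar)

    horizons = []
    for i, inc in enumerate(weathering_gradient):
        target = ciak_parent + inc
        if not (0 < target < 100):
            raise ConfigError(
                f"horizon {i}: target CIA-K {target:.1f} outside (0, 100); "
                "gradient would require negative oxide mass"
            )
        chem = dict(parent_chem)
        al_factor = 1.0 + 0.01 * inc
        if al_factor <= 0:
            raise ConfigError(f"horizon {i}: gradient drives Al2O3 negative")
        chem["Al2O3"] = parent_chem["Al2O3"] * al_factor
        al_mol = chem["Al2O3"] / _paleosol.OXIDE_MOLAR_MASS["Al2O3"]
        # CIA-K = 100*Al/(Al+Ca+Na): solve for the Ca+Na molar sum
        cana_target = al_mol * (100.0 / target - 1.0)
        cana_parent = (parent_molar["CaO"] + parent_molar["Na2O"])
        if cana_parent <= 0:
            raise ConfigError("parent must contain Ca or Na to weather")
        f = cana_target / cana_parent
        if f < 0:
            raise ConfigError(f"horizon {i}: gradient drives Ca/Na negative")
        chem["CaO"] = parent_chem.get("CaO", 0.0) * f
        chem["Na2O"] = parent_chem.get("Na2O", 0.0) * f
        if noise_sd > 0:
            for ox in chem:
                chem[ox] = max(0.0, chem[ox] + rng.normal(0.0, noise_sd))
        horizons.append(
            _paleosol.Horizon(label=f"B{i + 1}",
                              depth_cm=(i + 1) * horizon_thickness_cm,
                              oxides=chem)
        )
    horizons.append(
        _paleosol.Horizon(label="C", depth_cm=n_horizons * horizon_thickness_cm,
                          oxides=dict(parent_chem))
    )
    return _paleosol.PaleosolProfile(horizons=horizons,
                                     parent_index=n_horizons - 1)
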
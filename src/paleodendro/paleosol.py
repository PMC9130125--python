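"""Paleosol major-element climate proxies.

The chain runs: oxide weight percent -> molar proportions -> weathering
indices (CIA, with an optional authigenic-K correction, and CIA-K) ->
transfer functions for mean annual precipitation (MAP) and land surface
temperature (LST) -> annualized energy terms (Eppt, energy delivered by
precipitation; ET, evapotranspiration) -> humidity-province / floral-regime
classification, plus a profile-level quality-control check that pedogenic
chemical contrast is actually preserved.

Indices (molar):

    CIA   = 100 * Al2O3 / (Al2O3 + CaO* + Na2O + K2O)
    CIA-K = 100 * Al2O3 / (Al2O3 + CaO* + Na2O)

where CaO* is silicate-bound Ca.  By default CaO* = CaO (appropriate for
carbonate-free profiles); a McLennan-style cap CaO* = min(CaO, Na2O) is
available via ``cao_star="mclennan"``.

Transfer-function coefficients are deliberately *configuration*, not
constants of the code: the shipped defaults are the standard CIA-K -> MAP
exponential calibration, a provisional linear CIA -> LST pair, and simple
energy-balance stand-in forms for Eppt and ET (documented in
``docs/methods.md``).  ``strict=True`` refuses to run on shipped defaults
so that a study can insist on explicit coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OXIDE_MOLAR_MASS",
    "Horizon",
    "PaleosolProfile",
    "ClimateEstimate",
    "TransferConfig",
    "to_molar",
    "cia",
    "cia_k",
    "k_correction",
    "map_from_ciak",
    "lst_from_cia",
    "eppt_et",
    "humidity_province",
    "profile_qc",
    "estimate_climate",
]

#: g/mol of the reported oxides
OXIDE_MOLAR_MASS = {
    "Al2O3": 101.96,
    "CaO": 56.08,
    "Na2O": 61.98,
    "K2O": 94.20,
    "MgO": 40.30,
    "MnO": 70.94,
}


class PaleosolError(ValueError):
    pass


@dataclass
class Horizon:
    label: str
    depth_cm: float
    oxides: dict[str, float]

    def __post_init__(self) -> None:
        for ox, wt in self.oxides.items():
            if ox not in OXIDE_MOLAR_MASS:
                raise PaleosolError(f"unknown oxide {ox!r}")
            if not np.isfinite(wt) or wt < 0:
                raise PaleosolError(f"{self.label}: {ox} must be >= 0")


@dataclass
class PaleosolProfile:
    """Ordered horizons, surface -> parent; ``parent_index`` marks parent."""

    horizons: list[Horizon]
    parent_index: int = -1

    def __post_init__(self) -> None:
        if not self.horizons:
            raise PaleosolError("profile needs >= 1 horizon")
        self.parent_index = range(len(self.horizons))[self.parent_index]
        depths = [h.depth_cm for h in self.horizons]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise PaleosolError("horizon depths must increase downward")

    @property
    def parent(self) -> Horizon:
        return self.horizons[self.parent_index]

    @property
    def b_horizons(self) -> list[Horizon]:
        return [h for i, h in enumerate(self.horizons)
                if i != self.parent_index and h.label.upper().startswith("B")]


# ---------------------------------------------------------------------------
# Index arithmetic
# ---------------------------------------------------------------------------

def to_molar(oxides: dict[str, float]) -> dict[str, float]:
    """Convert oxide weight percent to molar proportions (wt% / molar mass)."""
    out = {}
    for ox, wt in oxides.items():
        if ox not in OXIDE_MOLAR_MASS:
            raise PaleosolError(f"unknown oxide {ox!r}")
        out[ox] = wt / OXIDE_MOLAR_MASS[ox]
    return out


def _cao_star(molar: dict[str, float], mode: str) -> float:
    ca = molar.get("CaO", 0.0)
    if mode == "cao":
        return ca
    if mode == "mclennan":
        return min(ca, molar.get("Na2O", 0.0))
    raise PaleosolError(f"unknown CaO* mode {mode!r}")


def cia(molar: dict[str, float], cao_star: str = "cao") -> float:
    """Chemical index of alteration, molar, 0-100."""
    al = molar.get("Al2O3", 0.0)
    if al <= 0:
        raise PaleosolError("CIA needs Al2O3 > 0")
    denom = (al + _cao_star(molar, cao_star) + molar.get("Na2O", 0.0)
             + molar.get("K2O", 0.0))
    return 100.0 * al / denom


def cia_k(molar: dict[str, float], cao_star: str = "cao") -> float:
    """CIA-K: the K-free variant (immune to potash metasomatism), 0-100."""
    al = molar.get("Al2O3", 0.0)
    if al <= 0:
        raise PaleosolError("CIA-K needs Al2O3 > 0")
    denom = al + _cao_star(molar, cao_star) + molar.get("Na2O", 0.0)
    return 100.0 * al / denom


def k_correction(molar: dict[str, float], parent_molar: dict[str, float],
                 cao_star: str = "cao") -> tuple[float, dict[str, float]]:
    """CIA corrected for authigenic (post-burial) K enrichment.

    The parent's molar K fraction m = K/(Al+Ca*+Na+K) is taken as the
    pre-metasomatism K proportion; the horizon's K is replaced by
    K_corr = m*(Al+Ca*+Na)/(1-m) and CIA recomputed.  The map is a fixed
    point when the horizon is already at the parent proportion, and is
    idempotent.

    Returns ``(cia_corrected, corrected_molar)``.
    """
    p_al = parent_molar.get("Al2O3", 0.0)
    p_base = p_al + _cao_star(parent_molar, cao_star) + parent_molar.get("Na2O", 0.0)
    p_k = parent_molar.get("K2O", 0.0)
    m = p_k / (p_base + p_k) if (p_base + p_k) > 0 else 0.0
    if m >= 1.0:
        raise PaleosolError("parent K fraction m >= 1: correction undefined")
    base = (molar.get("Al2O3", 0.0) + _cao_star(molar, cao_star)
            + molar.get("Na2O", 0.0))
    k_corr = m * base / (1.0 - m)
    corrected = dict(molar)
    corrected["K2O"] = k_corr
    return cia(corrected, cao_star=cao_star), corrected


# ---------------------------------------------------------------------------
# Transfer functions (all coefficients live in config)
# ---------------------------------------------------------------------------

@dataclass
class TransferConfig:
    """Versioned coefficients for the climate transfer functions.

    Shipped defaults: the standard exponential CIA-K -> MAP calibration
    (MAP = 221.1 * exp(0.0197 * CIA-K) mm/yr); a provisional linear
    CIA -> LST pair (T = 0.56*CIA - 25.7 deg C); Eppt as the sensible-heat
    flux delivered by rain, MAP[kg m-2 yr-1] * c_w * (LST - T_ref); ET as a
    temperature-scaled annual potential evapotranspiration
    (pet_coeff * LST mm/yr) expressed as the same sensible-heat flux so the
    Eppt/ET ratio reduces to the MAP/PET aridity index.  All are
    config-replaceable; ``strict`` refuses the shipped defaults.
    """

    version: str = "default-1"
    map_c1_mm: float = 221.1
    map_c2: float = 0.0197
    lst_a: float = 0.56            # degC per CIA unit (provisional default)
    lst_b: float = -25.7           # degC
    water_specific_heat_mj: float = 4.186e-3   # MJ kg-1 K-1
    reference_temp_c: float = 0.0
    pet_coeff_mm_per_degc: float = 58.93       # Holdridge-style annual PET
    energy_units: str = "MJ/m2/yr"
    province_boundaries: list[dict] | None = None
    is_default: bool = True

    def require_explicit(self, strict: bool) -> None:
        if strict and self.is_default:
            raise PaleosolError(
                "strict mode: shipped default transfer coefficients refused; "
                "supply an explicit TransferConfig"
            )


def map_from_ciak(cia_k_value: float, config: TransferConfig | None = None,
                  strict: bool = False) -> float:
    """Mean annual precipitation (mm/yr) from CIA-K, exponential calibration."""
    cfg = config or TransferConfig()
    cfg.require_explicit(strict)
    if not (0 <= cia_k_value <= 100):
        raise PaleosolError("CIA-K must be in [0, 100]")
    return cfg.map_c1_mm * np.exp(cfg.map_c2 * cia_k_value)


def lst_from_cia(cia_value: float, config: TransferConfig | None = None,
                 strict: bool = False) -> float:
    """Land surface temperature (deg C) from (K-corrected) CIA, linear."""
    cfg = config or TransferConfig()
    cfg.require_explicit(strict)
    if not (0 <= cia_value <= 100):
        raise PaleosolError("CIA must be in [0, 100]")
    return cfg.lst_a * cia_value + cfg.lst_b


def eppt_et(map_mm_yr: float, lst_celsius: float,
            config: TransferConfig | None = None,
            strict: bool = False) -> tuple[float, float]:
    """Annual Eppt and ET energy terms (MJ m-2 yr-1) from MAP and LST.

    Eppt = (MAP as water mass flux) * c_w * (LST - T_ref); ET uses the
    temperature-scaled potential-evapotranspiration mass flux in the same
    form.  1 mm/yr of water over 1 m2 is 1 kg/yr.
    """
    cfg = config or TransferConfig()
    cfg.require_explicit(strict)
    if map_mm_yr <= 0:
        raise PaleosolError("MAP must be > 0")
    dT = lst_celsius - cfg.reference_temp_c
    eppt = map_mm_yr * cfg.water_specific_heat_mj * dT
    pet_mm = cfg.pet_coeff_mm_per_degc * max(lst_celsius, 0.0)
    et = pet_mm * cfg.water_specific_heat_mj * dT
    return eppt, et


# Default humidity-province boundaries: polylines Eppt = r * ET in (ET, Eppt)
# space.  With the shipped Eppt/ET forms the slope r is the MAP/PET aridity
# ratio; labels dry -> wet.  Synthetic stand-in geometry, config-replaceable.
_DEFAULT_RATIOS = [0.05, 0.2, 0.5, 0.65, 1.0]
_DEFAULT_LABELS = [
    ("hyperarid", "desert"),
    ("arid", "desert shrubland"),
    ("semiarid", "steppe-woodland"),
    ("dry subhumid", "dry forest"),
    ("humid", "forest"),
    ("perhumid", "rainforest"),
]


def _default_boundaries() -> list[dict]:
    et_grid = [0.0, 1.0, 10.0, 100.0, 1000.0, 10000.0]
    return [
        {"name": f"boundary_{r}", "points": [(et, r * et) for et in et_grid]}
        for r in _DEFAULT_RATIOS
    ]


def _line_eppt_at(points: list[tuple[float, float]], et: float) -> float:
    xs = np.array([p[0] for p in points], dtype=float)
    ys = np.array([p[1] for p in points], dtype=float)
    if et <= xs[0]:
        i = 0
    elif et >= xs[-1]:
        i = len(xs) - 2
    else:
        i = int(np.searchsorted(xs, et) - 1)
    x0, x1, y0, y1 = xs[i], xs[i + 1], ys[i], ys[i + 1]
    return y0 + (y1 - y0) * (et - x0) / (x1 - x0) if x1 != x0 else y0


def humidity_province(
    eppt: float,
    et: float,
    boundaries: list[dict] | None = None,
    labels: list[tuple[str, str]] | None = None,
) -> tuple[str, str]:
    """Classify a point in (ET, Eppt) space between ordered boundary polylines.

    ``boundaries`` is an ordered (dry -> wet) list of non-crossing polylines
    ``{"points": [(et, eppt), ...]}``; ``labels`` has one (province,
    floral_regime) pair per region, i.e. ``len(boundaries) + 1`` entries.
    Points exactly on a boundary go to the wetter region.
    """
    if boundaries is None:
        boundaries = _default_boundaries()
    if labels is None:
        labels = _DEFAULT_LABELS
    if len(labels) != len(boundaries) + 1:
        raise PaleosolError("need len(boundaries) + 1 labels")
    # validate ordering / non-crossing on a probe grid
    probe = np.linspace(0.0, max(abs(et), 1.0) * 2 + 1.0, 32)
    prev = None
    for b in boundaries:
        vals = np.array([_line_eppt_at(b["points"], e) for e in probe])
        if prev is not None and np.any(vals < prev - 1e-9):
            raise PaleosolError(
                f"boundary {b.get('name', '?')!r} crosses the previous one"
            )
        prev = vals
    region = 0
    for b in boundaries:
        if eppt >= _line_eppt_at(b["points"], et):   # ties -> wetter side
            region += 1
        else:
            break
    return labels[region]


# ---------------------------------------------------------------------------
# Profile-level QC and the full estimate
# ---------------------------------------------------------------------------

def profile_qc(profile: PaleosolProfile, threshold_percent: float = 5.0,
               cao_star: str = "cao") -> dict:
    """Check that pedogenic chemical contrast is preserved.

    The contrast is the relative difference between the mean CIA-K of the
    B horizons and the parent CIA-K; the profile passes when it exceeds
    ``threshold_percent`` (default 5%), i.e. soil-forming chemistry is
    distinguishable from the parent material.
    """
    bs = profile.b_horizons
    if not bs:
        raise PaleosolError("profile has no B horizons")
    parent_ciak = cia_k(to_molar(profile.parent.oxides), cao_star=cao_star)
    if parent_ciak == 0:
        raise PaleosolError("parent CIA-K is zero")
    b_ciak = float(np.mean([cia_k(to_molar(h.oxides), cao_star=cao_star)
                            for h in bs]))
    contrast = 100.0 * abs(b_ciak - parent_ciak) / parent_ciak
    return {
        "ciak_parent": parent_ciak,
        "ciak_b_mean": b_ciak,
        "ciak_contrast_percent": contrast,
        "passes": bool(contrast > threshold_percent),
    }


@dataclass
class ClimateEstimate:
    """Per-horizon proxy estimates for one paleosol profile."""

    label: str
    depth_cm: float
    cia: float
    cia_corrected: float
    cia_k: float
    map_mm_yr: float
    lst_celsius: float
    eppt: float
    et: float
    humidity_province: str
    floral_regime: str


def estimate_climate(
    profile: PaleosolProfile,
    config: TransferConfig | None = None,
    cao_star: str = "cao",
    strict: bool = False,
) -> list[ClimateEstimate]:
    """Run the full proxy chain on every non-parent horizon."""
    cfg = config or TransferConfig()
    cfg.require_explicit(strict)
    parent_molar = to_molar(profile.parent.oxides)
    out = []
    for i, h in enumerate(profile.horizons):
        if i == profile.parent_index:
            continue
        molar = to_molar(h.oxides)
        c = cia(molar, cao_star=cao_star)
        c_corr, _ = k_correction(molar, parent_molar, cao_star=cao_star)
        ck = cia_k(molar, cao_star=cao_star)
        map_mm = map_from_ciak(ck, cfg)
        lst = lst_from_cia(c_corr, cfg)
        eppt, et = eppt_et(map_mm, lst, cfg)
        prov, floral = humidity_province(eppt, et,
                                         cfg.province_boundaries)
        out.append(ClimateEstimate(
            label=h.label, depth_cm=h.depth_cm, cia=c, cia_corrected=c_corr,
            cia_k=ck, map_mm_yr=map_mm, lst_celsius=lst, eppt=eppt, et=et,
            humidity_province=prov, floral_regime=floral,
        ))
    return out
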
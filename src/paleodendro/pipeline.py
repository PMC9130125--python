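"""End-to-end orchestration: simulate -> crossdate -> chronology -> wavelets
-> growth statistic / coherence / paleosol, with a reproducible run manifest.

The stage functions here are also the high-level library API used by the
analysis drivers, the test suite and the acceptance script; the CLI is a
thin shell over :func:`run_pipeline`.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .dendro_io import (RingWidthSeries, write_rwl, write_series_csv,
                        read_series_csv, read_rwl, write_json,
                        write_matrix_csv)
from . import crossdating as xd
from . import chronology as chron_mod
from . import spectral
from . import growth_climate as gc
from . import paleosol as ps
from . import synthetic_data as synth

__all__ = [
    "PipelineError",
    "validate_config",
    "crossdate_forest",
    "assemble_chronology",
    "aligned_forest_chronology",
    "RunManifest",
    "run_pipeline",
]

STAGES = ("simulate", "crossdate", "chrono", "cwt", "coherence",
          "growthstat", "paleosol")


class PipelineError(ValueError):
    pass


# ---------------------------------------------------------------------------
# High-level stage functions (library API)
# ---------------------------------------------------------------------------

def crossdate_forest(
    series: list[RingWidthSeries],
    min_overlap: int = xd.MIN_OVERLAP,
    thresholds: xd.MatchThresholds | None = None,
) -> tuple[list[RingWidthSeries], list[xd.CrossMatchResult], xd.MasterAlignment]:
    """Intra-tree averaging, inter-tree matching, and master alignment.

    Replicate radii of each tree are cross-matched and averaged; the
    per-tree mean series are then matched pairwise and the best accepted
    lag of each pair feeds the master alignment graph.

    Returns ``(tree_means, all_pair_results, master)``.
    """
    by_tree: dict[str, list[RingWidthSeries]] = {}
    for s in series:
        by_tree.setdefault(s.tree_id, []).append(s)
    means = [xd.average_radii(radii, tree_id=tid, min_overlap=min_overlap,
                              thresholds=thresholds)
             for tid, radii in by_tree.items()]

    results: list[xd.CrossMatchResult] = []
    best: list[xd.CrossMatchResult] = []
    for i, a in enumerate(means):
        for b in means[i + 1:]:
            res = xd.crossmatch(a, b, min_overlap=min_overlap,
                                thresholds=thresholds)
            results.extend(res)
            # only the top-ranked lag can be the accepted match (see
            # crossdating.average_radii for the rationale)
            top = res[0] if res and res[0].accepted else None
            if top is not None:
                best.append(top)
    master = xd.build_master(means, best)
    return means, results, master


def assemble_chronology(
    aligned: list[RingWidthSeries],
    cutoff_frac: float = 0.67,
    method: str = "biweight",
    sss_cutoff: float = chron_mod.SSS_CUTOFF,
) -> chron_mod.Chronology:
    """Detrend aligned series and average their RWI into a chronology."""
    indexed = []
    for s in aligned:
        fit = chron_mod.spline_detrend(s, cutoff_frac=cutoff_frac)
        indexed.append(chron_mod.to_rwi(s, fit))
    return chron_mod.average_chronology(indexed, method=method,
                                        sss_cutoff=sss_cutoff)


def aligned_forest_chronology(forest, cutoff_frac: float = 0.67,
                              method: str = "biweight"):
    """Chronology for a forest whose series are already on one year axis
    (e.g. a simulation without offsets): radii of each tree are averaged
    arithmetically, then detrended and combined."""
    by_tree: dict[str, list[RingWidthSeries]] = {}
    for s in forest.series:
        by_tree.setdefault(s.tree_id, []).append(s)
    means = []
    for tid, radii in by_tree.items():
        w = np.mean([r.widths for r in radii], axis=0)
        means.append(RingWidthSeries(series_id=tid, tree_id=tid,
                                     radius_id="mean",
                                     first_year=radii[0].first_year,
                                     widths=w))
    return assemble_chronology(means, cutoff_frac=cutoff_frac, method=method)


# ---------------------------------------------------------------------------
# Config handling
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG: dict = {
    "stages": ["simulate", "crossdate", "chrono", "cwt", "growthstat"],
    "simulate": {},                # ForestSimConfig fields
    "crossdate": {"min_overlap": 20,
                  "thresholds": {"t_min": 3.5, "glk_min": 65.0,
                                 "r_min": 0.5}},
    "chronology": {"cutoff_frac": 0.67, "method": "biweight",
                   "sss_cutoff": 0.5},
    "spectral": {"wavelet": "morlet", "voices_per_octave": 16,
                 "level": 0.05, "method": "theoretical", "n_sim": 1000},
    "growth": {"band": [20.0, 40.0], "wavelet": "dog"},
    "coherence": {"inputs": None, "n_sim": 300, "level": 0.05},
    "paleosol": {"input": None, "simulate": None, "cao_star": "cao",
                 "strict": False},
    "seed": 0,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def validate_config(config: dict | None) -> dict:
    """Merge a user config over defaults and check it against the schema.

    Raises before any computation on unknown keys, unknown stages, or
    out-of-range numerics.
    """
    config = config or {}
    if not isinstance(config, dict):
        raise PipelineError("config must be a mapping")
    unknown = set(config) - set(_DEFAULT_CONFIG)
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    cfg = _merge(_DEFAULT_CONFIG, config)
    for stage in cfg["stages"]:
        if stage not in STAGES:
            raise PipelineError(f"unknown stage {stage!r}")
    sp = cfg["spectral"]
    if not (0.0 < sp["level"] < 1.0):
        raise PipelineError("spectral.level must be in (0, 1)")
    if sp["wavelet"] not in ("morlet", "dog"):
        raise PipelineError(f"unknown wavelet {sp['wavelet']!r}")
    band = cfg["growth"]["band"]
    if len(band) != 2 or band[0] >= band[1]:
        raise PipelineError("growth.band must be [low, high] with low < high")
    if not isinstance(cfg["seed"], int):
        raise PipelineError("seed must be an integer")
    return cfg


# ---------------------------------------------------------------------------
# Manifest and runner
# ---------------------------------------------------------------------------

def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: identical config + seed => identical digests."""

    config_hash: str
    seed: int
    version: str
    stages: list[str]
    artifacts: dict[str, str] = field(default_factory=dict)   # path -> sha256
    started: float = 0.0
    finished: float = 0.0

    def to_json(self) -> dict:
        return asdict(self)


def run_pipeline(config: dict | None = None, out_dir: str | Path = "results",
                 seed: int | None = None, quiet: bool = True) -> RunManifest:
    """Execute the configured stages in dependency order.

    Every stage writes its artifacts before the next stage reads them;
    failures raise with the stage name.  ``seed`` overrides the config
    seed.  Returns the run manifest (also written to ``manifest.json``).
    """
    import sys

    cfg = validate_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(config_hash=config_hash, seed=cfg["seed"],
                           version=__version__, stages=list(cfg["stages"]),
                           started=time.time())

    def log(msg: str) -> None:
        if not quiet:
            print(msg, file=sys.stderr)

    def record(path: Path) -> None:
        manifest.artifacts[path.name] = _sha256_file(path)

    state: dict = {}
    for stage in cfg["stages"]:
        t0 = time.time()
        try:
            _run_stage(stage, cfg, out, state, record)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        log(f"[{stage}] done in {time.time() - t0:.1f}s")

    manifest.finished = time.time()
    payload = manifest.to_json()
    # timestamps are informational and excluded from the digest record
    (out / "manifest.json").write_text(json.dumps(payload, indent=2) + "\n")
    return manifest


def _run_stage(stage: str, cfg: dict, out: Path, state: dict,
               record) -> None:
    seed = cfg["seed"]
    if stage == "simulate":
        sim_kwargs = dict(cfg["simulate"])
        sim_kwargs.setdefault("seed", seed)
        if "climate_signal" in sim_kwargs:
            sim_kwargs["climate_signal"] = [
                synth.ClimateComponent(**c) if isinstance(c, dict) else c
                for c in sim_kwargs["climate_signal"]
            ]
        forest = synth.simulate_forest(synth.ForestSimConfig(**sim_kwargs))
        state["series"] = forest.series
        state["forest"] = forest
        write_series_csv(forest.series, out / "series.csv")
        write_rwl(forest.series, out / "series.rwl")
        record(out / "series.csv")
        record(out / "series.rwl")
    elif stage == "crossdate":
        series = state.get("series")
        if series is None:
            raise PipelineError("no input series (run simulate or load data)")
        th = xd.MatchThresholds(**cfg["crossdate"]["thresholds"])
        means, results, master = crossdate_forest(
            series, min_overlap=cfg["crossdate"]["min_overlap"],
            thresholds=th)
        state["master"] = master
        import pandas as pd
        rows = [{
            "series_a": m.series_a, "series_b": m.series_b, "lag": m.lag,
            "n_overlap": m.n_overlap, "r": m.r, "t_bp": m.t_bp,
            "t_ho": m.t_ho, "glk": m.glk, "accepted": m.accepted,
        } for m in results]
        pd.DataFrame(rows).to_csv(out / "crossmatch_stats.csv", index=False)
        write_rwl(master.aligned, out / "aligned.rwl")
        record(out / "crossmatch_stats.csv")
        record(out / "aligned.rwl")
    elif stage == "chrono":
        master = state.get("master")
        if master is None:
            raise PipelineError("chrono needs the crossdate stage upstream")
        ch = assemble_chronology(
            master.aligned, cutoff_frac=cfg["chronology"]["cutoff_frac"],
            method=cfg["chronology"]["method"],
            sss_cutoff=cfg["chronology"]["sss_cutoff"])
        state["chronology"] = ch
        import pandas as pd
        pd.DataFrame({"year": ch.years, "rwi": ch.rwi,
                      "sample_depth": ch.sample_depth,
                      "sss": ch.sss}).to_csv(out / "chronology.csv",
                                             index=False)
        write_json({"rbar": ch.rbar, "sss_year": ch.sss_year,
                    "n_total": ch.n_total, "length": len(ch),
                    "mean_overlap": master.mean_overlap,
                    "excluded": master.excluded},
                   out / "chronology_summary.json")
        record(out / "chronology.csv")
        record(out / "chronology_summary.json")
    elif stage == "cwt":
        ch = state.get("chronology")
        if ch is None:
            raise PipelineError("cwt needs the chrono stage upstream")
        sp_cfg = cfg["spectral"]
        spec = spectral.cwt(ch.rwi, wavelet=sp_cfg["wavelet"],
                            voices_per_octave=sp_cfg["voices_per_octave"],
                            times=ch.years)
        spectral.rednoise_significance(
            spec, level=sp_cfg["level"], method=sp_cfg["method"],
            n_sim=sp_cfg["n_sim"], seed=seed)
        state["spectrum"] = spec
        write_matrix_csv(spec.power, spec.fourier_periods, spec.times,
                         out / "cwt_power.csv")
        write_matrix_csv(spec.signif_mask.astype(int), spec.fourier_periods,
                         spec.times, out / "cwt_signif.csv")
        write_json({"wavelet": spec.wavelet, "ar1_alpha": spec.ar1_alpha,
                    "coi": spec.coi, "scales": spec.scales,
                    "level": sp_cfg["level"]}, out / "cwt_meta.json")
        for name in ("cwt_power.csv", "cwt_signif.csv", "cwt_meta.json"):
            record(out / name)
    elif stage == "growthstat":
        ch = state.get("chronology")
        if ch is None:
            raise PipelineError("growthstat needs the chrono stage upstream")
        g_cfg = cfg["growth"]
        dog = spectral.cwt(ch.rwi, wavelet="dog",
                           voices_per_octave=cfg["spectral"]["voices_per_octave"],
                           times=ch.years)
        res = gc.growth_response(ch, dog, band=tuple(g_cfg["band"]),
                                 level=cfg["spectral"]["level"])
        state["growth"] = res
        write_json({
            "band": res.band, "n_significant": res.n_significant,
            "suppressed_fraction": res.suppressed_fraction,
            "enhanced_fraction": res.enhanced_fraction,
            "neutral_fraction": res.neutral_fraction,
            "significant_years": res.significant_years,
            "empty": res.empty,
        }, out / "growth_response.json")
        record(out / "growth_response.json")
    elif stage == "coherence":
        inputs = cfg["coherence"]["inputs"]
        if inputs is None or len(inputs) != 2:
            raise PipelineError(
                "coherence needs coherence.inputs = [csv_a, csv_b] "
                "(chronology CSVs with a 'rwi' column)"
            )
        import pandas as pd
        series_pair = []
        for p in inputs:
            df = pd.read_csv(p)
            if "rwi" not in df.columns:
                raise PipelineError(f"{p}: no 'rwi' column")
            series_pair.append(df.rwi.to_numpy())
        n = min(map(len, series_pair))
        sx = spectral.cwt(series_pair[0][:n])
        sy = spectral.cwt(series_pair[1][:n])
        coh = spectral.coherence(sx, sy, level=cfg["coherence"]["level"],
                                 n_sim=cfg["coherence"]["n_sim"], seed=seed)
        state["coherence"] = coh
        write_matrix_csv(coh.coherence, coh.fourier_periods, coh.times,
                         out / "coherence.csv")
        write_json({
            "fourier_periods": coh.fourier_periods,
            "mean_coherence_by_period": coh.mean_coherence_by_period,
            "period_significant": coh.period_significant.astype(int),
            "level": coh.level,
        }, out / "coherence_by_period.json")
        record(out / "coherence.csv")
        record(out / "coherence_by_period.json")
    elif stage == "paleosol":
        p_cfg = cfg["paleosol"]
        if p_cfg.get("input"):
            profile = _read_profile_csv(p_cfg["input"])
        elif p_cfg.get("simulate"):
            sim = dict(p_cfg["simulate"])
            sim.setdefault("seed", seed)
            profile = synth.simulate_paleosol(**sim)
        else:
            raise PipelineError("paleosol needs 'input' csv or 'simulate'")
        estimates = ps.estimate_climate(profile,
                                        cao_star=p_cfg["cao_star"],
                                        strict=p_cfg["strict"])
        qc = ps.profile_qc(profile, cao_star=p_cfg["cao_star"])
        state["paleosol"] = (estimates, qc)
        import pandas as pd
        pd.DataFrame([vars(e) for e in estimates]).to_csv(
            out / "paleosol_estimates.csv", index=False)
        write_json(qc, out / "paleosol_qc.json")
        record(out / "paleosol_estimates.csv")
        record(out / "paleosol_qc.json")
    else:  # pragma: no cover - guarded by validate_config
        raise PipelineError(f"unknown stage {stage!r}")


def _read_profile_csv(path: str | Path) -> ps.PaleosolProfile:
    """Horizon CSV: columns horizon, depth_cm, then oxide wt% columns.

    The parent is the horizon labelled 'C' (or the deepest horizon if no
    'C' label is present).
    """
    import pandas as pd
    df = pd.read_csv(path)
    oxide_cols = [c for c in df.columns if c in ps.OXIDE_MOLAR_MASS]
    horizons = [
        ps.Horizon(label=str(row["horizon"]), depth_cm=float(row["depth_cm"]),
                   oxides={c: float(row[c]) for c in oxide_cols})
        for _, row in df.iterrows()
    ]
    labels = [h.label.upper() for h in horizons]
    parent_index = labels.index("C") if "C" in labels else len(horizons) - 1
    return ps.PaleosolProfile(horizons=horizons, parent_index=parent_index)
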
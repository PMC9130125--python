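"""Statistical cross-matching of ring-width series.

Candidate alignments between two series are scanned exhaustively over all
integer lags with sufficient overlap and scored with the classic battery:

* ``t_BP`` — Student t on the Pearson correlation of Baillie–Pilcher
  transformed series (log of width over its 5-year centred moving mean);
* ``t_HO`` — the same t on Hollstein "Wuchswerte" (100·log10 of the
  consecutive-width ratio);
* ``r`` — the Pearson correlation underlying ``t_BP``;
* ``glk`` — Gleichläufigkeit, the percent of year-to-year intervals in
  which both series move in the same direction (ties scored 1/2).

A match is accepted when every configured threshold is met at that lag.
``build_master`` composes accepted pairwise lags along the match graph
into a single consistent alignment and reports the assembled chronology
span; series that fail to connect are excluded, mirroring the practice of
dropping samples without a reliable cross-match.

Lag convention: ``lag`` is the shift applied to series *b*'s year axis to
bring it onto *a*'s axis, i.e. ring ``y`` of *b* is compared with ring
``y + lag`` of *a*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dendro_io import RingWidthSeries

__all__ = [
    "CrossMatchResult",
    "MatchThresholds",
    "bp_transform",
    "ho_transform",
    "t_statistic",
    "gleichlauf",
    "crossmatch",
    "average_radii",
    "build_master",
]

BP_WINDOW = 5          # years; classic Baillie–Pilcher moving-mean window
MIN_OVERLAP = 20       # years; minimum span for a replicable cross-match


class CrossdatingError(ValueError):
    pass


@dataclass(frozen=True)
class MatchThresholds:
    t_min: float = 3.5
    glk_min: float = 65.0
    r_min: float = 0.5


@dataclass
class CrossMatchResult:
    """Statistics of one candidate alignment of series b against series a."""

    series_a: str
    series_b: str
    lag: int
    n_overlap: int
    r: float
    t_bp: float
    t_ho: float
    glk: float
    accepted: bool
    rationale: str = ""
    degenerate: bool = False


@dataclass
class IndexedSeries:
    """A transformed series on the same relative year axis."""

    first_year: int
    values: np.ndarray

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.values))


def bp_transform(series: RingWidthSeries, window: int = BP_WINDOW) -> IndexedSeries:
    """Baillie–Pilcher transform: ln(width / centred moving mean).

    Edge years without a full window are dropped, so the result is
    ``len(series) - window + 1`` long and starts ``window // 2`` years in.
    """
    n = len(series)
    if n <= window:
        raise CrossdatingError(
            f"series {series.series_id!r}: length {n} <= window {window}"
        )
    kernel = np.ones(window) / window
    mov = np.convolve(series.widths, kernel, mode="valid")
    half = window // 2
    centre = series.widths[half:n - (window - 1 - half)]
    return IndexedSeries(series.first_year + half, np.log(centre / mov))


def ho_transform(series: RingWidthSeries) -> IndexedSeries:
    """Hollstein growth values: 100 * log10(w[i+1] / w[i]); length n-1."""
    if len(series) < 2:
        raise CrossdatingError("Hollstein transform needs length >= 2")
    ratios = series.widths[1:] / series.widths[:-1]
    return IndexedSeries(series.first_year, 100.0 * np.log10(ratios))


def t_statistic(x: np.ndarray, y: np.ndarray) -> dict:
    """Pearson r and its Student t over an aligned overlap.

    ``t = r * sqrt(n-2) / sqrt(1-r^2)``.  Perfect correlation or a zero
    variance input is reported as degenerate (t = +/-inf or nan) rather
    than raising.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3 or n != y.size:
        raise CrossdatingError("t_statistic needs an aligned overlap n >= 3")
    sx = x - x.mean()
    sy = y - y.mean()
    vx = float(sx @ sx)
    vy = float(sy @ sy)
    if vx == 0.0 or vy == 0.0:
        return {"r": math.nan, "t": math.nan, "n": n, "degenerate": True}
    r = float(sx @ sy / math.sqrt(vx * vy))
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-12:
        return {"r": r, "t": math.copysign(math.inf, r), "n": n,
                "degenerate": True}
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return {"r": r, "t": t, "n": n, "degenerate": False}


def gleichlauf(x: RingWidthSeries, y: RingWidthSeries, lag: int = 0) -> float:
    """Percent parallel covariation over the overlap at the given lag.

    Year-to-year first differences are compared: both moving in the same
    (nonzero) direction or both flat scores 1, exactly one flat scores
    1/2, opposite directions score 0; GLK is 100 times the mean score.
    """
    ax, ay = _overlap(x, y, lag)
    if ax.size < 2:
        raise CrossdatingError("gleichlauf needs overlap >= 2 years")
    dx = np.sign(np.diff(ax))
    dy = np.sign(np.diff(ay))
    score = np.where(dx == dy, 1.0, np.where((dx == 0) | (dy == 0), 0.5, 0.0))
    return 100.0 * float(score.mean())


def _overlap(a: RingWidthSeries | IndexedSeries,
             b: RingWidthSeries | IndexedSeries,
             lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Aligned value arrays over the common years of a and b-shifted-by-lag."""
    a_vals = a.widths if isinstance(a, RingWidthSeries) else a.values
    b_vals = b.widths if isinstance(b, RingWidthSeries) else b.values
    b_first = b.first_year + lag
    lo = max(a.first_year, b_first)
    hi = min(a.first_year + len(a_vals), b_first + len(b_vals))
    if hi <= lo:
        return np.empty(0), np.empty(0)
    return (a_vals[lo - a.first_year: hi - a.first_year],
            b_vals[lo - b_first: hi - b_first])


def crossmatch(
    a: RingWidthSeries,
    b: RingWidthSeries,
    min_overlap: int = MIN_OVERLAP,
    thresholds: MatchThresholds | None = None,
) -> list[CrossMatchResult]:
    """Exhaustive lag scan of b against a, scored at every candidate lag.

    Results are sorted by descending ``t_bp`` (ties: higher glk, then
    smaller ``|lag|``); each carries all four statistics and an accepted
    flag (all thresholds met).  Returns an empty list when no lag has
    ``min_overlap`` raw years in common.
    """
    if thresholds is None:
        thresholds = MatchThresholds()
    if len(a) < min_overlap or len(b) < min_overlap:
        return []
    bp_a, bp_b = bp_transform(a), bp_transform(b)
    ho_a, ho_b = ho_transform(a), ho_transform(b)

    lag_lo = a.first_year - b.first_year - (len(b) - min_overlap)
    lag_hi = a.first_year - b.first_year + (len(a) - min_overlap)
    results: list[CrossMatchResult] = []
    for lag in range(lag_lo, lag_hi + 1):
        xa, xb = _overlap(a, b, lag)
        n_overlap = xa.size
        if n_overlap < min_overlap:
            continue
        ba, bb = _overlap(bp_a, bp_b, lag)
        ha, hb = _overlap(ho_a, ho_b, lag)
        if ba.size < 3 or ha.size < 3:
            continue
        st_bp = t_statistic(ba, bb)
        st_ho = t_statistic(ha, hb)
        glk = gleichlauf(a, b, lag)
        r = st_bp["r"]
        t_bp = st_bp["t"]
        degenerate = st_bp["degenerate"] or st_ho["degenerate"]
        # both t statistics must clear the gate: the two transforms are
        # quasi-independent, which suppresses small-overlap flukes
        ok = (
            not math.isnan(t_bp)
            and not math.isnan(st_ho["t"])
            and t_bp >= thresholds.t_min
            and st_ho["t"] >= thresholds.t_min
            and glk >= thresholds.glk_min
            and r >= thresholds.r_min
        )
        results.append(CrossMatchResult(
            series_a=a.series_id, series_b=b.series_id, lag=lag,
            n_overlap=n_overlap, r=r, t_bp=t_bp, t_ho=st_ho["t"], glk=glk,
            accepted=ok, degenerate=degenerate,
            rationale=("all thresholds met" if ok else "below threshold"),
        ))

    def key(res: CrossMatchResult):
        t = res.t_bp if not math.isnan(res.t_bp) else -math.inf
        return (-t, -res.glk, abs(res.lag))

    results.sort(key=key)
    return results


def average_radii(radii: list[RingWidthSeries], tree_id: str | None = None,
                  min_overlap: int = MIN_OVERLAP,
                  thresholds: MatchThresholds | None = None) -> RingWidthSeries:
    """Average replicate radii of one tree after intra-tree cross-matching.

    The first radius anchors the axis; each further radius is aligned at
    its best accepted lag (radii that fail to cross-match are dropped with
    a warning recorded) and the per-year arithmetic mean is taken.
    """
    if not radii:
        raise CrossdatingError("no radii given")
    tree_id = tree_id or radii[0].tree_id
    anchor = radii[0]
    aligned = [anchor]
    for r in radii[1:]:
        matches = crossmatch(anchor, r, min_overlap=min_overlap,
                             thresholds=thresholds)
        # a cross-match succeeds only when the best-supported lag itself
        # passes the gates; falling back to a lower-ranked accepted lag
        # would prefer a worse-supported alignment
        best = matches[0] if matches and matches[0].accepted else None
        if best is None:
            continue
        aligned.append(r.shifted(best.lag))
    lo = min(s.first_year for s in aligned)
    hi = max(s.last_year for s in aligned)
    total = np.zeros(hi - lo + 1)
    count = np.zeros(hi - lo + 1)
    for s in aligned:
        i = s.first_year - lo
        total[i:i + len(s)] += s.widths
        count[i:i + len(s)] += 1
    mean = total[count > 0] / count[count > 0]
    first = lo + int(np.flatnonzero(count > 0)[0])
    return RingWidthSeries(series_id=tree_id, tree_id=tree_id, radius_id="mean",
                           first_year=first, widths=mean,
                           precision=anchor.precision)


@dataclass
class MasterAlignment:
    """A consistent alignment of cross-matched series on one year axis."""

    aligned: list[RingWidthSeries]
    offsets: dict[str, int]            # applied shift per retained series
    excluded: list[str]
    chronology_length: int
    mean_overlap: float


def build_master(series: list[RingWidthSeries],
                 matches: list[CrossMatchResult]) -> MasterAlignment:
    """Compose accepted pairwise lags into one master alignment.

    Offsets are propagated over the accepted-match graph from the first
    series of the largest connected component.  Any cycle whose composed
    lags disagree raises an alignment-conflict error naming the edge;
    series outside the component are reported as excluded.
    """
    import networkx as nx

    by_id = {s.series_id: s for s in series}
    g = nx.Graph()
    g.add_nodes_from(by_id)
    for m in matches:
        if not m.accepted:
            continue
        if m.series_a not in by_id or m.series_b not in by_id:
            raise CrossdatingError(f"match references unknown series: {m}")
        g.add_edge(m.series_a, m.series_b, lag=m.lag, a=m.series_a)

    components = sorted(nx.connected_components(g), key=len, reverse=True)
    if not components:
        raise CrossdatingError("no series given")
    keep = components[0]
    root = next(s.series_id for s in series if s.series_id in keep)

    shift: dict[str, int] = {root: 0}
    for u, v in nx.bfs_edges(g.subgraph(keep), root):
        edge = g.edges[u, v]
        # edge lag moves edge['a']'s partner onto edge['a']'s axis
        lag = edge["lag"] if edge["a"] == u else -edge["lag"]
        shift[v] = shift[u] + lag
    # verify every edge (including those closing cycles) is consistent
    for u, v, data in g.subgraph(keep).edges(data=True):
        lag = data["lag"] if data["a"] == u else -data["lag"]
        if shift[v] != shift[u] + lag:
            raise CrossdatingError(
                f"alignment conflict on cycle through {u!r}-{v!r}: "
                f"composed offset {shift[v] - shift[u]} != match lag {lag}"
            )

    aligned = [by_id[sid].shifted(shift[sid]) for sid in
               (s.series_id for s in series) if sid in keep]
    excluded = [s.series_id for s in series if s.series_id not in keep]
    lo = min(s.first_year for s in aligned)
    hi = max(s.last_year for s in aligned)

    overlaps = []
    for i, s1 in enumerate(aligned):
        for s2 in aligned[i + 1:]:
            ov = (min(s1.last_year, s2.last_year)
                  - max(s1.first_year, s2.first_year) + 1)
            if ov > 0:
                overlaps.append(ov)
    return MasterAlignment(
        aligned=aligned,
        offsets={sid: shift[sid] for sid in shift},
        excluded=excluded,
        chronology_length=hi - lo + 1,
        mean_overlap=float(np.mean(overlaps)) if overlaps else 0.0,
    )
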
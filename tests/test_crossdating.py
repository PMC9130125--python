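"""Transform arithmetic, match statistics, and master assembly."""

import math

import numpy as np
import pytest

from paleodendro import crossdating as xd
from paleodendro import pipeline as pl
from paleodendro import synthetic_data as sd
from paleodendro.dendro_io import RingWidthSeries


def _series(widths, sid="s", first_year=0):
    return RingWidthSeries(sid, sid, "1", first_year, np.asarray(widths, float))


class TestTransforms:
    def test_bp_constant_series_is_zero(self):
        out = xd.bp_transform(_series([2.0] * 10))
        np.testing.assert_allclose(out.values, 0.0)
        assert out.first_year == 2 and len(out.values) == 6

    def test_bp_hand_value(self):
        # centre of [1,1,4,1,1]: ln(4 / mean(1,1,4,1,1)) = ln(4/1.6)
        out = xd.bp_transform(_series([1, 1, 4, 1, 1, 1]), window=5)
        assert out.values[0] == pytest.approx(math.log(4 / 1.6), abs=1e-4)
        assert out.values[0] == pytest.approx(0.9163, abs=1e-4)

    def test_bp_too_short_errors(self):
        with pytest.raises(xd.CrossdatingError):
            xd.bp_transform(_series([1, 2, 3]), window=5)

    def test_ho_hand_values(self):
        out = xd.ho_transform(_series([1.0, 10.0]))
        assert out.values[0] == pytest.approx(100.0)
        const = xd.ho_transform(_series([3.3] * 8))
        np.testing.assert_allclose(const.values, 0.0)
        geo = xd.ho_transform(_series(2.0 ** np.arange(6)))
        np.testing.assert_allclose(geo.values, 100 * math.log10(2))

    def test_t_statistic_closed_form_and_degeneracy(self, rng):
        # exact r = 0.6, n = 27 -> t = 0.6*5/0.8 = 3.75
        x = rng.normal(size=27)
        y = rng.normal(size=27)
        x = (x - x.mean()) / x.std()
        y = y - y.mean()
        y -= (x @ y) / 27 * x          # orthogonalize
        y /= y.std()
        z = 0.6 * x + 0.8 * y          # corr(x, z) = 0.6 exactly
        st = xd.t_statistic(x, z)
        assert st["r"] == pytest.approx(0.6, abs=1e-12)
        assert st["t"] == pytest.approx(3.75, abs=1e-9)

        same = xd.t_statistic(x, 2 * x + 1)
        assert same["degenerate"] and same["t"] == math.inf
        flat = xd.t_statistic(x, np.ones(27))
        assert flat["degenerate"] and math.isnan(flat["t"])
        with pytest.raises(xd.CrossdatingError):
            xd.t_statistic(x[:2], z[:2])


class TestGleichlauf:
    def test_identity_and_antiphase(self):
        a = _series([1, 2, 3, 2, 4, 1, 5])
        assert xd.gleichlauf(a, a) == 100.0
        up = _series([1, 2, 3, 4, 5])
        down = _series([5, 4, 3, 2, 1])
        assert xd.gleichlauf(up, down) == 0.0

    def test_hand_counted_example(self):
        # diffs: x=(+,+,-,+), y=(+,-,+,+): agreements 1,0,0,1 -> 50%
        x = _series([1, 2, 3, 2, 4])
        y = _series([2, 3, 2, 3, 5])
        assert xd.gleichlauf(x, y) == 50.0

    def test_tie_scoring(self):
        # one flat diff vs moving scores 1/2; both flat scores 1
        x = _series([1, 1, 2])
        y = _series([1, 2, 3])
        assert xd.gleichlauf(x, y) == pytest.approx(75.0)
        z = _series([2, 2, 3])
        assert xd.gleichlauf(x, z) == pytest.approx(100.0)

    def test_too_short_errors(self):
        with pytest.raises(xd.CrossdatingError):
            xd.gleichlauf(_series([1, 2]), _series([1, 2]), lag=5)


class TestCrossmatch:
    def test_shifted_copy_recovered_exactly(self, lognormal_series):
        a = lognormal_series
        b = RingWidthSeries("b", "b", "1", 0, a.widths[10:])
        res = xd.crossmatch(a, b)
        best = res[0]
        assert best.lag == 10
        assert best.r == pytest.approx(1.0)
        assert best.glk == 100.0
        assert best.t_bp == math.inf and best.accepted

    def test_statistics_symmetric_under_argument_swap(self, lognormal_series):
        a = lognormal_series
        rng = np.random.default_rng(5)
        b = RingWidthSeries("b", "b", "1", 0,
                            a.widths[7:] * np.exp(rng.normal(0, 0.2,
                                                             len(a) - 7)))
        fwd = {m.lag: m for m in xd.crossmatch(a, b)}
        rev = {m.lag: m for m in xd.crossmatch(b, a)}
        assert set(fwd) == {-l for l in rev}
        for lag, m in fwd.items():
            m2 = rev[-lag]
            assert m.n_overlap == m2.n_overlap
            assert m.r == pytest.approx(m2.r)
            assert m.t_bp == pytest.approx(m2.t_bp)
            assert m.glk == pytest.approx(m2.glk)

    def test_scale_invariance(self, lognormal_series):
        a = lognormal_series
        rng = np.random.default_rng(6)
        b = RingWidthSeries("b", "b", "1", 0,
                            a.widths[5:] * np.exp(rng.normal(0, 0.2,
                                                             len(a) - 5)))
        b_scaled = RingWidthSeries("b", "b", "1", 0, 7.3 * b.widths)
        for m, ms in zip(xd.crossmatch(a, b), xd.crossmatch(a, b_scaled)):
            assert m.lag == ms.lag
            assert m.r == pytest.approx(ms.r)
            assert m.t_ho == pytest.approx(ms.t_ho)
            assert m.glk == pytest.approx(ms.glk)

    def test_no_sufficient_overlap_returns_empty(self):
        a = _series(np.linspace(1, 2, 25), "a")
        b = _series(np.linspace(1, 2, 19), "b")
        assert xd.crossmatch(a, b) == []

    def test_false_positive_rate_on_independent_red_noise(self):
        """Independent AR(1) pairs under default gates: FP rate <= 5%."""
        rng = np.random.default_rng(7)
        phi, n, npairs = 0.4, 100, 1000

        def make():
            eps = rng.normal(0, 0.3, n + 20)
            x = np.empty(n + 20)
            x[0] = eps[0] / math.sqrt(1 - phi**2)
            for t in range(1, n + 20):
                x[t] = phi * x[t - 1] + eps[t]
            return _series(np.exp(x[20:]))

        fp = sum(
            1 for _ in range(npairs)
            if (res := xd.crossmatch(make(), make())) and res[0].accepted
        )
        assert fp / npairs <= 0.05


class TestBuildMaster:
    def test_two_identical_series_at_lag_zero(self, lognormal_series):
        a = lognormal_series
        b = RingWidthSeries("b", "b", "1", 0, a.widths)
        res = xd.crossmatch(a, b)
        master = xd.build_master([a, b], [res[0]])
        assert master.chronology_length == len(a)
        assert master.excluded == []
        assert master.mean_overlap == len(a)

    def test_disconnected_series_reported_excluded(self, lognormal_series):
        a = lognormal_series
        b = RingWidthSeries("b", "b", "1", 0, a.widths[5:])
        rng = np.random.default_rng(0)
        c = RingWidthSeries("c", "c", "1", 0, np.exp(rng.normal(0, 0.2, 60)))
        match = xd.crossmatch(a, b)[0]
        master = xd.build_master([a, b, c], [match])
        assert master.excluded == ["c"]
        assert master.chronology_length == len(a)

    def test_inconsistent_cycle_raises_alignment_conflict(self,
                                                          lognormal_series):
        a = lognormal_series
        b = RingWidthSeries("b", "b", "1", 0, a.widths[5:])
        c = RingWidthSeries("c", "c", "1", 0, a.widths[9:])
        ab = xd.crossmatch(a, b)[0]
        bc = xd.crossmatch(b, c)[0]
        ac = xd.crossmatch(a, c)[0]
        assert (ab.lag, bc.lag, ac.lag) == (5, 4, 9)
        bad = xd.CrossMatchResult(series_a=a.series_id, series_b="c", lag=8,
                                  n_overlap=50, r=1.0, t_bp=10.0, t_ho=10.0,
                                  glk=100.0, accepted=True)
        with pytest.raises(xd.CrossdatingError, match="alignment conflict"):
            xd.build_master([a, b, c], [ab, bc, bad])

    def test_true_offsets_recovered_on_reference_forest(self):
        cfg = sd.reference_forest_config(seed=0)
        forest = sd.simulate_forest(cfg)
        _, _, master = pl.crossdate_forest(forest.series)
        assert master.excluded == []
        root = master.offsets["T01"]
        for i, true_off in enumerate(cfg.offsets):
            assert master.offsets[f"T{i + 1:02d}"] - root == true_off
        assert master.chronology_length == forest.true_span
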
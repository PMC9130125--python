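"""Weathering-index arithmetic and the climate transfer chain."""

import math

import numpy as np
import pytest

from paleodendro import paleosol as ps

MOLAR_EX = {"Al2O3": 20.0, "CaO": 5.0, "Na2O": 3.0, "K2O": 2.0}


class TestMolarConversion:
    def test_definitional_one_mole(self):
        assert ps.to_molar({"Al2O3": 101.96})["Al2O3"] == pytest.approx(1.0)

    def test_zero_map(self):
        out = ps.to_molar({k: 0.0 for k in ps.OXIDE_MOLAR_MASS})
        assert all(v == 0.0 for v in out.values())

    def test_worked_division(self):
        m = ps.to_molar(MOLAR_EX)
        assert m["Al2O3"] == pytest.approx(0.19616, abs=2e-5)
        assert m["CaO"] == pytest.approx(0.08916, abs=2e-5)
        assert m["Na2O"] == pytest.approx(0.04840, abs=2e-5)
        assert m["K2O"] == pytest.approx(0.02123, abs=2e-5)

    def test_unknown_oxide_rejected(self):
        with pytest.raises(ps.PaleosolError):
            ps.to_molar({"SiO2": 50.0})


class TestWeatheringIndices:
    def test_only_al_gives_100(self):
        assert ps.cia({"Al2O3": 0.2}) == 100.0
        assert ps.cia_k({"Al2O3": 0.2}) == 100.0

    def test_equal_molar_symmetry_gives_25(self):
        m = {"Al2O3": 0.1, "CaO": 0.1, "Na2O": 0.1, "K2O": 0.1}
        assert ps.cia(m) == pytest.approx(25.0)

    def test_worked_values_to_4_significant_figures(self):
        m = ps.to_molar(MOLAR_EX)
        assert ps.cia(m) == pytest.approx(55.26, abs=0.005)
        assert ps.cia_k(m) == pytest.approx(58.78, abs=0.005)

    def test_dilution_invariance(self):
        m = ps.to_molar(MOLAR_EX)
        diluted = ps.to_molar({k: 0.37 * v for k, v in MOLAR_EX.items()})
        assert ps.cia(diluted) == pytest.approx(ps.cia(m))
        assert ps.cia_k(diluted) == pytest.approx(ps.cia_k(m))

    def test_ciak_at_least_cia_when_k_present(self):
        m = ps.to_molar(MOLAR_EX)
        assert ps.cia_k(m) >= ps.cia(m)

    def test_mclennan_cao_star_caps_at_na(self):
        m = {"Al2O3": 0.2, "CaO": 0.3, "Na2O": 0.05, "K2O": 0.02}
        assert ps.cia(m, cao_star="mclennan") > ps.cia(m, cao_star="cao")

    def test_zero_al_rejected(self):
        with pytest.raises(ps.PaleosolError):
            ps.cia({"CaO": 0.1})


class TestKCorrection:
    def test_parent_proportion_is_fixed_point(self):
        parent = ps.to_molar(MOLAR_EX)
        corrected, _ = ps.k_correction(parent, parent)
        assert corrected == pytest.approx(ps.cia(parent), abs=1e-9)

    def test_k_enrichment_raises_corrected_cia(self):
        parent = ps.to_molar(MOLAR_EX)
        enriched = dict(parent)
        enriched["K2O"] = parent["K2O"] * 3.0
        corrected, _ = ps.k_correction(enriched, parent)
        assert corrected > ps.cia(enriched)

    def test_k_free_parent_zeroes_k(self):
        parent = {"Al2O3": 0.2, "CaO": 0.1, "Na2O": 0.05, "K2O": 0.0}
        horizon = {"Al2O3": 0.2, "CaO": 0.08, "Na2O": 0.04, "K2O": 0.03}
        _, out = ps.k_correction(horizon, parent)
        assert out["K2O"] == 0.0

    def test_idempotent(self):
        parent = ps.to_molar(MOLAR_EX)
        horizon = dict(parent)
        horizon["K2O"] *= 2.5
        once_cia, once = ps.k_correction(horizon, parent)
        twice_cia, twice = ps.k_correction(once, parent)
        assert twice_cia == pytest.approx(once_cia, abs=1e-12)
        assert twice["K2O"] == pytest.approx(once["K2O"], abs=1e-12)


class TestTransferFunctions:
    def test_map_intercept_and_worked_value(self):
        assert ps.map_from_ciak(0.0) == pytest.approx(221.1)
        assert ps.map_from_ciak(100.0) == pytest.approx(1585.5, abs=0.5)

    def test_map_monotone_increasing(self):
        vals = [ps.map_from_ciak(v) for v in (10, 40, 70, 95)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_lst_linear_defaults(self):
        assert ps.lst_from_cia(80.0) == pytest.approx(0.56 * 80 - 25.7)
        assert ps.lst_from_cia(80.0) == pytest.approx(19.1, abs=0.01)
        cfg = ps.TransferConfig(lst_a=0.0, lst_b=7.0, is_default=False)
        assert ps.lst_from_cia(10.0, cfg) == 7.0
        assert (ps.lst_from_cia(60.0) - ps.lst_from_cia(50.0)
                ) == pytest.approx(0.56 * 10)

    def test_strict_mode_refuses_shipped_defaults(self):
        with pytest.raises(ps.PaleosolError):
            ps.map_from_ciak(50.0, strict=True)
        explicit = ps.TransferConfig(is_default=False)
        assert ps.map_from_ciak(50.0, explicit, strict=True) > 0

    def test_eppt_zero_at_reference_temperature(self):
        cfg = ps.TransferConfig(reference_temp_c=12.0)
        eppt, _ = ps.eppt_et(800.0, 12.0, cfg)
        assert eppt == 0.0

    def test_eppt_homogeneous_in_map(self):
        e1, _ = ps.eppt_et(500.0, 15.0)
        e2, _ = ps.eppt_et(1000.0, 15.0)
        assert e2 == pytest.approx(2 * e1)

    def test_frozen_default_regression_values(self):
        # golden values computed once from the shipped default transfer
        eppt, et = ps.eppt_et(1000.0, 20.0)
        assert eppt == pytest.approx(83.72, abs=0.01)
        assert et == pytest.approx(98.68, abs=0.01)

    def test_nonpositive_map_rejected(self):
        with pytest.raises(ps.PaleosolError):
            ps.eppt_et(0.0, 10.0)


class TestHumidityProvince:
    def test_extremes(self):
        prov, floral = ps.humidity_province(1e5, 10.0)
        assert floral == "rainforest"
        prov, floral = ps.humidity_province(0.0, 1000.0)
        assert prov == "hyperarid" and floral == "desert"

    def test_containment_between_lines(self):
        # Eppt/ET = 0.575 sits between the 0.5 and 0.65 boundaries
        prov, floral = ps.humidity_province(57.5, 100.0)
        assert prov == "dry subhumid"

    def test_boundary_point_goes_to_wetter_region(self):
        prov, _ = ps.humidity_province(65.0, 100.0)
        assert prov == "humid"

    def test_classification_total_over_plane(self, rng):
        for _ in range(100):
            et = float(rng.uniform(0, 5000))
            eppt = float(rng.uniform(-100, 5000))
            prov, floral = ps.humidity_province(eppt, et)
            assert isinstance(prov, str) and isinstance(floral, str)

    def test_crossing_polylines_rejected(self):
        bad = [
            {"name": "lo", "points": [(0.0, 0.0), (100.0, 50.0)]},
            {"name": "hi", "points": [(0.0, 40.0), (100.0, 10.0)]},
        ]
        labels = [("a", "a"), ("b", "b"), ("c", "c")]
        with pytest.raises(ps.PaleosolError, match="crosses"):
            ps.humidity_province(30.0, 50.0, bad, labels)


class TestProfileQC:
    def _profile(self, b_ciak_vals, parent=MOLAR_EX):
        def chem_for(ciak):
            al = 0.2
            cana = al * (100.0 / ciak - 1.0)
            return {"Al2O3": al * 101.96, "CaO": cana / 2 * 56.08,
                    "Na2O": cana / 2 * 61.98, "K2O": 1.0}
        horizons = [ps.Horizon(f"B{i+1}", 10.0 * (i + 1), chem_for(v))
                    for i, v in enumerate(b_ciak_vals)]
        horizons.append(ps.Horizon("C", 10.0 * (len(b_ciak_vals) + 1),
                                   chem_for(60.0)))
        return ps.PaleosolProfile(horizons, parent_index=-1)

    def test_worked_contrast_ten_percent_passes(self):
        prof = self._profile([66.0])
        qc = ps.profile_qc(prof)
        assert qc["ciak_contrast_percent"] == pytest.approx(10.0, abs=1e-6)
        assert qc["passes"]

    def test_identical_b_and_parent_fails(self):
        qc = ps.profile_qc(self._profile([60.0]))
        assert qc["ciak_contrast_percent"] == pytest.approx(0.0, abs=1e-9)
        assert not qc["passes"]

    def test_no_b_horizon_rejected(self):
        prof = ps.PaleosolProfile(
            [ps.Horizon("C", 10.0, dict(MOLAR_EX))], parent_index=0)
        with pytest.raises(ps.PaleosolError):
            ps.profile_qc(prof)


class TestEstimateChain:
    def test_full_chain_emits_one_estimate_per_b_horizon(self):
        from paleodendro import synthetic_data as sd
        parent = {"Al2O3": 15.0, "CaO": 6.0, "Na2O": 3.0, "K2O": 2.5,
                  "MgO": 2.0, "MnO": 0.15}
        prof = sd.simulate_paleosol(4, parent, [7.0, 6.0, 4.0],
                                    noise_sd=0.05, seed=2)
        ests = ps.estimate_climate(prof)
        assert len(ests) == 3
        for e in ests:
            assert 0 <= e.cia_k <= 100
            assert e.map_mm_yr > 0
            assert isinstance(e.humidity_province, str)
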
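import math

import numpy as np
import pandas as pd
import pytest

import sunshade as ss
from sunshade import canopy


DAY_MET = dict(doy=172, sw_in=500.0, t_air=295.15, rh=0.65, wind=2.5,
               pressure=101.325, ca=400.0)


class TestPartitionCapacity:
    def test_closed_form_integrals(self):
        caps = canopy.partition_capacity(100.0, 167.0, lai=2.0, kn=0.3, kb=0.5)
        vsun = 100 * (1 - math.exp(-1.6)) / 0.8
        vtot = 100 * (1 - math.exp(-0.6)) / 0.3
        assert caps.vcmax_sun == pytest.approx(vsun)
        assert caps.vcmax_sun == pytest.approx(99.76, abs=0.01)
        assert caps.vcmax_total == pytest.approx(vtot)
        assert caps.vcmax_sha == pytest.approx(vtot - vsun)
        assert caps.vcmax_sun + caps.vcmax_sha == pytest.approx(caps.vcmax_total)

    def test_large_kb_moves_capacity_to_shade(self):
        caps = canopy.partition_capacity(100.0, 167.0, 2.0, 0.3, kb=500.0)
        vtot = 100 * (1 - math.exp(-0.6)) / 0.3
        assert caps.vcmax_sun < 0.01 * vtot
        assert caps.vcmax_sha == pytest.approx(vtot, rel=1e-2)

    def test_uniform_nitrogen_limit_matches_lai_split(self):
        # kn -> 0: capacity proportional to leaf area in each fraction
        kn = 1e-9
        kb, lai = 0.6, 3.0
        caps = canopy.partition_capacity(50.0, 83.5, lai, kn, kb)
        lai_sun = (1 - math.exp(-kb * lai)) / kb
        assert caps.vcmax_sun == pytest.approx(50.0 * lai_sun, rel=1e-6)
        assert caps.vcmax_total == pytest.approx(50.0 * lai, rel=1e-6)


class TestTwoBigLeafStep:
    def test_zero_lai_short_circuits(self, wheat_traits, wheat_native):
        out = ss.two_big_leaf_step(DAY_MET, wheat_traits, wheat_native, 0.0)
        assert out["an"] == 0.0

    def test_night_is_dark_respiration(self, wheat_traits, wheat_native):
        met = dict(DAY_MET, sw_in=0.0)
        out = ss.two_big_leaf_step(met, wheat_traits, wheat_native, 3.0)
        assert out["night"]
        assert out["an"] == pytest.approx(-out["rd"])
        assert out["an"] < 0

    def test_fraction_fluxes_sum_to_canopy(self, wheat_traits, wheat_native):
        out = ss.two_big_leaf_step(DAY_MET, wheat_traits, wheat_native, 3.0)
        assert out["an"] == pytest.approx(out["an_sun"] + out["an_sha"])
        assert out["converged_sun"] and out["converged_sha"]
        assert out["lai_sun"] + out["lai_sha"] == pytest.approx(3.0, abs=1e-9)

    def test_doubling_kcat_increases_daylight_assimilation(
            self, wheat_traits, wheat_native, doubled_kcat):
        base = ss.two_big_leaf_step(DAY_MET, wheat_traits, wheat_native, 3.0)
        fast = ss.two_big_leaf_step(DAY_MET, wheat_traits, doubled_kcat, 3.0)
        assert fast["an"] > base["an"]

    def test_halfhourly_mode_uses_instant_zenith(self, wheat_traits,
                                                 wheat_native):
        noon = ss.two_big_leaf_step(dict(DAY_MET, hour=12.0), wheat_traits,
                                    wheat_native, 3.0)
        evening = ss.two_big_leaf_step(dict(DAY_MET, hour=18.5, sw_in=80.0),
                                       wheat_traits, wheat_native, 3.0)
        assert noon["dt"] == 1800.0
        assert noon["an"] > evening["an"]

    def test_energy_budget_offsets_canopy_temperature(self, wheat_traits,
                                                      wheat_native):
        met = dict(DAY_MET, hour=12.0, rnet=400.0, h=250.0, le=149.0)
        out = ss.two_big_leaf_step(met, wheat_traits, wheat_native, 3.0)
        assert out["t_canopy"] > DAY_MET["t_air"]
        met_cool = dict(met, le=160.0)
        out_cool = ss.two_big_leaf_step(met_cool, wheat_traits, wheat_native, 3.0)
        assert out_cool["t_canopy"] < out["t_canopy"]


class TestRunSeason:
    def test_constant_forcing_is_additive(self, wheat_traits, wheat_native):
        met = pd.DataFrame([DAY_MET] * 5)
        lai = np.full(5, 3.0)
        df, total = ss.run_season(met, wheat_traits, wheat_native, lai)
        step = ss.two_big_leaf_step(DAY_MET, wheat_traits, wheat_native, 3.0)
        assert total == pytest.approx(5 * step["an"] * step["dt"], rel=1e-12)

    def test_gaps_skipped_not_fatal(self, wheat_traits, wheat_native):
        rows = [dict(DAY_MET) for _ in range(4)]
        rows[2]["sw_in"] = np.nan
        met = pd.DataFrame(rows)
        df, total = ss.run_season(met, wheat_traits, wheat_native,
                                  np.full(4, 3.0))
        assert df["gap"].sum() == 1
        df_full, total_full = ss.run_season(pd.DataFrame([DAY_MET] * 3),
                                            wheat_traits, wheat_native,
                                            np.full(3, 3.0))
        assert total == pytest.approx(total_full, rel=1e-12)

    def test_empty_series_rejected(self, wheat_traits, wheat_native):
        with pytest.raises(ValueError, match="empty"):
            ss.run_season(pd.DataFrame(), wheat_traits, wheat_native, [])

    def test_misaligned_lai_rejected(self, wheat_traits, wheat_native):
        met = pd.DataFrame([DAY_MET] * 3)
        with pytest.raises(ValueError, match="align"):
            ss.run_season(met, wheat_traits, wheat_native, np.ones(2))

    def test_seeded_season_regression_total(self, wheat_traits, wheat_native,
                                            daily_season):
        """Golden total for the seeded 30-day synthetic wheat season."""
        daily, lai = daily_season
        _, total = ss.run_season(daily, wheat_traits, wheat_native, lai)
        assert total == pytest.approx(25_132_515.605, rel=1e-6)


class TestSubstitutionScreen:
    def test_native_against_itself_is_exactly_zero(self, wheat_traits,
                                                   wheat_native, daily_season):
        daily, lai = daily_season
        res = ss.substitution_screen(wheat_native, [wheat_native], daily,
                                     wheat_traits, lai)
        assert len(res) == 1
        assert res[0].pct_change == 0.0

    def test_doubled_kcat_improves_uptake(self, wheat_traits, wheat_native,
                                          doubled_kcat, daily_season):
        daily, lai = daily_season
        res = ss.substitution_screen(wheat_native, [wheat_native, doubled_kcat],
                                     daily, wheat_traits, lai)
        by_name = {r.species_name: r for r in res}
        assert by_name["doubled-kcat"].pct_change > 0

    def test_sorted_consistent_with_totals(self, wheat_traits, wheat_native,
                                           doubled_kcat, daily_season,
                                           kinetics_table):
        daily, lai = daily_season
        spinach = next(k for k in kinetics_table
                       if k.species_name == "Spinacia oleracea")
        res = ss.substitution_screen(wheat_native,
                                     [wheat_native, doubled_kcat, spinach],
                                     daily, wheat_traits, lai)
        assert len(res) == 3
        pcts = [r.pct_change for r in res]
        totals = [r.total_uptake for r in res]
        assert pcts == sorted(pcts, reverse=True)
        assert totals == sorted(totals, reverse=True)

    def test_screen_is_deterministic(self, wheat_traits, wheat_native,
                                     doubled_kcat, daily_season):
        daily, lai = daily_season
        r1 = ss.substitution_screen(wheat_native, [wheat_native, doubled_kcat],
                                    daily, wheat_traits, lai)
        r2 = ss.substitution_screen(wheat_native, [wheat_native, doubled_kcat],
                                    daily, wheat_traits, lai)
        assert r1 == r2


class TestTraitsFromConfig:
    def test_known_crops(self):
        for crop, pathway in (("wheat", "C3"), ("maize", "C4"),
                              ("sugar_beet", "C3")):
            t = ss.traits_from_config(crop)
            assert t.pathway.value == pathway
            assert t.kn == 0.3

    def test_unknown_crop(self):
        with pytest.raises(KeyError, match="barley"):
            ss.traits_from_config("barley")
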
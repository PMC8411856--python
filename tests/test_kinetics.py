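import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sunshade import kinetics as kn
from sunshade.config import GAS_CONSTANT, T_REF


class TestLoadKineticsTable:
    def test_packaged_table_counts(self, kinetics_table):
        assert len(kinetics_table) == 27
        counts = {p: sum(k.pathway is p for k in kinetics_table)
                  for p in kn.Pathway}
        assert counts[kn.Pathway.C3] == 16
        assert counts[kn.Pathway.C4] == 10
        assert counts[kn.Pathway.C3C4] == 1

    def test_incomplete_row_excluded_and_reported(self, tmp_path, caplog):
        from importlib import resources
        with resources.as_file(resources.files("sunshade").joinpath(
                "data/rubisco_kinetics_synthetic.csv")) as src:
            df = pd.read_csv(src)
        df.loc[3, "ha_sco"] = np.nan
        p = tmp_path / "kin.csv"
        df.to_csv(p, index=False)
        with caplog.at_level("WARNING", logger="sunshade.kinetics"):
            out = kn.load_kinetics_table(p)
        assert len(out) == 26
        assert any("ha_sco" in rec.message for rec in caplog.records)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("species,pathway,kcat25\nx,C3,3.0\n")
        with pytest.raises(ValueError, match="missing columns"):
            kn.load_kinetics_table(p)

    def test_nonpositive_value_names_row_and_field(self, tmp_path):
        p = tmp_path / "neg.csv"
        p.write_text("species,pathway,kcat25,kc21_25,sco25,ha_kcat,ha_kc21,ha_sco\n"
                     "Bad plant,C3,-1.0,600,2700,60000,65000,20000\n")
        with pytest.raises(ValueError, match="kcat25"):
            kn.load_kinetics_table(p)


class TestArrhenius:
    @given(ha=st.floats(1e3, 3e5))
    @settings(max_examples=50, deadline=None)
    def test_identity_at_reference(self, ha):
        assert kn.arrhenius_adjust(5.0, ha, T_REF) == pytest.approx(5.0, rel=1e-12)

    def test_derived_value_at_35C(self):
        expected = math.exp(65330 * 10 / (298.15 * 8.314 * 308.15))
        assert kn.arrhenius_adjust(1.0, 65330, 308.15) == pytest.approx(expected)
        assert expected == pytest.approx(2.35, abs=0.01)

    def test_monotone_in_temperature(self):
        ts = np.linspace(255, 325, 40)
        vals = kn.arrhenius_adjust(2.0, 50000, ts)
        assert np.all(np.diff(vals) > 0)

    def test_temperature_domain_enforced(self):
        with pytest.raises(ValueError):
            kn.arrhenius_adjust(1.0, 5e4, 200.0)


class TestGammaStar:
    def test_values_and_linearity(self):
        assert kn.gamma_star(3100, 210000) == pytest.approx(0.5 * 210000 / 3100)
        assert kn.gamma_star(1e12, 209000) == pytest.approx(0.0, abs=1e-6)
        assert kn.gamma_star(2800, 2 * 209000) == pytest.approx(
            2 * kn.gamma_star(2800, 209000))

    def test_nonpositive_sco_rejected(self):
        with pytest.raises(ValueError):
            kn.gamma_star(0.0)


class TestVcmaxFromKcat:
    def test_product_of_factors(self):
        v = kn.vcmax25_from_kcat(3.5, na=2.0, flnr=0.16, fnr=7.16,
                                 sites_per_gram=14.545)
        assert v == pytest.approx(3.5 * 2.0 * 0.16 * 7.16 * 14.545)
        assert v == pytest.approx(116.6, abs=0.1)

    def test_zero_turnover_and_linearity(self):
        assert kn.vcmax25_from_kcat(0.0, 2.0, 0.16) == 0.0
        v1 = kn.vcmax25_from_kcat(3.0, 1.0, 0.16)
        assert kn.vcmax25_from_kcat(3.0, 2.0, 0.16) == pytest.approx(2 * v1)
        assert kn.vcmax25_from_kcat(6.0, 1.0, 0.16) == pytest.approx(2 * v1)

    def test_na_from_sla_and_cn(self):
        assert kn.leaf_nitrogen(0.08, 25.0) == pytest.approx(1.0 / 2.0)


class TestDerivePhotoparams:
    def test_c3_ratios_exact(self):
        p = kn.derive_photoparams(100.0, "C3")
        assert p.jmax25 == 1.67 * 100.0
        assert p.rd25 == 0.015 * 100.0
        assert p.kp25 is None

    def test_c4_ratios_exact(self):
        p = kn.derive_photoparams(40.0, "C4")
        assert p.rd25 == 0.025 * 40.0
        assert p.kp25 == 20000.0 * 40.0

    def test_unit_vcmax_exposes_ratio(self):
        assert kn.derive_photoparams(1.0, "C3").jmax25 == pytest.approx(1.67)

    def test_intermediate_treated_as_c3(self):
        p = kn.derive_photoparams(50.0, kn.Pathway.C3C4)
        assert p.rd25 == pytest.approx(0.015 * 50.0)
        assert p.kp25 is None

    def test_unknown_pathway_rejected(self):
        with pytest.raises(ValueError):
            kn.derive_photoparams(50.0, "CAM")


class TestTemperatureScaling:
    def test_peaked_factor_unity_at_25C(self):
        assert kn.peaked_factor(298.15, 149250, 485) == pytest.approx(1.0, rel=1e-12)

    def test_c3_vcmax_has_interior_maximum(self, wheat_native):
        p = kn.derive_photoparams(80.0, "C3")
        ts = np.linspace(255, 325, 200)
        v = np.array([kn.c3_temperature_scaling(p, wheat_native, t).vcmax
                      for t in ts])
        imax = int(np.argmax(v))
        assert 0 < imax < len(ts) - 1

    def test_c3_35C_closed_form(self, wheat_native):
        p = kn.derive_photoparams(80.0, "C3")
        t = 308.15
        adj = kn.c3_temperature_scaling(p, wheat_native, t)
        arr = math.exp(wheat_native.ha_kcat * (t - T_REF)
                       / (T_REF * GAS_CONSTANT * t))
        num = 1 + math.exp((T_REF * 485 - 149250) / (T_REF * GAS_CONSTANT))
        den = 1 + math.exp((t * 485 - 149250) / (t * GAS_CONSTANT))
        assert adj.vcmax == pytest.approx(80.0 * arr * num / den, rel=1e-12)
        # Rd co-varies with Vcmax
        assert adj.rd / p.rd25 == pytest.approx(adj.vcmax / 80.0, rel=1e-12)

    def test_c4_reference_temperature(self, kinetics_table):
        maize = next(k for k in kinetics_table if k.species_name == "Zea mays")
        p = kn.derive_photoparams(40.0, "C4")
        adj = kn.c4_temperature_scaling(p, maize, 298.15)
        inhibition = ((1 + math.exp(p.s1 * (298.15 - p.s2)))
                      * (1 + math.exp(p.s3 * (p.s4 - 298.15))))
        assert adj.vcmax == pytest.approx(40.0 / inhibition, rel=1e-12)

    def test_c4_plugin_evaluation(self, kinetics_table):
        maize = next(k for k in kinetics_table if k.species_name == "Zea mays")
        p = kn.derive_photoparams(40.0, "C4")
        t = 308.15
        adj = kn.c4_temperature_scaling(p, maize, t)
        expected = (40.0 * 2.0 ** ((t - 298.15) / 10.0)
                    / ((1 + math.exp(0.3 * (t - 313.15)))
                       * (1 + math.exp(0.2 * (288.15 - t)))))
        assert adj.vcmax == pytest.approx(expected, rel=1e-12)
        # high temperature falls below the pure-Q10 response
        hot = kn.c4_temperature_scaling(p, maize, 325.0)
        assert hot.vcmax < 40.0 * 2.0 ** ((325.0 - 298.15) / 10.0)

    def test_kp_and_rd_covary_with_vcmax(self, kinetics_table):
        maize = next(k for k in kinetics_table if k.species_name == "Zea mays")
        p = kn.derive_photoparams(40.0, "C4")
        adj = kn.c4_temperature_scaling(p, maize, 310.0)
        scale = adj.vcmax / 40.0
        assert adj.rd == pytest.approx(p.rd25 * scale, rel=1e-12)
        assert adj.kp == pytest.approx(p.kp25 * scale, rel=1e-12)

    def test_deterministic(self, wheat_native):
        p = kn.derive_photoparams(80.0, "C3")
        a = kn.c3_temperature_scaling(p, wheat_native, 303.15)
        b = kn.c3_temperature_scaling(p, wheat_native, 303.15)
        assert a == b


class TestLiquidToGasBasis:
    def test_sco_ratio_is_solubility_ratio(self):
        _, sco_gas = kn.liquid_to_gas_basis(20.0, 100.0)
        assert sco_gas / 100.0 == pytest.approx(0.0334 / 0.00126)
        assert sco_gas / 100.0 == pytest.approx(26.5, abs=0.1)

    def test_identity_when_factors_unity(self):
        kc, sco = kn.liquid_to_gas_basis(5.0, 80.0, sol_co2=1.0, sol_o2=1.0,
                                         pressure_bar=1.0)
        assert kc == pytest.approx(5.0)
        assert sco == pytest.approx(80.0)

    def test_kc_inverse_in_solubility(self):
        kc1, _ = kn.liquid_to_gas_basis(20.0, 100.0, sol_co2=0.0334)
        kc2, _ = kn.liquid_to_gas_basis(20.0, 100.0, sol_co2=0.0668)
        assert kc1 == pytest.approx(2 * kc2)
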
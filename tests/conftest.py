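import dataclasses

import pytest

import sunshade as ss
from sunshade import fluxio, laigdp, synthdata


@pytest.fixture(scope="session")
def kinetics_table():
    return ss.packaged_kinetics()


@pytest.fixture(scope="session")
def wheat_native(kinetics_table):
    return next(k for k in kinetics_table
                if k.species_name == "Triticum aestivum")


@pytest.fixture(scope="session")
def wheat_traits():
    return ss.traits_from_config("wheat")


@pytest.fixture(scope="session")
def c3_leaf(wheat_native):
    """Temperature-adjusted C3 leaf parameters at 25 C, Vcmax25 = 80."""
    params25 = ss.kinetics.derive_photoparams(80.0, "C3")
    return ss.kinetics.c3_temperature_scaling(params25, wheat_native, 298.15)


@pytest.fixture(scope="session")
def synth_season_30d():
    """Seeded 30-day synthetic season: half-hourly records + daily GPP."""
    return synthdata.synth_season(synthdata.SynthConfig(seed=1, n_days=30))


@pytest.fixture(scope="session")
def daily_season(synth_season_30d):
    """Daily daytime means and the GDP-LAI series for the 30-day season."""
    records, gpp_daily = synth_season_30d
    daily = fluxio.daily_average(records, sw_min=5.0)
    lai = laigdp.gdp_lai(gpp_daily.to_numpy(), lai_max=4.0)
    return daily, lai


@pytest.fixture()
def doubled_kcat(wheat_native):
    return dataclasses.replace(wheat_native, species_name="doubled-kcat",
                               kcat25=2.0 * wheat_native.kcat25)
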
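"""Daily-weather plumbing and the seasonal projection driver."""

import numpy as np
import pandas as pd
import pytest

from ideovine.climate import (
    ProjectionConfig,
    decade_summary,
    load_daily_weather,
    run_multiyear_projection,
    subdaily_forcing,
)
from ideovine.synth import gen_weather
from ideovine.types import PhenologyCalendar


class TestLoader:
    def test_well_formed_year_accepted(self):
        wx = gen_weather(years=1, seed=0)
        df = load_daily_weather(wx)
        assert len(df) in (365, 366)

    def test_duplicated_date_rejected(self):
        wx = gen_weather(years=1, seed=0)
        bad = pd.concat([wx, wx.iloc[[10]]]).sort_values("date").reset_index(drop=True)
        with pytest.raises(ValueError, match="duplicated"):
            load_daily_weather(bad)

    def test_gap_rejected(self):
        wx = gen_weather(years=1, seed=0)
        bad = wx.drop(index=50).reset_index(drop=True)
        with pytest.raises(ValueError, match="contiguous"):
            load_daily_weather(bad)

    def test_missing_column_rejected(self):
        wx = gen_weather(years=1, seed=0).drop(columns=["rain"])
        with pytest.raises(ValueError, match="rain"):
            load_daily_weather(wx)


class TestSubdaily:
    def test_temperature_extremes_match_daily_inputs(self):
        hours = np.linspace(0, 24, 2000)
        t_air, rh, ppfd = subdaily_forcing(8.0, 27.0, 60.0, 22.0, hours)
        assert abs(t_air.min() - 8.0) < 0.1
        assert abs(t_air.max() - 27.0) < 0.1
        assert np.all((rh > 0) & (rh <= 100))
        assert np.all(ppfd >= 0)

    def test_ppfd_integral_matches_daily_radiation(self):
        hours = np.arange(0, 24, 1 / 60.0)
        _, _, ppfd = subdaily_forcing(10.0, 20.0, 60.0, 20.0, hours, daylength_h=14.0)
        par_umol = np.trapezoid(ppfd, hours * 3600.0)
        from ideovine.meteo import PAR_J_TO_UMOL, SW_PAR_FRACTION

        expect = 20.0 * 1e6 * SW_PAR_FRACTION * PAR_J_TO_UMOL
        assert par_umol == pytest.approx(expect, rel=1e-3)


@pytest.fixture(scope="module")
def wet_year(grenache):
    wx = gen_weather(years=1, seed=21, rain_freq_summer=0.6,
                     rain_freq_winter=0.6, rain_mean_mm=10.0)
    return run_multiyear_projection(grenache, wx)


class TestProjection:
    def test_rainy_mild_year_causes_no_stress(self, wet_year):
        assert wet_year["max_leaf_plc"].iloc[0] < 10.0
        assert wet_year["failure_doy"].isna().all()

    def test_assimilation_accumulates(self, wet_year):
        assert wet_year["total_assimilation"].iloc[0] > 10.0

    def test_dry_season_orders_genotypes(self, grenache, syrah):
        """With no summer rain the profligate genotype reaches hydraulic
        failure earlier (or at higher PLC) than the conservative one."""
        wx = gen_weather(years=1, seed=8, rain_freq_summer=0.0,
                         rain_freq_winter=0.2, rain_mean_mm=4.0)
        a = run_multiyear_projection(grenache, wx)
        b = run_multiyear_projection(syrah, wx)
        fa, fb = a["failure_doy"].iloc[0], b["failure_doy"].iloc[0]
        if np.isnan(fa) and np.isnan(fb):
            assert b["max_leaf_plc"].iloc[0] > a["max_leaf_plc"].iloc[0]
        elif np.isnan(fa):
            assert True  # reference survives, profligate fails
        else:
            assert fb <= fa

    def test_partial_year_skipped_with_warning(self, grenache):
        wx = gen_weather(years=2, seed=0).iloc[: 365 + 100]
        with pytest.warns(UserWarning, match="partial year"):
            res = run_multiyear_projection(grenache, wx)
        assert len(res) == 1

    def test_decade_summary_counts_failures(self):
        seasons = pd.DataFrame({
            "year": [2030, 2031, 2040, 2041],
            "max_leaf_plc": [40.0, 99.6, 20.0, 99.8],
            "failure_doy": [np.nan, 210.0, np.nan, 250.0],
            "total_assimilation": [50.0] * 4,
        })
        dec = decade_summary(seasons)
        assert dec.set_index("decade").loc[2030, "failure_years"] == 1
        assert dec.set_index("decade").loc[2040, "failure_years"] == 1
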
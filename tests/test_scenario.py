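"""Scenario generators: anomaly schedules, sea level, cyclones, design."""

import numpy as np
import pandas as pd
import pytest

from deltasim.config import (
    BASE_WINDOW,
    MIDCENTURY_WINDOW,
    SOCIO_VARIANTS,
    derive_seed,
    load_world,
    ConfigurationError,
)
from deltasim.scenario import (
    econ_index,
    embankment_series,
    enumerate_runs,
    generate_climate,
    generate_cyclones,
    month_of_doy,
    parent_run_id,
    population_series,
    rice_tolerance,
    slr_series,
    unit_production_multiplier,
)
from deltasim.synthregion import make_climatology


@pytest.fixture(scope="module")
def clim():
    return make_climatology()


def window_mean(series: pd.Series, window) -> float:
    y0, y1 = window
    return float(series.loc[y0:y1].mean())


# ---------------------------------------------------------------------------
# Sea level
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("world,target", [("positive", 38.5), ("negative", 73.5)])
def test_slr_midcentury_window_mean_exact(world, target):
    s = slr_series(load_world(world))
    assert window_mean(s, MIDCENTURY_WINDOW) == pytest.approx(target, abs=1e-9)


def test_slr_zero_in_2000_and_monotone():
    s = slr_series(load_world("negative"))
    assert s.loc[2000] == pytest.approx(0.0)
    assert np.all(np.diff(s.to_numpy()) >= 0)


def test_slr_quadratic_shape():
    s = slr_series(load_world("positive"))
    # quadratic from 2000: value(2040) / value(2020) = (40/20)^2
    assert s.loc[2040] / s.loc[2020] == pytest.approx(4.0)


# ---------------------------------------------------------------------------
# Climate anomalies
# ---------------------------------------------------------------------------

def test_temperature_window_contrast_matches_annual_target(clim):
    cfg = load_world("positive")
    w = generate_climate(cfg, clim, end_year=MIDCENTURY_WINDOW[1])
    annual = w.groupby("year")["temp_C"].mean()
    rise = window_mean(annual, MIDCENTURY_WINDOW) - window_mean(annual, BASE_WINDOW)
    assert rise == pytest.approx(cfg.temp_rise_C.annual, abs=1e-9)


def test_precipitation_window_contrast_matches_annual_target(clim):
    cfg = load_world("positive")
    w = generate_climate(cfg, clim, end_year=MIDCENTURY_WINDOW[1])
    annual = w.groupby("year")["precip_mm"].sum()
    change = window_mean(annual, MIDCENTURY_WINDOW) / window_mean(annual, BASE_WINDOW) - 1.0
    assert change == pytest.approx(cfg.precip_change_frac.annual, abs=1e-9)


def test_monsoon_dries_more_slowly_than_dry_season(clim):
    cfg = load_world("positive")
    w = generate_climate(cfg, clim)
    by = w.groupby(["year", "season"])["precip_mm"].sum().unstack()
    base = by.loc[BASE_WINDOW[0]:BASE_WINDOW[1]].mean()
    mid = by.loc[MIDCENTURY_WINDOW[0]:MIDCENTURY_WINDOW[1]].mean()
    change = mid / base - 1.0
    # dry season configured to dry much harder than the monsoon
    assert change["dry"] < change["monsoon"] < 0.0


def test_no_leap_calendar_and_months(clim):
    w = generate_climate(load_world("positive"), clim, start_year=2000, end_year=2001)
    assert len(w) == 2 * 365
    assert w["doy"].max() == 365
    assert set(w["month"].unique()) == set(range(1, 13))
    assert (month_of_doy(np.array([1, 31, 32, 365])) == [1, 1, 2, 12]).all()


def test_climate_noise_requires_seed(clim):
    with pytest.raises(ConfigurationError):
        generate_climate(load_world("positive"), clim, noise=True)


def test_climate_deterministic(clim):
    a = generate_climate(load_world("negative"), clim)
    b = generate_climate(load_world("negative"), clim)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# Cyclones
# ---------------------------------------------------------------------------

def test_cyclone_rates_recovered_over_many_decades():
    years = range(0, 20000)
    events = generate_cyclones(0.4, 4.2, years, seed=123)
    strong = sum(e.intensity_class == "strong" for e in events)
    weak = sum(e.intensity_class == "weak" for e in events)
    decades = len(list(years)) / 10.0
    assert strong / decades == pytest.approx(0.4, rel=0.1)
    assert weak / decades == pytest.approx(4.2, rel=0.05)


def test_cyclone_attributes_in_bounds():
    events = generate_cyclones(2.0, 10.0, range(2000, 2200), seed=7)
    assert events, "expected some events"
    for e in events:
        assert 1 <= e.doy <= 365
        assert 0.0 <= e.landfall_position <= 1.0
        lo, hi = (140.0, 250.0) if e.intensity_class == "strong" else (80.0, 140.0)
        assert lo <= e.wind_speed_kmh < hi


def test_cyclone_multiplier_scales_rate():
    years = range(0, 5000)
    n1 = len(generate_cyclones(0.0, 4.0, years, seed=5, freq_multiplier=1.0))
    n2 = len(generate_cyclones(0.0, 4.0, years, seed=5, freq_multiplier=1.5))
    assert n2 / n1 == pytest.approx(1.5, rel=0.1)


def test_cyclones_deterministic_per_seed():
    a = generate_cyclones(1.0, 4.0, range(2000, 2051), seed=9)
    b = generate_cyclones(1.0, 4.0, range(2000, 2051), seed=9)
    c = generate_cyclones(1.0, 4.0, range(2000, 2051), seed=10)
    assert a == b
    assert a != c


# ---------------------------------------------------------------------------
# Annual socio-economic series
# ---------------------------------------------------------------------------

def test_population_endpoints():
    s = population_series(load_world("negative"))
    assert s.loc[2000] == pytest.approx(14.0)
    assert s.loc[2015] == pytest.approx(14.0)
    assert s.loc[2050] == pytest.approx(11.0)


def test_econ_index_flat_before_base_then_compounds():
    s = econ_index(load_world("positive"), 2015)
    assert s.loc[2000] == pytest.approx(1.0)
    assert s.loc[2015] == pytest.approx(1.0)
    assert s.loc[2050] == pytest.approx(1.025**35)


def test_embankment_series_floors_at_zero():
    s = embankment_series(50.0, load_world("negative"), range(2015, 2051))
    assert s.loc[2015] == pytest.approx(50.0)
    assert s.min() == 0.0
    assert (s >= 0).all()


def test_practice_ramps():
    cfg = load_world("positive")
    assert rice_tolerance(cfg, 2015) == pytest.approx(6.0)
    assert rice_tolerance(cfg, 2050) == pytest.approx(13.0)
    assert unit_production_multiplier(cfg, 2015) == pytest.approx(1.0)
    assert unit_production_multiplier(cfg, 2050) == pytest.approx(1.2)


# ---------------------------------------------------------------------------
# Experiment design
# ---------------------------------------------------------------------------

def test_design_counts():
    runs = enumerate_runs(master_seed=1)
    assert len(runs) == 62
    base = [r for r in runs if r.overridden_driver is None]
    oat = [r for r in runs if r.overridden_driver is not None]
    assert len(base) == 36
    assert len(oat) == 26
    for world in ("positive", "negative"):
        assert sum(r.parent_world == world for r in oat) == 13


def test_run_ids_unique_and_parent_present():
    runs = enumerate_runs(master_seed=1)
    ids = [r.run_id for r in runs]
    assert len(set(ids)) == 62
    for world in ("positive", "negative"):
        assert parent_run_id(world) in ids


def test_base_design_covers_full_factorial():
    runs = enumerate_runs(master_seed=0)
    base = {
        (r.parent_world, r.design_dict["cyclone_seq"], r.design_dict["socio_variant"], r.design_dict["slr_level"])
        for r in runs
        if r.overridden_driver is None
    }
    expected = {
        (w, s, v, l)
        for w in ("positive", "negative")
        for s in (0, 1, 2)
        for v in SOCIO_VARIANTS
        for l in ("low", "high")
    }
    assert base == expected


def test_derive_seed_deterministic_and_bounded():
    a = derive_seed(1, "weather")
    assert a == derive_seed(1, "weather")
    assert a != derive_seed(1, "cyclones")
    assert a != derive_seed(2, "weather")
    for s in (derive_seed(i, "x") for i in range(200)):
        assert 0 <= s < 2**31
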
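"""Reduced-form flood model and its PLS+CCA emulator."""

import numpy as np
import pytest

from deltasim.flood import (
    Emulator,
    FloodParams,
    UnionCell,
    fit_emulator,
    predict_emulator,
    simulate_flood,
)
from deltasim.scenario import CycloneEvent


def make_cells(elevations, embankments=None, poldered=None, areas=None, coast=None):
    n = len(elevations)
    embankments = embankments or [0.0] * n
    poldered = poldered if poldered is not None else [h > 0 for h in embankments]
    areas = areas or [10.0] * n
    coast = coast or [i / max(n - 1, 1) for i in range(n)]
    return [
        UnionCell(
            union_id=f"u{i}",
            area_km2=areas[i],
            elevation_m=elevations[i],
            poldered=poldered[i],
            embankment_height_m=embankments[i],
            coast_distance=coast[i],
            population=1000.0,
            alongshore=0.5,
        )
        for i in range(n)
    ]


def test_worked_three_cell_example():
    """Hand-worked case: base water level 1.2 m (20 cm SLR + 1 m tide)."""
    cells = make_cells(
        elevations=[0.5, 0.5, 0.5],
        embankments=[0.0, 0.5, 1.0],
        poldered=[False, True, True],
    )
    res = simulate_flood(cells, sea_level_cm=20.0, discharge_index=0.0,
                         annual_precip_mm=0.0, cyclones=[])
    np.testing.assert_allclose(res.inundated_fraction, [1.0, 1.0, 0.0])
    np.testing.assert_allclose(res.mean_depth_m, [0.7, 0.2, 0.0], atol=1e-12)
    assert res.inundated_area_km2 == pytest.approx(20.0)


def test_monotone_in_sea_level():
    rng = np.random.default_rng(42)
    cells = make_cells(
        elevations=rng.uniform(0.0, 3.0, 12).tolist(),
        embankments=rng.uniform(0.0, 2.0, 12).tolist(),
    )
    areas = []
    for slr in np.linspace(0.0, 150.0, 16):
        res = simulate_flood(cells, slr, 1.0, 2000.0, [])
        areas.append(res.inundated_area_km2)
    diffs = np.diff(areas)
    assert np.all(diffs >= -1e-12)
    assert areas[-1] > areas[0]


def test_monotone_in_embankment_height():
    base_elev = [0.3, 0.8, 1.2, 1.8]
    areas = []
    for h in np.linspace(0.0, 3.0, 13):
        cells = make_cells(base_elev, embankments=[h] * 4, poldered=[True] * 4)
        res = simulate_flood(cells, 50.0, 1.0, 2500.0, [])
        areas.append(res.inundated_area_km2)
    assert np.all(np.diff(areas) <= 1e-12)


def test_cyclone_surge_decays_alongshore_and_inland():
    params = FloodParams()
    ev = CycloneEvent(year=2030, doy=200, intensity_class="strong",
                      wind_speed_kmh=200.0, landfall_position=0.5)
    near = UnionCell("near", 10.0, 0.5, False, 0.0, 0.0, 1000.0, alongshore=0.5)
    inland = UnionCell("inland", 10.0, 0.5, False, 0.0, 0.9, 1000.0, alongshore=0.5)
    away = UnionCell("away", 10.0, 0.5, False, 0.0, 0.0, 1000.0, alongshore=0.02)
    res = simulate_flood([near, inland, away], 0.0, 0.0, 0.0, [ev], params)
    depth = dict(zip(res.union_ids, res.mean_depth_m))
    assert depth["near"] > depth["inland"]
    assert depth["near"] > depth["away"]


def test_polders_suppress_fluvial_flooding():
    open_cell = make_cells([2.5], poldered=[False])[0]
    polder = UnionCell("p", 10.0, 2.5, True, 0.0, 0.5, 1000.0)
    res = simulate_flood([open_cell, polder], 0.0, 1.5, 3000.0, [])
    frac = dict(zip(res.union_ids, res.inundated_fraction))
    assert frac["u0"] > frac["p"] > 0.0


def test_floodwater_salinity_fresher_inland():
    cells = make_cells([0.1, 0.1, 0.1], coast=[0.0, 0.5, 1.0])
    res = simulate_flood(cells, 100.0, 0.0, 0.0, [])
    sal = res.floodwater_salinity_dS_m
    assert sal[0] > sal[1] > sal[2] > 0.0


def test_cell_validation():
    with pytest.raises(ValueError):
        UnionCell("x", -1.0, 0.5, False, 0.0, 0.0, 100.0)
    with pytest.raises(ValueError):
        UnionCell("x", 1.0, 0.5, True, -0.1, 0.0, 100.0)


# ---------------------------------------------------------------------------
# Emulator
# ---------------------------------------------------------------------------

def test_emulator_recovers_noiseless_linear_map():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(200, 5))
    B = rng.normal(size=(5, 3))
    Y = X @ B + 1.0
    em = fit_emulator(X, Y, n_components=5)
    Yhat = predict_emulator(em, X)
    ss_res = np.sum((Y - Yhat) ** 2)
    ss_tot = np.sum((Y - Y.mean(0)) ** 2)
    assert 1.0 - ss_res / ss_tot > 0.999


def test_emulator_null_model_is_training_mean():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(50, 4))
    Y = rng.normal(size=(50, 2))
    em = fit_emulator(X, Y, n_components=0)
    Yhat = predict_emulator(em, rng.normal(size=(7, 4)))
    np.testing.assert_allclose(Yhat, np.tile(Y.mean(0), (7, 1)))


def test_emulator_rejects_excess_components():
    X = np.random.default_rng(2).normal(size=(20, 3))
    Y = X @ np.ones((3, 2))
    with pytest.raises(ValueError):
        Emulator(n_components=4).fit(X, Y)
    with pytest.raises(ValueError):
        Emulator(n_components=-1)


def test_emulator_clips_requested_columns():
    rng = np.random.default_rng(3)
    X = rng.uniform(size=(80, 3))
    Y = np.column_stack([X @ [3.0, -3.0, 1.0], X @ [1.0, 1.0, 1.0]])
    em = fit_emulator(X, Y, n_components=3, clip01_cols=[0])
    Yhat = predict_emulator(em, rng.uniform(-2, 3, size=(50, 3)))
    assert Yhat[:, 0].min() >= 0.0 and Yhat[:, 0].max() <= 1.0


def test_emulator_cross_validated_on_toy_flood_model():
    """5-fold CV R^2 >= 0.9 against the reduced-form flood model."""
    rng = np.random.default_rng(10)
    m = 64
    cells = make_cells(
        elevations=rng.uniform(0.0, 3.0, m).tolist(),
        embankments=(rng.uniform(0.0, 1.5, m) * (rng.uniform(size=m) < 0.5)).tolist(),
    )
    n = 150
    X = np.column_stack(
        [
            rng.uniform(0.0, 100.0, n),   # sea level, cm
            rng.uniform(0.5, 1.5, n),     # discharge index
            rng.uniform(1500.0, 3000.0, n),  # annual precip
        ]
    )
    Y = np.array(
        [
            [
                (res := simulate_flood(cells, x[0], x[1], x[2], [])).inundated_area_km2,
                float(res.mean_depth_m.mean()),
                float(np.average(res.floodwater_salinity_dS_m, weights=res.areas_km2)),
            ]
            for x in X
        ]
    )
    folds = np.arange(n) % 5
    ss_res = ss_tot = 0.0
    for f in range(5):
        tr, te = folds != f, folds == f
        em = fit_emulator(X[tr], Y[tr], n_components=3)
        pred = predict_emulator(em, X[te])
        ss_res += np.sum((Y[te] - pred) ** 2)
        ss_tot += np.sum((Y[te] - Y[tr].mean(0)) ** 2)
    assert 1.0 - ss_res / ss_tot >= 0.9
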
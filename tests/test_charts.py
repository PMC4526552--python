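"""Chart assembly, simulation study orderings, tuning-series optima."""

import json

import numpy as np
import pandas as pd
import pytest

from esip.charts import (
    ESIPChart,
    analyze_tuning_series,
    build_chart,
    run_simulation_study,
)
from esip.fitting import ParameterMaps
from esip.simulate import ToyDataConfig, generate_synthetic_stack, solution_z_grid


@pytest.fixture(scope="module")
def layer_chart():
    rng = np.random.default_rng(21)
    n = 32
    maps = {
        "A_photons": np.full((n, n), 150.0),
        "z0": np.zeros((n, n)),
        "wFWHM": np.ones((n, n)),
        "s": np.full((n, n), -0.025),
    }
    z = np.arange(-6.0, 6.0001, 0.25)
    stack = generate_synthetic_stack(maps, z, kind="layer", rng=rng)
    return build_chart(stack, z, model="layer", shape="gauss", bin=4)


def test_chart_homogeneous_layer(layer_chart):
    ch = layer_chart
    assert ch.maps.converged.all()
    a_mean, a_std = ch.summary["A"]
    assert a_std / a_mean < 0.05  # uniform amplitude map
    z0_mean, z0_std = ch.summary["z0"]
    assert abs(z0_mean) < 0.05 and z0_std < 0.05
    s_mean, _ = ch.summary["s"]
    assert s_mean == pytest.approx(-0.025, abs=0.02)
    assert len(ch.profiles) == 5
    assert ch.calibration is not None
    assert ch.calibration.CF == pytest.approx(500.0, rel=0.1)
    # amplitude is also reported in photons and percent of max photons
    assert "A_photons" in ch.maps.params
    assert "A_percent_pmax" in ch.maps.params
    assert np.nanmax(ch.maps.params["A_percent_pmax"]) <= 101.0


def test_chart_json_round_trip(layer_chart, tmp_path):
    path = tmp_path / "chart.json"
    layer_chart.to_json(path)
    back = ESIPChart.from_json(path)
    assert back.schema_version == layer_chart.schema_version
    for k, v in layer_chart.maps.params.items():
        np.testing.assert_allclose(back.maps.params[k], v, equal_nan=True)
    assert back.calibration.CF == layer_chart.calibration.CF
    assert back.summary == {k: tuple(v) for k, v in layer_chart.summary.items()}


def test_chart_solution_null_length_constant():
    rng = np.random.default_rng(22)
    n = 16
    maps = {
        "A_photons": np.full((n, n), 80.0),
        "z0": np.zeros((n, n)),
        "wFWHM": np.ones((n, n)),
        "LC": np.zeros((n, n)),
    }
    z = solution_z_grid()
    stack = generate_synthetic_stack(maps, z, kind="solution", rng=rng)
    ch = build_chart(stack, z, model="solution", shape="gauss", bin=4,
                     variant="exact", fix={"ol": 0.0})
    lc_mean, lc_std = ch.summary["LC"]
    assert abs(lc_mean) < 2.0 * lc_std  # LC = 0 truth recovered as null


# ---------------------------------------------------------------------------
# simulation study
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_study():
    cfg = ToyDataConfig(kind="layer", levels=(2, 20, 200), n_reps=60, seed=101)
    return run_simulation_study(cfg)


def test_study_fit_beats_lookup_precision(small_study):
    """Fitted-amplitude scatter never exceeds the lookup scatter (>= 10 photons)."""
    for level in (20, 200):
        lk = small_study.select("lookup", "A")
        ft = small_study.select("fit", "A")
        assert (
            ft[ft.level == level]["std"].item()
            <= lk[lk.level == level]["std"].item()
        )


def test_study_lookup_amplitude_biased_high_at_low_counts(small_study):
    lk = small_study.select("lookup", "A")
    assert lk[lk.level == 2]["accuracy"].item() > 0


def test_study_z0_precision_floor(small_study):
    """Lookup axial precision is floored by the z spacing; the fit keeps
    improving with photon number."""
    lk = small_study.select("lookup", "z0_err")
    ft = small_study.select("fit", "z0_err")
    assert ft[ft.level == 200]["std"].item() < ft[ft.level == 20]["std"].item()
    assert lk[lk.level == 200]["std"].item() > ft[ft.level == 200]["std"].item()


def test_study_mean_fwhm_at_high_flux(small_study):
    ft = small_study.select("fit", "wFWHM")
    assert ft[ft.level == 200]["mean"].item() == pytest.approx(1.0, rel=0.03)


def test_study_skew_conversion_recorded(small_study):
    assert small_study.skew_conversion == pytest.approx(-2.0, rel=0.1)
    assert {"estimator", "parameter", "level", "mean", "std", "accuracy", "rel_std"} <= set(
        small_study.table.columns
    )


# ---------------------------------------------------------------------------
# tuning series
# ---------------------------------------------------------------------------


def _maps_with(A, w, z0):
    n = 8
    mk = lambda v: np.full((n, n), float(v))
    return ParameterMaps(
        bin=4,
        params={"A": mk(A), "wFWHM": mk(w), "z0": mk(z0)},
        r2=mk(1.0),
        converged=np.ones((n, n), bool),
        bin_centers=(np.arange(n), np.arange(n)),
        model="layer",
        shape="gauss",
    )


def test_tuning_parabola_vertex_exact():
    settings = np.linspace(0.1, 0.2, 7)
    series = [
        (s, _maps_with(A=100 - 4000 * (s - 0.137) ** 2, w=1 + 30 * (s - 0.162) ** 2, z0=0))
        for s in settings
    ]
    ts = analyze_tuning_series(series)
    assert ts.optima["A"] == pytest.approx(0.137, abs=1e-6)
    assert ts.optima["wFWHM"] == pytest.approx(0.162, abs=1e-6)
    assert not ts.boundary["A"] and not ts.boundary["wFWHM"]


def test_tuning_affine_setting_rescale():
    settings = np.linspace(0.1, 0.2, 7)
    make = lambda s: _maps_with(A=100 - 4000 * (s - 0.137) ** 2, w=1.0, z0=0)
    t1 = analyze_tuning_series([(s, make(s)) for s in settings])
    t2 = analyze_tuning_series([(10 * s + 3, make(s)) for s in settings])
    assert t2.optima["A"] == pytest.approx(10 * t1.optima["A"] + 3, rel=1e-9)


def test_tuning_dz0_sign_change_root():
    settings = np.linspace(0.0, 1.0, 6)
    series = [
        (s, _maps_with(100, 1, z0=0.4 * (s - 0.73)), _maps_with(100, 1, z0=0.0))
        for s in settings
    ]
    ts = analyze_tuning_series(series)
    assert ts.optima["dz0"] == pytest.approx(0.73, abs=1e-9)


def test_tuning_monotone_series_warns_boundary():
    series = [(s, _maps_with(A=10 * s, w=1, z0=0)) for s in (0.1, 0.2, 0.3, 0.4)]
    ts = analyze_tuning_series(series)
    assert ts.boundary["A"]
    assert any("extend series" in w for w in ts.warnings)


def test_tuning_needs_three_settings():
    with pytest.raises(ValueError, match="3 settings"):
        analyze_tuning_series([(0, _maps_with(1, 1, 0)), (1, _maps_with(1, 1, 0))])
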
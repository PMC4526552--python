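"""Axial profile models: closed forms, limits, stability, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from esip.models import (
    FOUR_LN2,
    AxialProfile,
    LayerParams,
    SolutionParams,
    layer_model,
    penetration_drop,
    skew_transform,
    solution_model_approx,
    solution_model_exact,
    voigt_mixture_error,
)

# ---------------------------------------------------------------------------
# independent literal transcriptions used as oracles (kept deliberately
# naive: they re-derive nothing from the implementation under test)
# ---------------------------------------------------------------------------


def _oracle_layer_pseudo_voigt(I0, A, z0, w, s, mL, z):
    dz = z - z0
    zs = dz * np.exp(s * dz)
    lorentz = w**2 / (4 * zs**2 + w**2)
    gauss = np.exp(-4 * np.log(2) * (zs / w) ** 2)
    return I0 + A * (mL * lorentz + (1 - mL) * gauss)


def _oracle_solution_pv_approx(I0, A, z0, w, LC, ol, mL, z):
    import math

    dz = z - z0
    env = (1 - ol) * np.exp(-LC * dz) + ol
    lor = (1 / np.pi) * (np.pi / 2 + np.arctan(2 * dz / w))
    gau = 0.5 * (1 + np.array([math.erf(v) for v in np.sqrt(4 * np.log(2)) * dz / w]))
    return I0 + A * env * (mL * lor + (1 - mL) * gau)


def _quadrature_solution(I0, A, z0, w, LC, ol, zv):
    """Adaptive quadrature of the printed integrand (narrow-kernel aware)."""
    import math

    def integrand(zp):
        return (
            math.sqrt(4 * math.log(2) / math.pi)
            / w
            * math.exp(-4 * math.log(2) * ((zp - zv) / w) ** 2)
            * ((1 - ol) * math.exp(-LC * (zp - z0)) + ol)
        )

    total = 0.0
    # split so the narrow Gaussian around zv is never missed
    cuts = sorted({z0, max(z0, zv - 12 * w), max(z0, zv + 12 * w)})
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b > a:
            total += quad(integrand, a, b, limit=400)[0]
    total += quad(integrand, cuts[-1], np.inf, limit=400)[0]
    return I0 + A * total


# ---------------------------------------------------------------------------
# skew transform and layer models
# ---------------------------------------------------------------------------


def test_skew_transform_values():
    assert skew_transform(0.0, -0.025) == 0.0
    assert skew_transform(3.7, 0.0) == 3.7
    assert np.isclose(skew_transform(1.0, -0.025), np.exp(-0.025))


@pytest.mark.parametrize("shape", ["gauss", "lorentz", "pseudo_voigt"])
def test_layer_peak_and_half_maximum(shape):
    p = LayerParams(I0=500, A=5000, z0=0.0, wFWHM=1.0, s=0.0, mL=0.65)
    z = np.array([-0.5, 0.0, 0.5])
    vals = layer_model(p, z, shape)
    assert vals[1] == pytest.approx(5500.0)
    # half maximum (I0 + A/2) at z0 +- wFWHM/2 for every shape when s = 0
    assert vals[0] == pytest.approx(3000.0)
    assert vals[2] == pytest.approx(3000.0)


def test_layer_pseudo_voigt_matches_literal_transcription():
    p = LayerParams(I0=500, A=5000, z0=0.0, wFWHM=1.0, s=-0.025, mL=0.65)
    z = np.array([0.8])
    expected = _oracle_layer_pseudo_voigt(500, 5000, 0.0, 1.0, -0.025, 0.65, z)
    assert layer_model(p, z, "pseudo_voigt") == pytest.approx(expected, rel=1e-12)


def test_layer_model_translation_invariance():
    z = np.linspace(-3, 3, 61)
    a = layer_model(LayerParams(100, 1000, 0.0, 1.2, s=-0.05, mL=0.3), z, "pseudo_voigt")
    b = layer_model(LayerParams(100, 1000, 5.0, 1.2, s=-0.05, mL=0.3), z + 5.0, "pseudo_voigt")
    np.testing.assert_allclose(a, b, rtol=1e-12)


def test_invalid_shape_rejected():
    p = LayerParams(0, 1, 0, 1)
    with pytest.raises(ValueError, match="shape"):
        layer_model(p, np.zeros(3), "voigt")


@settings(max_examples=50, deadline=None)
@given(
    mL=st.floats(0.05, 0.95),
    z=st.floats(-5, 5),
    w=st.floats(0.2, 4.0),
)
def test_pseudo_voigt_is_convex_combination(mL, z, w):
    za = np.array([z])
    g = layer_model(LayerParams(0, 1, 0, w), za, "gauss")[0]
    l = layer_model(LayerParams(0, 1, 0, w), za, "lorentz")[0]
    pv = layer_model(LayerParams(0, 1, 0, w, mL=mL), za, "pseudo_voigt")[0]
    assert min(g, l) - 1e-12 <= pv <= max(g, l) + 1e-12
    assert pv == pytest.approx(mL * l + (1 - mL) * g, rel=1e-12)


# ---------------------------------------------------------------------------
# solution models
# ---------------------------------------------------------------------------


def test_solution_exact_interface_and_plateau_limits():
    p = SolutionParams(I0=500, A=2000, z0=0.0, wFWHM=1.0, LC=0.0, ol=0.3)
    assert solution_model_exact(p, np.array([0.0]))[0] == pytest.approx(1500.0)
    assert solution_model_exact(p, np.array([1e4]))[0] == pytest.approx(2500.0)


@pytest.mark.parametrize(
    "LC,ol", [(0.0, 0.0), (0.00952, 0.0), (0.002, 0.1), (0.05, 0.5)]
)
def test_solution_exact_matches_quadrature(LC, ol):
    p = SolutionParams(I0=500, A=2000, z0=0.0, wFWHM=1.0, LC=LC, ol=ol)
    for zv in [-2.0, -0.3, 0.0, 0.7, 3.0, 40.0, 150.0]:
        expected = _quadrature_solution(500, 2000, 0.0, 1.0, LC, ol, zv)
        got = solution_model_exact(p, np.array([zv]))[0]
        assert got == pytest.approx(expected, rel=1e-6)


def test_solution_exact_quadrature_on_dense_grid():
    """Closed form equals the integral to 1e-6 relative on a 1000-point grid."""
    p = SolutionParams(I0=0.0, A=1.0, z0=0.0, wFWHM=1.0, LC=0.00952, ol=0.0)
    zg = np.linspace(-5.0, 200.0, 1000)
    got = solution_model_exact(p, zg)
    check = np.linspace(0, 999, 25, dtype=int)  # quadrature is slow; subsample
    for i in check:
        expected = _quadrature_solution(0.0, 1.0, 0.0, 1.0, 0.00952, 0.0, zg[i])
        assert got[i] == pytest.approx(expected, rel=1e-6, abs=1e-12)


def test_solution_exact_stable_where_naive_composition_fails():
    """Scaled-erfc evaluation stays finite where exp() * erfc() breaks down."""
    from scipy.special import erfc, erfcx

    # LC * w = 10: finite and non-negative over a deep z range
    p = SolutionParams(I0=0.0, A=1.0, z0=0.0, wFWHM=1.0, LC=10.0)
    z = np.linspace(-5, 200, 500)
    v = solution_model_exact(p, z)
    assert np.all(np.isfinite(v)) and np.all(v >= -1e-15)

    # strong attenuation: at the interface the naive composition is
    # exp(+overflow) * erfc(+underflow) = inf * 0 = nan
    p2 = SolutionParams(I0=0.0, A=1.0, z0=0.0, wFWHM=1.0, LC=100.0)
    dz = 0.0
    sq = np.sqrt(FOUR_LN2)
    x = p2.LC * p2.wFWHM / (2 * sq) - sq * dz / p2.wFWHM
    with np.errstate(over="ignore", invalid="ignore"):
        naive = 0.5 * np.exp(p2.LC * (p2.LC / (16 * np.log(2)) - dz)) * erfc(x)
    assert np.isnan(naive)
    got = solution_model_exact(p2, np.array([0.0]))[0]
    assert np.isfinite(got)
    assert got == pytest.approx(0.5 * erfcx(x), rel=1e-12)


def test_solution_approx_mixture_endpoints(rng):
    p = SolutionParams(I0=500, A=2000, z0=0.0, wFWHM=1.0, LC=0.002, ol=0.1, mL=0.0)
    z = rng.uniform(-5, 150, 50)
    z.sort()
    np.testing.assert_allclose(
        solution_model_approx(p, z, "pseudo_voigt"),
        solution_model_approx(p, z, "gauss"),
        rtol=0, atol=0,
    )
    p1 = p.replace(mL=1.0)
    np.testing.assert_allclose(
        solution_model_approx(p1, z, "pseudo_voigt"),
        solution_model_approx(p1, z, "lorentz"),
        rtol=0, atol=0,
    )


def test_solution_approx_equals_exact_at_zero_LC():
    p = SolutionParams(I0=500, A=2000, z0=0.0, wFWHM=1.0, LC=0.0, ol=0.2)
    z = np.linspace(-5, 200, 400)
    a = solution_model_approx(p, z, "gauss")
    b = solution_model_exact(p, z)
    np.testing.assert_allclose(a, b, rtol=1e-12)


def test_solution_pv_approx_matches_literal_transcription():
    z = np.array([10.0])
    p = SolutionParams(I0=500, A=2000, z0=0.0, wFWHM=1.0, LC=0.002, ol=0.1, mL=0.65)
    expected = _oracle_solution_pv_approx(500, 2000, 0.0, 1.0, 0.002, 0.1, 0.65, z)
    assert solution_model_approx(p, z, "pseudo_voigt")[0] == pytest.approx(
        float(expected[0]), rel=1e-12
    )


# ---------------------------------------------------------------------------
# penetration drop and Voigt fidelity
# ---------------------------------------------------------------------------


def test_penetration_drop_values():
    # 63x oil objective: LC = 9.52 / mm = 0.00952 / um over 100 um depth
    assert penetration_drop(0.00952, 100.0) == pytest.approx(0.614, abs=5e-4)
    assert penetration_drop(0.0, 100.0) == 0.0
    assert penetration_drop(0.5, 0.0) == 0.0
    # 20x air objective row
    assert penetration_drop(0.00264, 100.0) == pytest.approx(1 - np.exp(-0.264))


def test_penetration_drop_monotone():
    depths = np.linspace(0, 300, 30)
    lcs = np.linspace(0, 0.02, 20)
    d1 = penetration_drop(0.005, depths)
    assert np.all(np.diff(d1) > 0)
    d2 = np.array([penetration_drop(lc, 100.0) for lc in lcs])
    assert np.all(np.diff(d2) > 0)


def test_pseudo_voigt_close_to_true_voigt_single_ratio():
    err = voigt_mixture_error(width_ratios=[1.0])
    assert err[0] < 1.0  # percent of peak


def test_profile_container_validation():
    with pytest.raises(ValueError, match="increasing"):
        AxialProfile(np.array([0.0, 0.0, 1.0]), np.zeros(3))
    with pytest.raises(ValueError, match="length"):
        AxialProfile(np.arange(3.0), np.zeros(4))
    prof = AxialProfile(np.arange(4.0), np.arange(4.0) ** 2)
    fl = prof.flipped()
    assert np.all(np.diff(fl.z) > 0)
    np.testing.assert_allclose(fl.intensity, prof.intensity[::-1])
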
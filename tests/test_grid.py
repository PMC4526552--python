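"""Grid analysis: crossings, distortion, chromatic shift, Moire spectra."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from esip.grid import (
    chromatic_shift,
    detect_crossings,
    estimate_period,
    moire_spectrum,
    quantify_distortion,
)
from esip.simulate import GridTruth, generate_grid_image

PX = 0.6
PERIOD = 6.0


def _truth(**kw):
    return GridTruth(period=PERIOD, line_width=1.2, pixel_size=PX,
                     shape=(128, 128), **kw)


@pytest.fixture(scope="module")
def perfect():
    t = _truth()
    img = generate_grid_image(t)
    pts = detect_crossings(img, pixel_size=PX, period=PERIOD, line_width=1.2)
    return t, img, pts


def test_crossings_on_perfect_lattice(perfect):
    t, img, pts = perfect
    truth = t.crossing_positions(margin=3.0)
    d, _ = cKDTree(pts).query(truth)
    assert d.max() / PX < 0.1  # sub-pixel accuracy
    assert len(pts) >= len(truth)


def test_period_estimation(perfect):
    _, img, _ = perfect
    assert estimate_period(img, PX) == pytest.approx(PERIOD, rel=0.05)


def test_blank_image_refused():
    blank = np.full((128, 128), 120.0)
    with pytest.raises(ValueError, match="refused"):
        detect_crossings(blank, pixel_size=PX, period=PERIOD)
    rng = np.random.default_rng(0)
    noise = rng.poisson(120.0, (128, 128)).astype(float)
    with pytest.raises(ValueError, match="refused"):
        detect_crossings(noise, pixel_size=PX, period=PERIOD)


def test_rotation_covariance(perfect):
    t, img, pts = perfect
    pts_rot = detect_crossings(np.rot90(img), pixel_size=PX, period=PERIOD, line_width=1.2)
    # 90 deg rotation maps (x, y) -> (y, W - x) in physical units
    w_um = (img.shape[1] - 1) * PX
    mapped = np.column_stack([pts[:, 1], w_um - pts[:, 0]])
    d, _ = cKDTree(pts_rot).query(mapped)
    assert d.max() / PX < 0.1


def test_warp_preserves_detection_count(perfect):
    _, _, pts0 = perfect
    img = generate_grid_image(_truth(c2_vertical=2e-3))
    pts = detect_crossings(img, pixel_size=PX, period=PERIOD, line_width=1.2)

    def inner(p):
        w = (128 - 1) * PX
        m = (p > PERIOD).all(axis=1) & (p < w - PERIOD).all(axis=1)
        return m.sum()

    # away from the image border (where window clipping applies) the warp
    # does not change how many crossings are found
    assert inner(pts) == inner(pts0)


def test_affine_lattice_has_zero_c2():
    t = _truth()
    pts = t.crossing_positions()
    aff = np.array([[1.02, 0.07], [-0.05, 0.97]])
    warped = pts @ aff.T + np.array([1.3, -0.8])
    for line in quantify_distortion(warped, period=PERIOD):
        assert abs(line.c2) < 1e-10


def test_injected_c2_recovered_within_ten_percent():
    c2 = 2e-3
    img = generate_grid_image(_truth(c2_vertical=c2))
    pts = detect_crossings(img, pixel_size=PX, period=PERIOD, line_width=1.2)
    lines = quantify_distortion(pts, period=PERIOD)
    vert = [l.c2 for l in lines if l.family == "vertical" and l.n_points >= 5]
    assert np.mean(vert) == pytest.approx(c2, rel=0.10)
    horiz = [l.c2 for l in lines if l.family == "horizontal" and l.n_points >= 5]
    assert abs(np.mean(horiz)) < 0.1 * c2


def test_barrel_distortion_grows_toward_edges():
    img = generate_grid_image(_truth(barrel=2e-5))
    pts = detect_crossings(img, pixel_size=PX, period=PERIOD, line_width=1.2)
    lines = quantify_distortion(pts, period=PERIOD)
    vert = [l for l in lines if l.family == "vertical" and l.n_points >= 5]
    pos = np.array([l.c0 for l in vert])
    mag = np.array([abs(l.c2) for l in vert])
    order = np.argsort(np.abs(pos))
    # |c2| increases from field centre to the edge lines
    assert mag[order[-1]] > 3.0 * mag[order[0]]
    assert np.corrcoef(np.abs(pos), mag)[0, 1] > 0.8


def test_chromatic_shift_constant_offset():
    t = _truth(channel_offsets={1: (0.12, 0.06)})
    a = detect_crossings(generate_grid_image(t, 0), pixel_size=PX, period=PERIOD, line_width=1.2)
    b = detect_crossings(generate_grid_image(t, 1), pixel_size=PX, period=PERIOD, line_width=1.2)
    _, vec, flags = chromatic_shift(a, b, period=PERIOD)
    assert flags == ()
    # 0.05 px tolerance on the mean recovered offset
    assert np.allclose(vec.mean(axis=0), [0.12, 0.06], atol=0.05 * PX)
    # antisymmetry
    _, vec_rev, _ = chromatic_shift(b, a, period=PERIOD)
    assert np.allclose(vec_rev.mean(axis=0), -vec.mean(axis=0), atol=1e-6)


def test_chromatic_shift_identical_channels(perfect):
    _, _, pts = perfect
    _, vec, _ = chromatic_shift(pts, pts, period=PERIOD)
    assert np.max(np.abs(vec)) == 0.0


def test_chromatic_shift_radial_field():
    radial = lambda xc, yc: (2e-3 * xc, 2e-3 * yc)
    t = _truth(channel_offsets={1: radial})
    a = detect_crossings(generate_grid_image(t, 0), pixel_size=PX, period=PERIOD, line_width=1.2)
    b = detect_crossings(generate_grid_image(t, 1), pixel_size=PX, period=PERIOD, line_width=1.2)
    anchors, vec, _ = chromatic_shift(a, b, period=PERIOD)
    centre = anchors.mean(axis=0)
    expect = np.column_stack(radial(anchors[:, 0] - centre[0], anchors[:, 1] - centre[1]))
    rx = np.corrcoef(vec[:, 0], expect[:, 0])[0, 1]
    ry = np.corrcoef(vec[:, 1], expect[:, 1])[0, 1]
    assert rx > 0.95 and ry > 0.95


# ---------------------------------------------------------------------------
# Moire spectra
# ---------------------------------------------------------------------------


def test_moire_well_sampled_grid_peak():
    t = GridTruth(period=0.6, line_width=0.25, pixel_size=0.1, shape=(64, 256))
    peaks = moire_spectrum(generate_grid_image(t), axis=1, pixel_size=0.1, period=0.6)
    assert peaks[0].kind == "grid"
    assert peaks[0].frequency == pytest.approx(1 / 0.6, rel=0.05)


def test_moire_beat_dominates_at_similar_pixel_size():
    # pixel pitch close to the line period: the grid frequency itself is
    # beyond Nyquist and a low-frequency beat dominates the spectrum
    t = GridTruth(period=0.6, line_width=0.25, pixel_size=0.63, shape=(64, 256))
    peaks = moire_spectrum(generate_grid_image(t), axis=1, pixel_size=0.63, period=0.6)
    assert peaks and peaks[0].kind == "beat"
    assert peaks[0].frequency < 0.5 / 0.6


def test_moire_beat_frequency_formula():
    """Pixel 580 nm on a 600 nm grid: beat at |1/0.6 - 1/0.58| per um."""
    t = GridTruth(period=0.6, line_width=0.25, pixel_size=0.58, shape=(64, 512))
    peaks = moire_spectrum(generate_grid_image(t), axis=1, pixel_size=0.58, period=0.6)
    expected = abs(1 / 0.6 - 1 / 0.58)
    df = 1.0 / (512 * 0.58)
    beat = [p for p in peaks if p.kind == "beat"]
    assert beat
    assert min(abs(p.frequency - expected) for p in beat) <= 2 * df


def test_moire_needs_enough_samples():
    with pytest.raises(ValueError, match="64 samples"):
        moire_spectrum(np.zeros((4, 32)), axis=1)
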
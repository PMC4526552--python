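"""Lateral calibration from structured grid targets.

Crossing points of a two-family line grid are detected (threshold,
morphology, skeleton branch points, sub-pixel refinement), grouped into
lines, and each line is fitted with a second-order polynomial in centred
field coordinates; the quadratic term quantifies distortion (0 = linear).
Comparing matched crossings between two excitation channels yields
chromatic shift vectors.  A 1-D Fourier analysis diagnoses Moire beating
when the scan pixel pitch approaches the grid period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import binary_closing as ndi_binary_closing
from scipy.ndimage import binary_dilation, gaussian_filter, map_coordinates
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import skeletonize

__all__ = [
    "LineFit",
    "SpectralPeak",
    "GridAnalysisResult",
    "estimate_period",
    "detect_crossings",
    "quantify_distortion",
    "chromatic_shift",
    "moire_spectrum",
]


@dataclass(frozen=True)
class LineFit:
    """Second-order fit of one grid line: ``pos = c0 + c1 t + c2 t^2``.

    For the vertical family, ``pos`` is x and ``t`` the centred y
    coordinate (and vice versa).  ``c2`` (1/um) is the distortion metric;
    multiply by 1e5 for display.
    """

    family: str
    c0: float
    c1: float
    c2: float
    n_points: int
    flags: Tuple[str, ...] = ()


@dataclass(frozen=True)
class SpectralPeak:
    frequency: float  # 1/um
    power: float
    kind: str  # 'grid' | 'beat' | 'other'


@dataclass
class GridAnalysisResult:
    """Outcome of a lateral grid analysis (one or two channels)."""

    crossings: Dict[int, np.ndarray]
    lines: Dict[int, List[LineFit]]
    shift_points: Optional[np.ndarray] = None
    shift_vectors: Optional[np.ndarray] = None
    period: Optional[float] = None
    flags: Tuple[str, ...] = ()


def estimate_period(image: np.ndarray, pixel_size: float = 1.0) -> float:
    """Grid period (um) from the strongest non-DC Fourier peak of the
    row/column mean profiles."""
    best = None
    for axis in (0, 1):
        prof = image.astype(float).mean(axis=axis)
        prof -= prof.mean()
        power = np.abs(np.fft.rfft(prof)) ** 2
        freqs = np.fft.rfftfreq(prof.size, d=pixel_size)
        if power.size < 3:
            continue
        i = 1 + int(np.argmax(power[1:]))
        if best is None or power[i] > best[0]:
            best = (power[i], freqs[i])
    if best is None or best[1] == 0:
        raise ValueError("cannot estimate grid period")
    return 1.0 / best[1]


def detect_crossings(
    image: np.ndarray,
    pixel_size: float = 1.0,
    period: Optional[float] = None,
    line_width: Optional[float] = None,
    min_crossings: int = 4,
    min_separability: float = 50.0,
) -> np.ndarray:
    """Detect grid crossing points, returned as (N, 2) ``(x, y)`` in um.

    Pipeline: structure gate (the grid frequency must stand out of the mean
    row/column spectra by ``min_separability`` over the noise floor),
    Gaussian smoothing (sigma = line_width / 2), Otsu threshold, binary
    closing, skeletonisation, branch-point extraction, clustering of branch
    pixels, and sub-pixel refinement by an iteratively re-centred
    Gaussian-weighted intensity centroid.  Crossings whose refinement
    window would leave the image are dropped.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if period is None:
        period = estimate_period(img, pixel_size)
    p_px = period / pixel_size
    lw = line_width if line_width is not None else period / 4.0
    sigma_px = max(lw / 2.0 / pixel_size, 0.5)

    sm = gaussian_filter(img, sigma_px)
    if np.ptp(sm) == 0:
        raise ValueError("grid contrast below noise: analysis refused")
    # structure check: a real grid shows a prominent spectral line at the
    # grid frequency in the row/column mean profiles; noise does not
    prominence = 0.0
    for axis in (0, 1):
        prof = img.mean(axis=axis) - img.mean()
        power = np.abs(np.fft.rfft(prof)) ** 2
        freqs = np.fft.rfftfreq(prof.size, d=pixel_size)
        if power.size < 4:
            continue
        sel = np.abs(freqs - 1.0 / period) <= 2.0 * freqs[1]
        if sel.any():
            prominence = max(
                prominence, power[sel].max() / max(np.median(power[1:]), 1e-300)
            )
    if prominence < min_separability:
        raise ValueError("grid contrast below noise: analysis refused")
    t = threshold_otsu(sm)
    fg = sm > t
    if not 0 < fg.mean() < 1:
        raise ValueError("grid contrast below noise: analysis refused")

    fg = ndi_binary_closing(fg, structure=np.ones((3, 3), dtype=bool))
    skel = skeletonize(fg)
    # branch points: skeleton pixels with >= 3 skeleton neighbours
    nb = np.zeros_like(skel, dtype=int)
    s = skel.astype(int)
    nb[1:-1, 1:-1] = (
        s[:-2, :-2] + s[:-2, 1:-1] + s[:-2, 2:]
        + s[1:-1, :-2] + s[1:-1, 2:]
        + s[2:, :-2] + s[2:, 1:-1] + s[2:, 2:]
    )
    branches = skel & (nb >= 3)
    if not branches.any():
        raise ValueError("fewer than 4 crossings detected: analysis refused")

    # cluster nearby branch pixels into candidate crossings
    grow = int(max(1, round(p_px / 8.0)))
    clustered = binary_dilation(branches, iterations=grow)
    labels = label(clustered)
    cands = [r.centroid for r in regionprops(labels)]  # (row, col)

    half = int(max(3, round(0.4 * p_px)))
    rw = max(p_px / 6.0, 1.0)  # Gaussian window radius (px)
    bg = np.percentile(sm, 20)
    off = np.arange(-half, half + 1, dtype=float)
    wgt = np.exp(-(off[:, None] ** 2 + off[None, :] ** 2) / (2.0 * rw**2))
    pts = []
    for cy, cx in cands:
        x_c, y_c = float(cx), float(cy)
        ok = True
        # iterative Gaussian-weighted centroid on a patch interpolated
        # symmetrically around the current estimate (an integer window
        # would bias the centroid toward its own centre)
        for _ in range(12):
            if not (
                half <= y_c <= img.shape[0] - 1 - half
                and half <= x_c <= img.shape[1] - 1 - half
            ):
                ok = False
                break
            coords = np.meshgrid(y_c + off, x_c + off, indexing="ij")
            win = map_coordinates(sm, np.array(coords), order=3, mode="nearest")
            m = np.clip(win - bg, 0.0, None) * wgt
            tot = m.sum()
            if tot <= 0:
                ok = False
                break
            dx = float((m.sum(axis=0) * off).sum() / tot)
            dy = float((m.sum(axis=1) * off).sum() / tot)
            x_c += dx
            y_c += dy
            if np.hypot(dx, dy) < 1e-4:
                break
        if ok:
            pts.append((x_c, y_c))
    pts = np.asarray(pts, dtype=float)
    if pts.shape[0] < min_crossings:
        raise ValueError("fewer than 4 crossings detected: analysis refused")
    return pts * pixel_size


def _assign_lines(coord: np.ndarray, period: float) -> np.ndarray:
    """Initial line labels by rounding the coordinate to the period raster."""
    offs = np.angle(np.exp(2j * np.pi * coord / period).mean()) / (2 * np.pi) * period
    return np.round((coord - offs) / period).astype(int)


def quantify_distortion(
    points: np.ndarray,
    period: float,
    min_points_per_line: int = 3,
    n_iter: int = 5,
) -> List[LineFit]:
    """Group crossings into lines and fit ``c0 + c1 t + c2 t^2`` per line.

    Points are assigned to the vertical family by their x coordinate and to
    the horizontal family by y, then iteratively re-assigned to the nearest
    fitted line; points nearly equidistant to two lines are flagged
    ``ambiguous``.  Fits use centred field coordinates so ``c2`` is
    comparable across fields; an affine-transformed perfect lattice yields
    ``c2 = 0`` for every line.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (N, 2)")
    xm, ym = pts.mean(axis=0)
    xc, yc = pts[:, 0] - xm, pts[:, 1] - ym

    fits: List[LineFit] = []
    for family, pos, t in (("vertical", xc, yc), ("horizontal", yc, xc)):
        labels = _assign_lines(pos, period)
        ambiguous = np.zeros(pos.size, dtype=bool)
        for _ in range(n_iter):
            coeffs = {}
            for lab in np.unique(labels):
                m = labels == lab
                if m.sum() >= min_points_per_line:
                    deg = 2 if m.sum() > 3 else min(m.sum() - 1, 2)
                    coeffs[lab] = np.polyfit(t[m], pos[m], deg)
            if not coeffs:
                break
            labs = np.array(sorted(coeffs))
            pred = np.vstack([np.polyval(coeffs[l], t) for l in labs])
            d = np.abs(pred - pos[None, :])
            new = labs[np.argmin(d, axis=0)]
            srt = np.sort(d, axis=0)
            if srt.shape[0] > 1:
                ambiguous = srt[1] - srt[0] < 0.05 * period
            if np.array_equal(new, labels):
                labels = new
                break
            labels = new
        for lab in np.unique(labels):
            m = labels == lab
            if m.sum() < min_points_per_line:
                continue
            c = np.polyfit(t[m], pos[m], 2)
            flags = ("ambiguous",) if np.any(ambiguous & m) else ()
            fits.append(
                LineFit(family=family, c0=float(c[2]), c1=float(c[1]),
                        c2=float(c[0]), n_points=int(m.sum()), flags=flags)
            )
    return fits


def chromatic_shift(
    points_ch1: np.ndarray,
    points_ch2: np.ndarray,
    period: float,
    max_unmatched: float = 0.2,
):
    """Shift vectors between matched crossings of two channels.

    Each channel-1 crossing is matched to its nearest channel-2 crossing
    within half a period; the vector is ``ch2 - ch1``.  Returns
    ``(anchor_points, vectors, flags)``; a warning flag is set when more
    than ``max_unmatched`` of the channel-1 points stay unmatched.
    Antisymmetric by construction: swapping the channels negates the
    vectors.
    """
    p1 = np.asarray(points_ch1, dtype=float)
    p2 = np.asarray(points_ch2, dtype=float)
    tree = cKDTree(p2)
    d, j = tree.query(p1, distance_upper_bound=period / 2.0)
    ok = np.isfinite(d)
    flags: Tuple[str, ...] = ()
    if (~ok).mean() > max_unmatched:
        flags = ("unmatched_fraction_high",)
    vectors = p2[j[ok]] - p1[ok]
    return p1[ok], vectors, flags


def moire_spectrum(
    image: np.ndarray,
    axis: int = 1,
    pixel_size: float = 1.0,
    period: Optional[float] = None,
    floor_multiple: float = 8.0,
    max_harmonic: int = 4,
) -> List[SpectralPeak]:
    """1-D power spectrum along ``axis`` with Moire-peak classification.

    Every row (line of the image along ``axis``) is mean-subtracted and
    Fourier-transformed; the power spectra are averaged.  Peaks above
    ``floor_multiple`` times the median power are reported and classified
    against the (given or estimated) grid frequency: ``grid`` when the peak
    sits at the grid frequency, ``beat`` when it matches an aliased beat
    ``|m * f_grid - k * f_s|`` of the grid harmonics with the sampling
    frequency ``f_s``, otherwise ``other``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if img.shape[axis] < 64:
        raise ValueError("need at least 64 samples along the analysis axis")
    rows = img if axis == 1 else img.T
    rows = rows - rows.mean(axis=1, keepdims=True)
    power = (np.abs(np.fft.rfft(rows, axis=1)) ** 2).mean(axis=0)
    freqs = np.fft.rfftfreq(rows.shape[1], d=pixel_size)
    df = freqs[1]

    if period is None:
        period = estimate_period(img, pixel_size)
    f_grid = 1.0 / period
    f_s = 1.0 / pixel_size

    floor = floor_multiple * max(np.median(power[1:]), 1e-300)
    idx, _ = find_peaks(power, height=floor)
    idx = idx[np.argsort(power[idx])[::-1]]

    beats = []
    for m in range(1, max_harmonic + 1):
        for k in range(0, max_harmonic + 1):
            f = abs(m * f_grid - k * f_s)
            if 0 < f <= freqs[-1] + df:
                beats.append((f, m, k))

    peaks = []
    tol = 2.0 * df
    for i in idx:
        f = freqs[i]
        if abs(f - f_grid) <= tol:
            kind = "grid"
        elif any(abs(f - fb) <= tol and not (m == 1 and k == 0) for fb, m, k in beats):
            kind = "beat"
        else:
            kind = "other"
        peaks.append(SpectralPeak(frequency=float(f), power=float(power[i]), kind=kind))
    return peaks
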
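"""Lookup estimators: the non-fit baseline and fit-start provider.

The layer lookup re-implements the classic SIPchart recipe: brightest value,
half-maximum crossings by linear interpolation, offset from the profile
ends, and the centricity skew ``(b - a) / (a + b)``.  The solution lookup is
plumbing of this package (no published recipe exists); it only has to seed
the nonlinear fit and every constant in it is a keyword argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .models import FOUR_LN2, AxialProfile, LayerParams, layer_model

__all__ = [
    "LookupEstimate",
    "lookup_layer",
    "lookup_solution",
    "SkewCalibration",
    "skew_conversion_factor",
]

#: FWHM of a Gaussian in units of its standard deviation.
_FWHM_PER_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))
#: Interquartile range of a Gaussian in units of its standard deviation.
_IQR_PER_SIGMA = 1.3489795003921634


@dataclass(frozen=True)
class LookupEstimate:
    """Looked-up profile parameters (baseline estimate and fit start).

    ``a`` and ``b`` are the distances from ``z0`` to the left and right
    half-maximum crossings; for the layer lookup ``wFWHM = a + b`` and
    ``skew = (b - a) / (a + b)``.  ``complete`` is False when a required
    feature (e.g. a half-max crossing) could not be located; the fit engine
    then falls back to heuristic start values.
    """

    A: float
    z0: float
    wFWHM: float
    I0: float
    skew: Optional[float] = None
    a: Optional[float] = None
    b: Optional[float] = None
    LC: Optional[float] = None
    ol: Optional[float] = None
    mL: Optional[float] = None
    complete: bool = True
    flags: Tuple[str, ...] = ()


def _interp_crossing(z1, y1, z2, y2, level):
    """z where the chord through (z1, y1)-(z2, y2) crosses ``level``."""
    return z1 + (level - y1) * (z2 - z1) / (y2 - y1)


def lookup_layer(profile: AxialProfile, n_offset_per_side: int = 5) -> LookupEstimate:
    """SIPchart-style lookup on a thin-layer profile.

    The amplitude is the brightest value above the offset, the axial
    position the z of that value (first index on ties), the offset the mean
    of the ten values most distant from ``z0`` (five from each end of the z
    range), and the half-max crossings are located by linear interpolation
    between the outermost point above half maximum and its below-half
    neighbour on each side.
    """
    if len(profile) < 12:
        raise ValueError("layer lookup requires at least 12 points")
    z, I = profile.z, profile.intensity
    flags = []

    k = n_offset_per_side
    I0 = float(np.mean(np.concatenate([I[:k], I[-k:]])))
    imax = int(np.argmax(I))
    if np.count_nonzero(I == I[imax]) > 1:
        flags.append("max_tie")
    A = float(I[imax] - I0)
    z0 = float(z[imax])

    est = _layer_crossings(z, I, I0, A, z0, flags)
    if est.complete:
        # re-derive the offset from points outside +-2*wFWHM when the plain
        # end windows intrude into the peak region
        outside = np.abs(z - z0) > 2.0 * est.wFWHM
        if np.count_nonzero(outside) < 2 * k:
            flags.append("offset_window_adjusted")
            if np.any(outside):
                I0 = float(np.mean(I[outside]))
                A = float(I[imax] - I0)
                est = _layer_crossings(z, I, I0, A, z0, flags)
    return est


def _layer_crossings(z, I, I0, A, z0, flags) -> LookupEstimate:
    half = I0 + A / 2.0
    above = I > half
    idx = np.flatnonzero(above)
    a = b = skew = wFWHM = None
    complete = True
    if idx.size == 0:
        complete = False
        flags = flags + ["no_points_above_half"]
    else:
        il, ir = idx[0], idx[-1]
        if il == 0 or above[il - 1]:
            complete = False
            flags = flags + ["no_left_crossing"]
        if ir == I.size - 1 or above[ir + 1]:
            complete = False
            flags = flags + ["no_right_crossing"]
        if complete:
            zl = _interp_crossing(z[il], I[il], z[il - 1], I[il - 1], half)
            zr = _interp_crossing(z[ir], I[ir], z[ir + 1], I[ir + 1], half)
            a = float(z0 - zl)
            b = float(zr - z0)
            wFWHM = a + b
            skew = (b - a) / (a + b)
    return LookupEstimate(
        A=A,
        z0=z0,
        wFWHM=wFWHM if wFWHM is not None else np.nan,
        I0=I0,
        skew=skew,
        a=a,
        b=b,
        complete=complete,
        flags=tuple(flags),
    )


def _robust_noise(I) -> float:
    """Noise scale from median absolute successive differences."""
    d = np.diff(I)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def lookup_solution(
    profile: AxialProfile,
    decile: float = 0.1,
    deep_region_widths: float = 5.0,
    min_contrast_sigmas: float = 5.0,
) -> LookupEstimate:
    """Heuristic lookup on a solution (interface) profile.

    Plateau and offset are medians of the top and bottom intensity deciles;
    ``z0`` is the first half-rise crossing; the steepness parameter is the
    25%-75% crossing distance converted to an equivalent Gaussian FWHM; the
    length-constant start is the log-slope of the background-subtracted
    signal in the deep region ``z > z0 + deep_region_widths * wFWHM``.
    """
    if len(profile) < 6:
        raise ValueError("solution lookup requires at least 6 points")
    z, I = profile.z, profile.intensity
    noise = _robust_noise(I)
    if I.max() - I.min() <= min_contrast_sigmas * max(noise, 1e-12):
        raise ValueError("no interface: intensity range within the noise floor")

    flags = []
    lo = float(np.median(np.sort(I)[: max(1, int(decile * I.size))]))
    hi = float(np.median(np.sort(I)[-max(1, int(decile * I.size)):]))
    I0, A = lo, hi - lo

    def first_crossing(level):
        above = I >= level
        for i in range(1, I.size):
            if above[i] and not above[i - 1]:
                return _interp_crossing(z[i - 1], I[i - 1], z[i], I[i], level)
        return None

    z50 = first_crossing(I0 + 0.5 * A)
    z25 = first_crossing(I0 + 0.25 * A)
    z75 = first_crossing(I0 + 0.75 * A)
    complete = z50 is not None and z25 is not None and z75 is not None and z75 > z25
    if not complete:
        flags.append("no_rise_crossing")
        return LookupEstimate(
            A=A, z0=np.nan, wFWHM=np.nan, I0=I0, LC=0.0, ol=0.0, mL=0.5,
            complete=False, flags=tuple(flags),
        )
    wFWHM = (z75 - z25) / _IQR_PER_SIGMA * _FWHM_PER_SIGMA

    LC = 0.0
    deep = z > z50 + deep_region_widths * wFWHM
    y = I - I0
    deep &= y > 0
    if np.count_nonzero(deep) >= 3:
        slope = np.polyfit(z[deep], np.log(y[deep]), 1)[0]
        LC = float(-slope)
    else:
        flags.append("no_deep_region")
    return LookupEstimate(
        A=A, z0=float(z50), wFWHM=float(wFWHM), I0=I0,
        LC=LC, ol=0.0, mL=0.5, complete=True, flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# skew conversion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SkewCalibration:
    """Empirical relation between the lookup skew and the skewness factor s.

    ``response_slope`` is d(skew)/ds (about ``-wFWHM / 2`` on the reference
    grid); ``conversion`` is the reciprocal regression used to convert
    lookup skew values into s units, ``s ~= conversion * skew`` (about -2
    for a 1 um FWHM profile).
    """

    conversion: float
    response_slope: float
    s_values: np.ndarray
    skews: np.ndarray


def skew_conversion_factor(
    s_values: Optional[np.ndarray] = None,
    z: Optional[np.ndarray] = None,
    wFWHM: float = 1.0,
) -> SkewCalibration:
    """Calibrate the lookup skew against the generating skewness factor.

    Noise-free skewed Gaussian layer profiles are generated on the
    reference grid (default -10..10 um, 0.2 um spacing), the lookup skew is
    computed for each, and both directions of the linear relation are
    fitted.
    """
    if s_values is None:
        s_values = np.linspace(-0.05, 0.05, 21)
    if z is None:
        z = np.arange(-10.0, 10.0 + 1e-9, 0.2)
    skews = []
    for s in s_values:
        p = LayerParams(I0=0.0, A=1.0, z0=0.0, wFWHM=wFWHM, s=float(s))
        prof = AxialProfile(z, layer_model(p, z, "gauss"))
        est = lookup_layer(prof)
        if not est.complete or est.skew is None:
            raise ValueError(f"lookup incomplete for s={s}")
        skews.append(est.skew)
    skews = np.asarray(skews)
    s_values = np.asarray(s_values, dtype=float)
    response = float(np.polyfit(s_values, skews, 1)[0])
    conversion = float(np.polyfit(skews, s_values, 1)[0])
    return SkewCalibration(conversion, response, s_values, skews)
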
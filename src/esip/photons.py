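"""Photon-counting calibration from Poisson statistics.

A photomultiplier reports intensity ``I = CF * p + I0`` in digital levels
(DL) for ``p`` detected photons.  Because photon detection is Poissonian,
``var(I) / <I - I0> = CF``, so the conversion factor is the slope of the
variance-versus-mean relation.  With the calibration z-stacks used here,
laterally neighbouring pixels within a small bin are statistically
equivalent, so per-bin sample means and variances replace the usual
defocused time series.  Calibration is detector-channel specific: the
result records the channel it was computed for.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy.stats import linregress

__all__ = ["PhotonCalibration", "CalibrationError", "estimate_conversion_factor", "to_photons"]

SATURATION_LEVEL = float(2**16 - 1)


class CalibrationError(ValueError):
    """Raised when the data cannot support a conversion-factor estimate."""


@dataclass(frozen=True)
class PhotonCalibration:
    """Detector conversion factor with fit diagnostics.

    ``CF`` is in DL per detected photon and ``I0_dark`` the dark offset in
    DL.  In free-intercept mode the implied offset ``-c / CF`` absorbs any
    constant read-noise variance (flagged); dark-anchored mode uses the
    measured dark level and subtracts the dark variance instead.
    """

    CF: float
    I0_dark: float
    R2: float
    CF_stderr: float
    n_bins: int
    intensity_range: Tuple[float, float]
    channel: Union[int, str] = 0
    mode: str = "free_intercept"
    flags: Tuple[str, ...] = ()

    def __post_init__(self):
        if not self.CF > 0:
            raise CalibrationError(f"conversion factor must be > 0, got {self.CF}")


def _bin_moments(stack: np.ndarray, bin: int, saturation: float):
    """Per-plane, per-bin sample mean and unbiased variance (+ saturation)."""
    nz, ny, nx = stack.shape
    by, bx = ny // bin, nx // bin
    if by < 1 or bx < 1:
        raise CalibrationError("bin size larger than image")
    s = stack[:, : by * bin, : bx * bin].astype(float)
    tiles = s.reshape(nz, by, bin, bx, bin)
    means = tiles.mean(axis=(2, 4))
    variances = tiles.var(axis=(2, 4), ddof=1)
    sat = (tiles >= saturation).any(axis=(2, 4))
    return means.ravel(), variances.ravel(), sat.ravel()


def estimate_conversion_factor(
    stack: np.ndarray,
    bin: int = 4,
    dark: Optional[Union[float, np.ndarray]] = None,
    channel: Union[int, str] = 0,
    aggregate_bins: Optional[int] = 50,
    saturation: float = SATURATION_LEVEL,
    min_pairs: int = 200,
    upper_percentile: float = 99.5,
    min_range_factor: float = 10.0,
) -> PhotonCalibration:
    """Estimate the DL-per-photon conversion factor from a z-stack.

    For every ``bin x bin`` pixel bin of every z-plane the sample mean and
    unbiased variance are computed; bins containing saturated pixels or
    with mean above the ``upper_percentile`` are excluded.  The surviving
    (mean, variance) pairs are aggregated into ``aggregate_bins``
    equal-count groups (heteroscedasticity control; pass ``None`` for raw
    pairs) and fitted linearly:

    * without a dark reference: ``var = CF * mean + c`` (free intercept),
    * with one: ``var - var_dark = CF * (mean - I0_dark)`` through the
      origin, where ``I0_dark``/``var_dark`` come from the dark frame
      (a scalar dark provides the offset only).

    Raises
    ------
    CalibrationError
        If the intensity dynamic range is below ``min_range_factor`` times
        the noise floor, or too few pairs survive the exclusions.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise CalibrationError("stack must be a 3-D (nz, ny, nx) array")
    means, variances, sat = _bin_moments(stack, bin, saturation)

    keep = ~sat
    cutoff = np.percentile(means[keep], upper_percentile) if keep.any() else np.inf
    keep &= means <= cutoff
    means, variances = means[keep], variances[keep]
    if means.size < min_pairs:
        raise CalibrationError(f"need >= {min_pairs} (mean, var) pairs, got {means.size}")

    # noise floor: spread of the darkest decile of bins
    order = np.argsort(means)
    dark_decile = order[: max(2, means.size // 10)]
    floor = np.sqrt(max(np.median(variances[dark_decile]), 1e-12))
    span = means.max() - means.min()
    if span < min_range_factor * floor:
        raise CalibrationError(
            "insufficient range: intensity dynamic range "
            f"{span:.3g} DL is below {min_range_factor} x noise floor {floor:.3g} DL"
        )

    flags = []
    I0_dark = 0.0
    var_dark = 0.0
    if dark is not None:
        darr = np.asarray(dark, dtype=float)
        if darr.ndim == 0:
            I0_dark = float(darr)
            flags.append("scalar_dark_no_variance")
        else:
            I0_dark = float(darr.mean())
            var_dark = float(darr.var(ddof=1))
        mode = "dark_anchored"
    else:
        mode = "free_intercept"
        flags.append("offset_includes_read_noise")

    x, y = means, variances
    if aggregate_bins is not None and x.size > 2 * aggregate_bins:
        order = np.argsort(x)
        groups = np.array_split(order, aggregate_bins)
        x = np.array([x[g].mean() for g in groups])
        y = np.array([y[g].mean() for g in groups])

    if mode == "free_intercept":
        fit = linregress(x, y)
        cf = float(fit.slope)
        stderr = float(fit.stderr)
        r2 = float(fit.rvalue**2)
        if cf <= 0:
            raise CalibrationError("variance does not increase with mean; no Poisson signal")
        I0_dark = float(-fit.intercept / cf)
    else:
        xs = x - I0_dark
        ys = y - var_dark
        sxx = float(np.sum(xs**2))
        if sxx <= 0:
            raise CalibrationError("degenerate dark-anchored fit")
        cf = float(np.sum(xs * ys) / sxx)
        resid = ys - cf * xs
        stderr = float(np.sqrt(np.sum(resid**2) / max(xs.size - 1, 1) / sxx))
        ss_tot = float(np.sum((ys - ys.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan

    return PhotonCalibration(
        CF=cf,
        I0_dark=I0_dark,
        R2=r2,
        CF_stderr=stderr,
        n_bins=int(means.size),
        intensity_range=(float(means.min()), float(means.max())),
        channel=channel,
        mode=mode,
        flags=tuple(flags),
    )


def to_photons(intensity, cal: PhotonCalibration):
    """Convert digital levels to detected photons, ``p = (I - I0) / CF``.

    Values below the dark offset map to negative photon numbers; they are
    deliberately not clipped (sub-offset noise carries information).
    """
    return (np.asarray(intensity, dtype=float) - cal.I0_dark) / cal.CF
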
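"""Bounded nonlinear least-squares fitting of axial profile models.

``fit_profile`` fits one :class:`~esip.models.AxialProfile`;
``fit_stack`` sweeps a binned z-stack and assembles per-bin parameter maps.

Optimizer: trust-region reflective least squares (scipy), unit weights,
bounds keeping ``wFWHM > 0``, ``mL`` and ``ol`` in [0, 1] and ``A >= 0``.
One restart from a perturbed start (w x1.2, z0 +-0.5 um) is attempted on
non-convergence.  Saturated samples (>= 2^16 - 1 by default) are excluded
from the residual and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
from scipy.optimize import least_squares

from .lookup import LookupEstimate, lookup_layer, lookup_solution
from .models import (
    AxialProfile,
    LayerParams,
    SolutionParams,
    layer_model,
    solution_model_approx,
    solution_model_exact,
)

__all__ = ["FitResult", "ParameterMaps", "fit_profile", "fit_stack", "SATURATION_LEVEL"]

SATURATION_LEVEL = float(2**16 - 1)

Params = Union[LayerParams, SolutionParams]


@dataclass(frozen=True)
class FitResult:
    """Fitted profile parameters with quality metrics."""

    params: Params
    stderr: Dict[str, float]
    R2: float
    converged: bool
    n_iter: int
    start: Optional[LookupEstimate]
    model: str
    shape: str
    variant: str = "approx"
    flags: Tuple[str, ...] = ()
    cost: float = np.nan


# free-parameter order per model; mL appended for pseudo_voigt
_LAYER_FREE = ("I0", "A", "z0", "wFWHM", "s")
_SOLUTION_FREE = ("I0", "A", "z0", "wFWHM", "LC", "ol")


def _free_names(model: str, shape: str, fix: Dict[str, float]) -> Tuple[str, ...]:
    base = _LAYER_FREE if model == "layer" else _SOLUTION_FREE
    names = list(base)
    if shape == "pseudo_voigt":
        names.append("mL")
    return tuple(n for n in names if n not in fix)


def _bounds(name: str, z: np.ndarray) -> Tuple[float, float]:
    span = z[-1] - z[0]
    return {
        "I0": (-np.inf, np.inf),
        "A": (0.0, np.inf),
        "z0": (z[0] - 0.5 * span, z[-1] + 0.5 * span),
        "wFWHM": (1e-6, np.inf),
        "s": (-10.0, 10.0),
        "LC": (-np.inf, np.inf),
        "ol": (0.0, 1.0),
        "mL": (0.0, 1.0),
    }[name]


def _heuristic_start(z, I, model: str) -> Dict[str, float]:
    k = max(3, I.size // 10)
    if model == "layer":
        i0 = float(np.mean(np.concatenate([I[:k], I[-k:]])))
        imax = int(np.argmax(I))
        return {
            "I0": i0,
            "A": max(float(I[imax] - i0), 1e-6),
            "z0": float(z[imax]),
            "wFWHM": (z[-1] - z[0]) / 10.0,
            "s": 0.0,
            "mL": 0.5,
        }
    i0 = float(np.median(np.sort(I)[:k]))
    hi = float(np.median(np.sort(I)[-k:]))
    return {
        "I0": i0,
        "A": max(hi - i0, 1e-6),
        "z0": float(z[np.argmax(I >= (i0 + hi) / 2.0)]),
        "wFWHM": (z[-1] - z[0]) / 20.0,
        "LC": 0.0,
        "ol": 0.0,
        "mL": 0.5,
    }


def _start_dict(start: Optional[LookupEstimate], z, I, model: str) -> Dict[str, float]:
    vals = _heuristic_start(z, I, model)
    if start is not None and start.complete:
        vals["I0"] = start.I0
        vals["A"] = max(start.A, 1e-6)
        vals["z0"] = start.z0
        if np.isfinite(start.wFWHM) and start.wFWHM > 0:
            vals["wFWHM"] = start.wFWHM
        if model == "layer" and start.skew is not None:
            # lookup skew ~= -2 * s on the reference grid (see lookup module)
            vals["s"] = float(np.clip(-0.5 * start.skew, -1.0, 1.0))
        if model == "solution":
            if start.LC is not None:
                vals["LC"] = start.LC
            if start.ol is not None:
                vals["ol"] = start.ol
        if start.mL is not None:
            vals["mL"] = start.mL
    return vals


def fit_profile(
    profile: AxialProfile,
    model: str = "layer",
    shape: str = "gauss",
    start: Optional[LookupEstimate] = None,
    fix: Optional[Dict[str, float]] = None,
    variant: str = "approx",
    flip_z: bool = False,
    saturation: float = SATURATION_LEVEL,
) -> FitResult:
    """Fit one axial profile with the chosen model.

    Parameters
    ----------
    model : {"layer", "solution"}
    shape : {"gauss", "lorentz", "pseudo_voigt"}
    start
        Lookup estimate used as start values; computed internally when
        omitted (falling back to plain heuristics if the lookup fails).
    fix
        Mapping of parameter names to fixed values, e.g. ``{"LC": 0.0}``.
    variant : {"approx", "exact"}
        Solution model flavour; ``"exact"`` uses the closed-form integral
        (Gaussian kernel, shape must be ``"gauss"``).
    flip_z
        Reverse the acquisition direction before fitting (solution stacks
        recorded with intensity falling along +z).

    Raises
    ------
    ValueError
        If fewer valid points than free parameters + 2 remain, or the
        intensities are all equal.
    """
    if model not in ("layer", "solution"):
        raise ValueError(f"unknown model {model!r}")
    if variant not in ("approx", "exact"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "exact" and (model != "solution" or shape != "gauss"):
        raise ValueError("variant='exact' applies to the solution model with shape='gauss'")
    fix = dict(fix or {})
    if model == "solution":
        fix.setdefault("s", 0.0)  # solution profiles are assumed symmetric

    if flip_z:
        profile = profile.flipped()
    keep = np.ones(len(profile), dtype=bool)
    flags = []
    if profile.saturated is not None:
        keep &= ~profile.saturated
    keep &= profile.intensity < saturation
    if not np.all(keep):
        flags.append("saturated_points_excluded")
    z, I = profile.z[keep], profile.intensity[keep]

    min_pts = 8 if model == "layer" else 6
    if z.size < min_pts:
        raise ValueError(f"{model} fit requires at least {min_pts} valid points")
    if np.ptp(I) == 0:
        raise ValueError("fit refused: all intensities are equal")

    free = _free_names(model, shape, fix)
    if z.size < len(free) + 2:
        raise ValueError("fit refused: fewer points than free parameters + 2")

    if start is None:
        try:
            sub = AxialProfile(z, I)
            start = lookup_layer(sub) if model == "layer" else lookup_solution(sub)
        except ValueError:
            start = None
    vals = _start_dict(start, z, I, model)
    vals.update(fix)

    lo = np.array([_bounds(n, z)[0] for n in free])
    hi = np.array([_bounds(n, z)[1] for n in free])

    def make_params(x) -> Params:
        d = dict(vals)
        d.update(dict(zip(free, x)))
        if model == "layer":
            return LayerParams(
                I0=d["I0"], A=d["A"], z0=d["z0"], wFWHM=d["wFWHM"],
                s=d.get("s", 0.0), mL=d.get("mL", 0.0),
            )
        return SolutionParams(
            I0=d["I0"], A=d["A"], z0=d["z0"], wFWHM=d["wFWHM"],
            LC=d.get("LC", 0.0), ol=d.get("ol", 0.0), mL=d.get("mL", 0.0),
        )

    def evaluate(p: Params):
        if model == "layer":
            return layer_model(p, z, shape)
        if variant == "exact":
            return solution_model_exact(p, z)
        return solution_model_approx(p, z, shape)

    def resid(x):
        return evaluate(make_params(x)) - I

    x0 = np.clip(np.array([vals[n] for n in free], dtype=float), lo, hi)
    max_nfev = 400 * len(free)

    def solve(x_init):
        return least_squares(
            resid, x_init, bounds=(lo, hi), method="trf",
            ftol=1e-10, xtol=1e-8, max_nfev=max_nfev,
        )

    res = solve(x0)
    converged = res.status > 0
    if not converged:
        # one restart from a perturbed start
        x1 = x0.copy()
        d = dict(zip(free, x1))
        if "wFWHM" in d:
            d["wFWHM"] *= 1.2
        if "z0" in d:
            shift = 0.5 if d["z0"] + 0.5 <= hi[free.index("z0")] else -0.5
            d["z0"] += shift
        x1 = np.clip(np.array([d[n] for n in free]), lo, hi)
        res2 = solve(x1)
        if res2.status > 0 or res2.cost < res.cost:
            res = res2
            converged = res2.status > 0
        flags.append("restarted")

    params = make_params(res.x)
    if model == "solution" and params.LC < 0:
        flags.append("negative_LC")

    fitted = evaluate(params)
    ss_res = float(np.sum((I - fitted) ** 2))
    ss_tot = float(np.sum((I - I.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    stderr = {n: np.nan for n in free}
    dof = z.size - len(free)
    if dof > 0:
        try:
            jtj = res.jac.T @ res.jac
            cov = np.linalg.pinv(jtj) * (ss_res / dof)
            for n, v in zip(free, np.sqrt(np.maximum(np.diag(cov), 0.0))):
                stderr[n] = float(v)
        except np.linalg.LinAlgError:
            flags.append("covariance_failed")

    return FitResult(
        params=params,
        stderr=stderr,
        R2=r2,
        converged=converged,
        n_iter=int(res.nfev),
        start=start,
        model=model,
        shape=shape,
        variant=variant,
        flags=tuple(flags),
        cost=float(res.cost),
    )


# ---------------------------------------------------------------------------
# stack sweep
# ---------------------------------------------------------------------------


@dataclass
class ParameterMaps:
    """Per-bin parameter grids from a z-stack sweep.

    ``params`` maps parameter names to ``(ny_bins, nx_bins)`` float arrays
    (NaN where a bin's fit was refused); ``bin_centers`` holds the pixel
    coordinates of the bin centres (y then x).
    """

    bin: int
    params: Dict[str, np.ndarray]
    r2: np.ndarray
    converged: np.ndarray
    bin_centers: Tuple[np.ndarray, np.ndarray]
    model: str
    shape: str
    flags: Tuple[str, ...] = ()

    @property
    def grid_shape(self) -> Tuple[int, int]:
        return self.r2.shape


def bin_stack(stack: np.ndarray, bin: int) -> np.ndarray:
    """Mean-bin a (nz, ny, nx) stack laterally; trailing pixels dropped."""
    nz, ny, nx = stack.shape
    by, bx = ny // bin, nx // bin
    if by < 1 or bx < 1:
        raise ValueError("bin size larger than image")
    s = stack[:, : by * bin, : bx * bin].astype(float)
    return s.reshape(nz, by, bin, bx, bin).mean(axis=(2, 4))


def fit_stack(
    stack: np.ndarray,
    z: np.ndarray,
    model: str = "layer",
    shape: str = "gauss",
    bin: int = 4,
    photon_cal=None,
    fix: Optional[Dict[str, float]] = None,
    variant: str = "approx",
    flip_z: bool = False,
    saturation: float = SATURATION_LEVEL,
) -> ParameterMaps:
    """Fit every ``bin x bin`` pixel bin of a z-stack.

    Each bin's profile is the mean intensity over the bin per z-plane (so
    amplitudes stay in per-pixel DL).  A binned z-sample is flagged
    saturated when any contributing pixel reaches the saturation level.
    When a :class:`~esip.photons.PhotonCalibration` is supplied, an
    additional ``A_photons`` map converts the amplitude to detected
    photons per pixel.
    """
    stack = np.asarray(stack)
    z = np.asarray(z, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be a 3-D (nz, ny, nx) array")
    if z.ndim != 1 or z.size != stack.shape[0]:
        raise ValueError("z metadata missing or inconsistent with the stack")

    binned = bin_stack(stack, bin)
    nz, by, bx = binned.shape
    sat = bin_stack((stack >= saturation).astype(float), bin) > 0

    names = list(_free_names(model, shape, dict(fix or {})))
    maps: Dict[str, np.ndarray] = {n: np.full((by, bx), np.nan) for n in names}
    r2 = np.full((by, bx), np.nan)
    conv = np.zeros((by, bx), dtype=bool)
    flags = []

    order = np.argsort(z)
    zs = z[order]
    for iy in range(by):
        for ix in range(bx):
            prof = AxialProfile(zs, binned[order, iy, ix], sat[order, iy, ix])
            try:
                fr = fit_profile(
                    prof, model=model, shape=shape, fix=fix,
                    variant=variant, flip_z=flip_z, saturation=saturation,
                )
            except ValueError:
                continue
            for n in names:
                maps[n][iy, ix] = getattr(fr.params, n)
            r2[iy, ix] = fr.R2
            conv[iy, ix] = fr.converged

    if conv.mean() < 0.5:
        warnings.warn("fewer than 50% of bins converged", RuntimeWarning)
        flags.append("low_convergence")

    if photon_cal is not None and "A" in maps:
        maps["A_photons"] = maps["A"] / photon_cal.CF

    yc = (np.arange(by) + 0.5) * bin - 0.5
    xc = (np.arange(bx) + 0.5) * bin - 0.5
    return ParameterMaps(
        bin=bin, params=maps, r2=r2, converged=conv,
        bin_centers=(yc, xc), model=model, shape=shape, flags=tuple(flags),
    )
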
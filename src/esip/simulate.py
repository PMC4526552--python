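"""Synthetic calibration data: toy profiles, field-varying z-stacks, grids.

The toy protocol emulates the reference simulation-study conditions: axial
profiles are evaluated in expected-photon units, Poisson photon noise is
scaled by the conversion factor, a constant digital offset and Gaussian
read noise are added, and the interface/peak position is jittered within
half a z step per replicate so profile features never coincide permanently
with the sampling grid.

Defaults (the study conditions):

* layer z grid -10..+10 um, 0.2 um spacing; solution grid -5..+5 um at
  0.1 um, 6..50 um at 1 um, 55..200 um at 5 um;
* FWHM 1 um, z0 = 0, offset 500 DL, conversion factor 500 DL/photon;
* layer skewness s = -0.025 / um, solution length constant LC = 0;
* read noise 0.5 photon-equivalents (250 DL) - the reference protocol
  names the detector but not the magnitude, so a conservative sub-photon
  value is used and exposed in the config;
* 500 replicates per peak-photon level, levels 1..1000.

All generators are pure functions of (config, seed): identical seeds
reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .models import (
    FOUR_LN2,
    AxialProfile,
    LayerParams,
    SolutionParams,
    layer_model,
    solution_model_exact,
)

__all__ = [
    "ToyDataConfig",
    "GridTruth",
    "layer_z_grid",
    "solution_z_grid",
    "generate_toy_profile",
    "generate_toy_ensemble",
    "generate_synthetic_stack",
    "generate_grid_image",
]

DEFAULT_LEVELS = (1, 2, 5, 10, 20, 50, 100, 200, 500, 1000)


def layer_z_grid() -> np.ndarray:
    """Reference layer grid: -10..+10 um, 0.2 um spacing (101 points)."""
    return np.round(np.arange(-10.0, 10.0 + 1e-9, 0.2), 10)


def solution_z_grid() -> np.ndarray:
    """Reference solution grid: 0.1 um / 1 um / 5 um piecewise spacing."""
    return np.concatenate(
        [
            np.round(np.arange(-5.0, 5.0 + 1e-9, 0.1), 10),
            np.arange(6.0, 50.0 + 1e-9, 1.0),
            np.arange(55.0, 200.0 + 1e-9, 5.0),
        ]
    )


@dataclass(frozen=True)
class ToyDataConfig:
    """Configuration of the toy-profile Monte-Carlo protocol."""

    kind: str = "layer"
    z: Optional[np.ndarray] = None
    wFWHM: float = 1.0
    z0: float = 0.0
    s: float = -0.025
    LC: float = 0.0
    ol: float = 0.0
    I0_dl: float = 500.0
    cf: float = 500.0
    read_sigma_dl: float = 250.0
    levels: Tuple[float, ...] = DEFAULT_LEVELS
    n_reps: int = 500
    seed: int = 0
    jitter: bool = True

    def __post_init__(self):
        if self.kind not in ("layer", "solution"):
            raise ValueError(f"kind must be 'layer' or 'solution', got {self.kind!r}")
        z = self.z if self.z is not None else (
            layer_z_grid() if self.kind == "layer" else solution_z_grid()
        )
        z = np.asarray(z, dtype=float)
        if not np.all(np.diff(z) > 0):
            raise ValueError("z grid must be strictly increasing")
        object.__setattr__(self, "z", z)
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not self.cf > 0:
            raise ValueError("cf must be > 0")

    def replace(self, **kw) -> "ToyDataConfig":
        return replace(self, **kw)


def _local_half_step(z: np.ndarray, z0: float) -> float:
    i = int(np.clip(np.searchsorted(z, z0), 1, z.size - 1))
    return 0.5 * (z[i] - z[i - 1])


def _expected_photons(cfg: ToyDataConfig, peak_photons: float, z0: float) -> np.ndarray:
    if cfg.kind == "layer":
        p = LayerParams(I0=0.0, A=peak_photons, z0=z0, wFWHM=cfg.wFWHM, s=cfg.s)
        lam = layer_model(p, cfg.z, "gauss")
    else:
        p = SolutionParams(
            I0=0.0, A=peak_photons, z0=z0, wFWHM=cfg.wFWHM, LC=cfg.LC, ol=cfg.ol
        )
        lam = solution_model_exact(p, cfg.z)
    # the noise-free expectation is non-negative by construction
    assert np.all(lam >= -1e-9), "negative expected photon count"
    return np.clip(lam, 0.0, None)


def generate_toy_profile(
    cfg: ToyDataConfig,
    peak_photons: float,
    rng: np.random.Generator,
):
    """One noisy toy profile.

    Returns ``(profile, truth)`` where ``truth`` carries the per-replicate
    ground-truth parameters in digital levels (``A = cf * peak_photons``,
    jittered ``z0``).
    """
    dz0 = 0.0
    if cfg.jitter:
        h = _local_half_step(cfg.z, cfg.z0)
        dz0 = float(rng.uniform(-h, h))
    z0 = cfg.z0 + dz0
    lam = _expected_photons(cfg, peak_photons, z0)
    I = (
        cfg.cf * rng.poisson(lam)
        + cfg.I0_dl
        + rng.normal(0.0, cfg.read_sigma_dl, size=lam.size)
    )
    profile = AxialProfile(cfg.z, I)
    if cfg.kind == "layer":
        truth = LayerParams(
            I0=cfg.I0_dl, A=cfg.cf * peak_photons, z0=z0, wFWHM=cfg.wFWHM, s=cfg.s
        )
    else:
        truth = SolutionParams(
            I0=cfg.I0_dl, A=cfg.cf * peak_photons, z0=z0, wFWHM=cfg.wFWHM,
            LC=cfg.LC, ol=cfg.ol,
        )
    return profile, truth


def generate_toy_ensemble(cfg: ToyDataConfig) -> Dict[float, List[tuple]]:
    """Replicate collections per peak-photon level, keyed by level."""
    rng = np.random.default_rng(cfg.seed)
    out: Dict[float, List[tuple]] = {}
    for level in cfg.levels:
        out[level] = [generate_toy_profile(cfg, level, rng) for _ in range(cfg.n_reps)]
    return out


# ---------------------------------------------------------------------------
# field-varying z-stacks
# ---------------------------------------------------------------------------


def _layer_expectation_maps(z_k, A, z0, w, s):
    dz = z_k - z0
    u = dz * np.exp(s * dz)
    return A * np.exp(-FOUR_LN2 * (u / w) ** 2)


def _solution_expectation_maps(z_k, A, z0, w, LC, ol):
    from .models import gauss_interface_unit

    return A * gauss_interface_unit(z_k - z0, w, LC, ol)


def generate_synthetic_stack(
    maps: Dict[str, np.ndarray],
    z: np.ndarray,
    kind: str = "layer",
    cf: float = 500.0,
    I0_dl: float = 500.0,
    read_sigma_dl: float = 250.0,
    rng: Optional[np.random.Generator] = None,
    noise: bool = True,
) -> np.ndarray:
    """Render a (nz, ny, nx) uint16 stack from per-pixel truth maps.

    ``maps`` holds 2-D truth fields (all the same shape): ``A_photons``
    (peak/plateau expected photons) and any of ``z0``, ``wFWHM``, ``s``
    (layer) or ``LC``, ``ol`` (solution); missing fields default to the
    toy-protocol values.  Per pixel the model expectation is evaluated and
    the toy noise model applied.
    """
    if kind not in ("layer", "solution"):
        raise ValueError(f"kind must be 'layer' or 'solution', got {kind!r}")
    shapes = {np.asarray(m).shape for m in maps.values()}
    if len(shapes) != 1:
        raise ValueError("all truth maps must share one shape")
    (ny, nx) = shapes.pop()
    z = np.asarray(z, dtype=float)
    rng = rng or np.random.default_rng(0)

    A = np.asarray(maps.get("A_photons", np.full((ny, nx), 100.0)), dtype=float)
    z0 = np.asarray(maps.get("z0", np.zeros((ny, nx))), dtype=float)
    w = np.asarray(maps.get("wFWHM", np.ones((ny, nx))), dtype=float)
    out = np.empty((z.size, ny, nx))
    for k, zk in enumerate(z):
        if kind == "layer":
            s = np.asarray(maps.get("s", np.zeros((ny, nx))), dtype=float)
            lam = _layer_expectation_maps(zk, A, z0, w, s)
        else:
            LC = np.asarray(maps.get("LC", np.zeros((ny, nx))), dtype=float)
            ol = np.asarray(maps.get("ol", np.zeros((ny, nx))), dtype=float)
            lam = _solution_expectation_maps(zk, A, z0, w, LC, ol)
        lam = np.clip(lam, 0.0, None)
        if noise:
            plane = cf * rng.poisson(lam) + I0_dl + rng.normal(0.0, read_sigma_dl, lam.shape)
        else:
            plane = cf * lam + I0_dl
        out[k] = plane
    return np.clip(np.round(out), 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# grid targets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridTruth:
    """Ground truth of a rendered two-family line grid.

    The grid is a square lattice of Gaussian-cross-section lines spaced
    ``period`` um apart.  Geometric distortions:

    * ``c2_vertical`` / ``c2_horizontal`` (1/um): uniform second-order line
      bending - a vertical line at nominal x is displaced by
      ``c2_vertical * yc**2`` (centred field coordinate yc), etc.;
    * ``barrel`` (1/um^2): radial cubic field distortion displacing
      ``(x, y)`` by ``barrel * r^2 * (xc, yc)``, which makes the per-line
      quadratic term grow toward the field edges;
    * ``channel_offsets``: per-channel constant lateral shift (um) or a
      callable ``(xc, yc) -> (dx, dy)`` for radial chromatic-shift fields.
    """

    period: float = 6.0
    line_width: float = 1.2
    pixel_size: float = 0.6
    shape: Tuple[int, int] = (256, 256)
    c2_vertical: float = 0.0
    c2_horizontal: float = 0.0
    barrel: float = 0.0
    channel_offsets: Dict[int, object] = field(default_factory=dict)
    amplitude: float = 2000.0
    background: float = 100.0

    def __post_init__(self):
        if not (self.period > self.line_width > 0):
            raise ValueError("need period > line_width > 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel size must be > 0")

    def field_center(self) -> Tuple[float, float]:
        ny, nx = self.shape
        return ((nx - 1) * self.pixel_size / 2.0, (ny - 1) * self.pixel_size / 2.0)

    def _offset(self, channel: int, xc, yc):
        off = self.channel_offsets.get(channel, (0.0, 0.0))
        if callable(off):
            return off(xc, yc)
        return off

    def _displacement(self, xc, yc, channel: int):
        """Feature displacement (du, dv) at centred coords.

        A grid feature nominally at centred position ``(xc, yc)`` appears
        displaced by this amount in the image, so injected coefficients are
        recovered with their own sign by the grid analysis.
        """
        r2 = xc**2 + yc**2
        dx, dy = self._offset(channel, xc, yc)
        du = self.c2_vertical * yc**2 + self.barrel * r2 * xc + dx
        dv = self.c2_horizontal * xc**2 + self.barrel * r2 * yc + dy
        return du, dv

    def crossing_positions(self, channel: int = 0, margin: float = 0.0) -> np.ndarray:
        """Image-space (x, y) um positions of the distorted lattice crossings.

        Solved by fixed-point iteration of ``p = L + disp(p)`` for each
        undistorted lattice node ``L`` inside the field.
        """
        cx, cy = self.field_center()
        ny, nx = self.shape
        wx, wy = (nx - 1) * self.pixel_size, (ny - 1) * self.pixel_size
        ks = np.arange(np.ceil((margin - cx) / self.period), (wx - margin - cx) / self.period + 1e-9)
        ms = np.arange(np.ceil((margin - cy) / self.period), (wy - margin - cy) / self.period + 1e-9)
        pts = []
        for kx in ks:
            for my in ms:
                lx, ly = kx * self.period, my * self.period  # centred lattice node
                x, y = lx, ly
                for _ in range(30):
                    du, dv = self._displacement(x, y, channel)
                    xn, yn = lx + du, ly + dv
                    if abs(xn - x) < 1e-10 and abs(yn - y) < 1e-10:
                        x, y = xn, yn
                        break
                    x, y = xn, yn
                px, py = x + cx, y + cy
                if margin <= px <= wx - margin and margin <= py <= wy - margin:
                    pts.append((px, py))
        return np.asarray(pts)


def generate_grid_image(
    truth: GridTruth,
    channel: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render one channel of the distorted grid as a uint16 image.

    Pixel values are point samples of the continuous grid (no area
    integration), so sampling with a pixel pitch near the line period
    reproduces Moire beating.  Poisson noise is applied when ``rng`` is
    given.
    """
    ny, nx = truth.shape
    cx, cy = truth.field_center()
    x = np.arange(nx) * truth.pixel_size - cx
    y = np.arange(ny) * truth.pixel_size - cy
    X, Y = np.meshgrid(x, y)
    du, dv = truth._displacement(X, Y, channel)
    U, V = X - du, Y - dv
    sigma = truth.line_width / np.sqrt(8.0 * np.log(2.0))

    def comb(c):
        d = np.mod(c + truth.period / 2.0, truth.period) - truth.period / 2.0
        return np.exp(-0.5 * (d / sigma) ** 2)

    img = truth.background + truth.amplitude * np.clip(comb(U) + comb(V), 0.0, 1.0)
    if rng is not None:
        img = rng.poisson(img).astype(float)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)
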
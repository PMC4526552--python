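"""Chart assembly, the lookup-vs-fit simulation study, and tuning series.

An eSIP chart bundles, for one calibration stack: the per-bin parameter
maps, the photon calibration, five representative axial profiles with
their fits (field centre plus four positions inset 10% from the corners),
and summary statistics per parameter.  Charts serialise to a versioned
JSON schema and per-parameter map images.

The simulation study runs the lookup and fit estimators over the toy
ensemble and tabulates accuracy (mean - truth) and precision (STD) per
parameter and photon level.  Tuning series reduce a sequence of charts
taken at different instrument settings (correction collar, collimator) to
optimum settings by amplitude, axial resolution, or the axial-position
difference between two excitation channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .fitting import FitResult, ParameterMaps, fit_profile, fit_stack
from .lookup import lookup_layer, lookup_solution, skew_conversion_factor
from .models import AxialProfile
from .photons import CalibrationError, PhotonCalibration, estimate_conversion_factor
from .simulate import ToyDataConfig, generate_toy_profile

__all__ = [
    "CHART_SCHEMA_VERSION",
    "ESIPChart",
    "SimStudyReport",
    "TuningSeries",
    "build_chart",
    "run_simulation_study",
    "skew_precision_threshold",
    "analyze_tuning_series",
]

CHART_SCHEMA_VERSION = 1


@dataclass
class ESIPChart:
    """Per-bin calibration chart of one stack (maps + photon calibration)."""

    maps: ParameterMaps
    calibration: Optional[PhotonCalibration]
    profiles: List[Dict]
    metadata: Dict
    summary: Dict[str, Tuple[float, float]]
    schema_version: int = CHART_SCHEMA_VERSION

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> Dict:
        m = self.maps
        return {
            "schema_version": self.schema_version,
            "maps": {
                "bin": m.bin,
                "model": m.model,
                "shape": m.shape,
                "params": {k: v.tolist() for k, v in m.params.items()},
                "r2": m.r2.tolist(),
                "converged": m.converged.tolist(),
                "bin_centers": [m.bin_centers[0].tolist(), m.bin_centers[1].tolist()],
                "flags": list(m.flags),
            },
            "calibration": None
            if self.calibration is None
            else {
                "CF": self.calibration.CF,
                "I0_dark": self.calibration.I0_dark,
                "R2": self.calibration.R2,
                "CF_stderr": self.calibration.CF_stderr,
                "n_bins": self.calibration.n_bins,
                "intensity_range": list(self.calibration.intensity_range),
                "channel": self.calibration.channel,
                "mode": self.calibration.mode,
                "flags": list(self.calibration.flags),
            },
            "profiles": self.profiles,
            "metadata": self.metadata,
            "summary": {k: list(v) for k, v in self.summary.items()},
        }

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: Dict) -> "ESIPChart":
        md = d["maps"]
        maps = ParameterMaps(
            bin=md["bin"],
            params={k: np.asarray(v, dtype=float) for k, v in md["params"].items()},
            r2=np.asarray(md["r2"], dtype=float),
            converged=np.asarray(md["converged"], dtype=bool),
            bin_centers=(
                np.asarray(md["bin_centers"][0], dtype=float),
                np.asarray(md["bin_centers"][1], dtype=float),
            ),
            model=md["model"],
            shape=md["shape"],
            flags=tuple(md.get("flags", ())),
        )
        cd = d.get("calibration")
        cal = None
        if cd is not None:
            cal = PhotonCalibration(
                CF=cd["CF"], I0_dark=cd["I0_dark"], R2=cd["R2"],
                CF_stderr=cd["CF_stderr"], n_bins=cd["n_bins"],
                intensity_range=tuple(cd["intensity_range"]),
                channel=cd["channel"], mode=cd["mode"], flags=tuple(cd["flags"]),
            )
        return cls(
            maps=maps,
            calibration=cal,
            profiles=d.get("profiles", []),
            metadata=d.get("metadata", {}),
            summary={k: tuple(v) for k, v in d.get("summary", {}).items()},
            schema_version=d.get("schema_version", CHART_SCHEMA_VERSION),
        )

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "ESIPChart":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))

    def save_maps(self, outdir: Union[str, Path]) -> List[Path]:
        """Write one PNG per parameter map (and a CSV per map)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, arr in {**self.maps.params, "R2": self.maps.r2}.items():
            fig, ax = plt.subplots(figsize=(4, 3.2))
            im = ax.imshow(arr, origin="lower", cmap="viridis")
            ax.set_title(name)
            fig.colorbar(im, ax=ax, shrink=0.85)
            p = outdir / f"map_{name}.png"
            fig.savefig(p, dpi=120, bbox_inches="tight")
            plt.close(fig)
            np.savetxt(outdir / f"map_{name}.csv", arr, delimiter=",")
            written.append(p)
        return written


def _representative_positions(by: int, bx: int) -> List[Tuple[int, int]]:
    """Centre plus four positions inset 10% from the map corners."""
    iy, ix = max(int(round(0.1 * by)), 0), max(int(round(0.1 * bx)), 0)
    pos = [
        (by // 2, bx // 2),
        (iy, ix),
        (iy, bx - 1 - ix),
        (by - 1 - iy, ix),
        (by - 1 - iy, bx - 1 - ix),
    ]
    seen, out = set(), []
    for p in pos:
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out


def build_chart(
    stack: np.ndarray,
    z: np.ndarray,
    model: str = "layer",
    shape: str = "gauss",
    bin: int = 4,
    dark=None,
    channel: Union[int, str] = 0,
    variant: str = "approx",
    fix: Optional[Dict[str, float]] = None,
    metadata: Optional[Dict] = None,
    percentile_pmax: float = 99.9,
) -> ESIPChart:
    """Assemble a full calibration chart from one z-stack.

    Runs the photon calibration (variance-over-mean) and the per-bin model
    fits, converts the amplitude map to photons and to percent of the
    maximal photon number (robust 99.9th percentile), extracts the five
    representative profiles, and summarises every parameter as mean +- STD
    over the converged bins.  A failed photon calibration downgrades the
    chart (amplitude stays in DL) instead of failing it.
    """
    stack = np.asarray(stack)
    notes = []
    try:
        cal = estimate_conversion_factor(stack, bin=bin, dark=dark, channel=channel)
    except CalibrationError as e:
        cal = None
        notes.append(f"photon calibration unavailable: {e}")

    maps = fit_stack(
        stack, z, model=model, shape=shape, bin=bin,
        photon_cal=cal, fix=fix, variant=variant,
    )
    if cal is not None and "A_photons" in maps.params:
        ap = maps.params["A_photons"]
        finite = ap[np.isfinite(ap)]
        if finite.size:
            pmax = np.percentile(finite, percentile_pmax)
            if pmax > 0:
                maps.params["A_percent_pmax"] = 100.0 * ap / pmax

    by, bx = maps.grid_shape
    binned = stack[:, : by * bin, : bx * bin].astype(float)
    binned = binned.reshape(stack.shape[0], by, bin, bx, bin).mean(axis=(2, 4))
    order = np.argsort(np.asarray(z, dtype=float))
    zs = np.asarray(z, dtype=float)[order]
    profiles = []
    for iy, ix in _representative_positions(by, bx):
        prof = AxialProfile(zs, binned[order, iy, ix])
        entry = {
            "bin_yx": [int(iy), int(ix)],
            "z": zs.tolist(),
            "intensity": prof.intensity.tolist(),
        }
        try:
            fr = fit_profile(prof, model=model, shape=shape, fix=fix, variant=variant)
            entry["fit"] = {
                "params": {k: float(v) for k, v in vars(fr.params).items()},
                "R2": fr.R2,
                "converged": fr.converged,
            }
        except ValueError as e:
            entry["fit"] = {"error": str(e)}
        profiles.append(entry)

    summary = {}
    conv = maps.converged
    for name, arr in maps.params.items():
        vals = arr[conv & np.isfinite(arr)]
        if vals.size:
            summary[name] = (float(vals.mean()), float(vals.std(ddof=1) if vals.size > 1 else 0.0))

    meta = dict(metadata or {})
    meta.setdefault("channel", channel)
    meta["notes"] = notes
    return ESIPChart(maps=maps, calibration=cal, profiles=profiles,
                     metadata=meta, summary=summary)


# ---------------------------------------------------------------------------
# simulation study (lookup vs fit)
# ---------------------------------------------------------------------------


@dataclass
class SimStudyReport:
    """Accuracy/precision table of the toy-data Monte-Carlo study.

    ``table`` rows: estimator x parameter x level with mean, STD, accuracy
    (mean - truth; for z0 the per-replicate jittered truth is subtracted
    first) and relative STD (STD / |mean|).  ``skew_conversion`` is the
    empirical factor converting lookup skew values into skewness units.
    """

    table: pd.DataFrame
    config: ToyDataConfig
    truth: Dict[str, float]
    skew_conversion: float

    def to_csv(self, path: Union[str, Path]) -> None:
        self.table.to_csv(path, index=False)

    def select(self, estimator: str, parameter: str) -> pd.DataFrame:
        t = self.table
        return t[(t.estimator == estimator) & (t.parameter == parameter)].sort_values("level")


def run_simulation_study(
    cfg: ToyDataConfig,
    estimators: Sequence[str] = ("lookup", "fit"),
    shape: str = "gauss",
) -> SimStudyReport:
    """Run the lookup-vs-fit accuracy/precision study on toy profiles.

    Layer profiles are fitted with the skewed Gaussian layer model;
    solution profiles with the exact Gaussian-kernel interface model with
    the length constant and exponential offset fixed at their generation
    values (the reference protocol does not fit them).  Lookup skew values
    are additionally reported converted to skewness units through the
    empirical conversion factor.
    """
    rng = np.random.default_rng(cfg.seed)
    conv = skew_conversion_factor().conversion
    if cfg.kind == "layer":
        truth = {"A": np.nan, "wFWHM": cfg.wFWHM, "s": cfg.s,
                 "I0": cfg.I0_dl, "z0": 0.0}
        fix = None
        variant, model = "approx", "layer"
    else:
        truth = {"A": np.nan, "wFWHM": cfg.wFWHM, "I0": cfg.I0_dl, "z0": 0.0,
                 "LC": cfg.LC, "ol": cfg.ol}
        fix = {"LC": cfg.LC, "ol": cfg.ol}
        variant, model = "exact", "solution"

    rows = []
    for level in cfg.levels:
        a_truth = cfg.cf * level
        samples: Dict[Tuple[str, str], List[float]] = {}
        n_ok = {e: 0 for e in estimators}
        for _ in range(cfg.n_reps):
            prof, tru = generate_toy_profile(cfg, level, rng)
            if "lookup" in estimators:
                try:
                    est = lookup_layer(prof) if cfg.kind == "layer" else lookup_solution(prof)
                    if est.complete:
                        n_ok["lookup"] += 1
                        samples.setdefault(("lookup", "A"), []).append(est.A)
                        samples.setdefault(("lookup", "wFWHM"), []).append(est.wFWHM)
                        samples.setdefault(("lookup", "I0"), []).append(est.I0)
                        samples.setdefault(("lookup", "z0_err"), []).append(est.z0 - tru.z0)
                        if est.skew is not None:
                            samples.setdefault(("lookup", "skew"), []).append(est.skew)
                            samples.setdefault(("lookup", "s_from_skew"), []).append(
                                conv * est.skew
                            )
                except ValueError:
                    pass
            if "fit" in estimators:
                try:
                    # toy intensities are synthetic DL values, not limited by
                    # a 16-bit detector: no saturation exclusion
                    fr = fit_profile(prof, model=model, shape=shape, fix=fix,
                                     variant=variant, saturation=np.inf)
                except ValueError:
                    continue
                if not fr.converged:
                    continue
                n_ok["fit"] += 1
                p = fr.params
                samples.setdefault(("fit", "A"), []).append(p.A)
                samples.setdefault(("fit", "wFWHM"), []).append(p.wFWHM)
                samples.setdefault(("fit", "I0"), []).append(p.I0)
                samples.setdefault(("fit", "z0_err"), []).append(p.z0 - tru.z0)
                if cfg.kind == "layer":
                    samples.setdefault(("fit", "s"), []).append(p.s)

        for (estimator, parameter), vals in samples.items():
            v = np.asarray(vals, dtype=float)
            mean, std = float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0
            if parameter == "z0_err":
                t = 0.0
            elif parameter == "A":
                t = a_truth
            elif parameter in ("s", "s_from_skew"):
                t = cfg.s
            else:
                t = truth.get(parameter, np.nan)
            rows.append(
                {
                    "estimator": estimator,
                    "parameter": parameter,
                    "level": level,
                    "n": int(v.size),
                    "mean": mean,
                    "std": std,
                    "accuracy": mean - t if np.isfinite(t) else np.nan,
                    "rel_std": std / abs(mean) if mean != 0 else np.inf,
                }
            )
    table = pd.DataFrame(rows)
    truth["skew_conversion"] = conv
    return SimStudyReport(table=table, config=cfg, truth=truth, skew_conversion=conv)


def skew_precision_threshold(report: SimStudyReport, target: float = 1.0) -> float:
    """Peak photon count at which the fitted-skew relative STD reaches
    ``target`` (1.0 = 100%).

    The relative STD of the fitted skewness decays as a power law in the
    peak photon number, so the threshold is located by regressing
    ``log(rel_std)`` on ``log(level)`` and solving for the target.  Levels
    whose mean skewness estimate is not significantly different from zero
    (within two standard errors) are excluded: there the relative STD is
    dominated by the vanishing denominator, not by the power-law decay.
    Returns NaN when the scatter does not decrease with photon number.
    """
    s = report.select("fit", "s")
    lv = s["level"].to_numpy(dtype=float)
    rs = s["rel_std"].to_numpy(dtype=float)
    mean = s["mean"].to_numpy(dtype=float)
    std = s["std"].to_numpy(dtype=float)
    n = s["n"].to_numpy(dtype=float)
    ok = (
        np.isfinite(rs)
        & (rs > 0)
        & (np.abs(mean) > 2.0 * std / np.sqrt(np.maximum(n, 1.0)))
    )
    if ok.sum() < 3:
        return float("nan")
    b, a = np.polyfit(np.log(lv[ok]), np.log(rs[ok]), 1)
    if b >= 0:
        return float("nan")
    return float(np.exp((np.log(target) - a) / b))


# ---------------------------------------------------------------------------
# instrument-tuning series
# ---------------------------------------------------------------------------


@dataclass
class TuningSeries:
    """Reduction of a chart series over an instrument-setting axis."""

    settings: np.ndarray
    summaries: pd.DataFrame
    optima: Dict[str, float]
    boundary: Dict[str, bool]
    warnings: Tuple[str, ...] = ()


def _center_mean(maps: ParameterMaps, name: str, center_fraction: float) -> float:
    arr = maps.params[name]
    by, bx = arr.shape
    hy = max(int(round(by * center_fraction / 2)), 1)
    hx = max(int(round(bx * center_fraction / 2)), 1)
    sl = (slice(by // 2 - hy, by // 2 + hy + 1), slice(bx // 2 - hx, bx // 2 + hx + 1))
    sub = arr[sl]
    conv = maps.converged[sl]
    vals = sub[conv & np.isfinite(sub)]
    return float(vals.mean()) if vals.size else np.nan


def _parabola_vertex(x: np.ndarray, y: np.ndarray, best: int, maximize: bool):
    """3-point parabolic interpolation around the best sample."""
    if best in (0, x.size - 1):
        return float(x[best]), True
    xs, ys = x[best - 1 : best + 2], y[best - 1 : best + 2]
    c = np.polyfit(xs, ys, 2)
    if c[0] == 0 or (maximize and c[0] > 0) or (not maximize and c[0] < 0):
        return float(x[best]), False
    return float(-c[1] / (2 * c[0])), False


def analyze_tuning_series(
    series: Sequence[Tuple],
    center_fraction: float = 0.33,
    amplitude_key: str = "A",
) -> TuningSeries:
    """Find optimum instrument settings from a series of charts.

    ``series`` is a list of ``(setting, chart)`` entries, or
    ``(setting, chart_a, chart_b)`` for a two-excitation comparison (then
    the axial-position difference ``dz0 = z0_a - z0_b`` is analysed too).
    Per setting the centre-region means of the amplitude and axial
    resolution are computed; optima are located by 3-point parabolic
    interpolation around the best sample (amplitude: maximum; axial
    resolution: minimum) and, for ``dz0``, by the sign-change root when the
    difference crosses zero.  A boundary optimum raises an
    "extend series" warning.
    """
    if len(series) < 3:
        raise ValueError("a tuning series needs at least 3 settings")
    entries = []
    for item in series:
        setting = float(item[0])
        charts = item[1:] if len(item) > 2 else (item[1],)
        if len(charts) == 1 and isinstance(charts[0], (tuple, list)):
            charts = tuple(charts[0])
        entries.append((setting, charts))
    entries.sort(key=lambda e: e[0])
    x = np.array([e[0] for e in entries])
    paired = all(len(e[1]) == 2 for e in entries)

    def pm(chart) -> ParameterMaps:
        return chart.maps if isinstance(chart, ESIPChart) else chart

    rows = []
    for setting, charts in entries:
        m = pm(charts[0])
        row = {
            "setting": setting,
            "A": _center_mean(m, amplitude_key, center_fraction),
            "wFWHM": _center_mean(m, "wFWHM", center_fraction),
        }
        if paired:
            row["dz0"] = _center_mean(m, "z0", center_fraction) - _center_mean(
                pm(charts[1]), "z0", center_fraction
            )
        rows.append(row)
    df = pd.DataFrame(rows)

    warnings_: List[str] = []
    optima: Dict[str, float] = {}
    boundary: Dict[str, bool] = {}

    for key, maximize in (("A", True), ("wFWHM", False)):
        y = df[key].to_numpy()
        best = int(np.nanargmax(y) if maximize else np.nanargmin(y))
        opt, at_edge = _parabola_vertex(x, y, best, maximize)
        optima[key] = opt
        boundary[key] = at_edge or best in (0, x.size - 1)
        if boundary[key]:
            warnings_.append(f"optimum for {key} at series boundary: extend series")

    if paired:
        d = df["dz0"].to_numpy()
        sign = np.sign(d)
        crossings = np.flatnonzero(sign[:-1] * sign[1:] < 0)
        if crossings.size:
            i = crossings[0]
            opt = x[i] - d[i] * (x[i + 1] - x[i]) / (d[i + 1] - d[i])
            optima["dz0"] = float(opt)
            boundary["dz0"] = False
        else:
            best = int(np.nanargmin(np.abs(d)))
            opt, at_edge = _parabola_vertex(x, np.abs(d), best, maximize=False)
            optima["dz0"] = opt
            boundary["dz0"] = at_edge or best in (0, x.size - 1)
            if boundary["dz0"]:
                warnings_.append("optimum for dz0 at series boundary: extend series")

    return TuningSeries(
        settings=x, summaries=df, optima=optima,
        boundary=boundary, warnings=tuple(warnings_),
    )
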
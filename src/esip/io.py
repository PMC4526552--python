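"""File I/O and run configuration.

Calibration stacks are read from OME-TIFF (z positions from the OME plane
metadata) or from plain TIFF plus a sidecar table of z positions.  16-bit
data and non-uniform z spacing are preserved exactly.
"""

from __future__ import annotations

import hashlib
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import tifffile
import yaml

__all__ = ["Stack", "RunConfig", "read_stack", "write_stack", "read_z_sidecar"]


@dataclass
class Stack:
    """An axial image stack with z metadata.

    ``data`` is (nz, ny, nx); ``z`` holds the plane positions in um
    (non-uniform spacing allowed); ``channel`` names the detection channel
    the data belongs to (photon calibration is channel specific).
    """

    data: np.ndarray
    z: np.ndarray
    channel: Union[int, str] = 0
    pixel_size: Optional[float] = None
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.z = np.asarray(self.z, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be (nz, ny, nx)")
        if self.z.shape != (self.data.shape[0],):
            raise ValueError("z metadata length must match the number of planes")


def read_z_sidecar(path: Union[str, Path]) -> np.ndarray:
    """Read z positions (um) from a one-column CSV (optional 'z' header)."""
    lines = Path(path).read_text().strip().splitlines()
    if lines and not _is_number(lines[0].split(",")[0]):
        lines = lines[1:]
    return np.array([float(l.split(",")[0]) for l in lines if l.strip()])


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _ome_planes(ome_xml: str):
    root = ET.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0][1:]} if "}" in root.tag else {}
    planes = root.findall(".//ome:Plane", ns) if ns else root.findall(".//Plane")
    channels = root.findall(".//ome:Channel", ns) if ns else root.findall(".//Channel")
    px = root.find(".//ome:Pixels", ns) if ns else root.find(".//Pixels")
    return planes, channels, px


def read_stack(
    path: Union[str, Path],
    z: Optional[Union[str, Path, Sequence[float]]] = None,
    channel: Optional[Union[int, str]] = None,
) -> Stack:
    """Read a TIFF/OME-TIFF z-stack.

    z positions come from the OME plane metadata when present, otherwise
    from ``z`` (a sidecar CSV path or an explicit sequence).  For
    multi-channel files ``channel`` selects one channel (index or OME
    channel name); single-channel files need no selection.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta: Dict = {"axes": axes, "path": str(path)}
        z_positions = None
        pixel_size = None
        ch_names = []
        if tf.ome_metadata:
            planes, channels, px = _ome_planes(tf.ome_metadata)
            ch_names = [c.get("Name") or c.get("ID") for c in channels]
            if px is not None and px.get("PhysicalSizeX"):
                pixel_size = float(px.get("PhysicalSizeX"))
            zc = {}
            for p in planes:
                if p.get("PositionZ") is not None:
                    zc[(int(p.get("TheC", 0)), int(p.get("TheZ", 0)))] = float(
                        p.get("PositionZ")
                    )
            if zc:
                nz = 1 + max(k[1] for k in zc)
                z_positions = np.array([zc.get((0, i), np.nan) for i in range(nz)])
                if np.isnan(z_positions).any():
                    z_positions = None

    # reduce to (nz, ny, nx), selecting a channel when present
    if "C" in axes:
        cax = axes.index("C")
        n_ch = data.shape[cax]
        if channel is None:
            if n_ch > 1:
                raise ValueError(
                    f"stack has {n_ch} channels; select one via channel="
                )
            ci = 0
        elif isinstance(channel, str):
            if channel not in ch_names:
                raise ValueError(f"channel {channel!r} not in {ch_names}")
            ci = ch_names.index(channel)
        else:
            ci = int(channel)
        data = np.take(data, ci, axis=cax)
        axes = axes.replace("C", "")
        channel_label = channel if channel is not None else 0
    else:
        channel_label = channel if channel is not None else 0
    data = np.squeeze(data)
    if data.ndim == 2:
        data = data[None]

    if z is not None:
        if isinstance(z, (str, Path)):
            z_positions = read_z_sidecar(z)
        else:
            z_positions = np.asarray(z, dtype=float)
    if z_positions is None:
        raise ValueError(
            "no z positions: the file carries no OME plane metadata; "
            "pass z=<sidecar.csv> (one position per plane, um)"
        )
    return Stack(
        data=data, z=z_positions, channel=channel_label,
        pixel_size=pixel_size, metadata=meta,
    )


def write_stack(
    path: Union[str, Path],
    data: np.ndarray,
    z: Sequence[float],
    pixel_size: Optional[float] = None,
    channel_name: Optional[str] = None,
) -> None:
    """Write a (nz, ny, nx) stack as OME-TIFF with per-plane z positions."""
    data = np.asarray(data)
    z = np.asarray(z, dtype=float)
    if data.ndim != 3 or z.size != data.shape[0]:
        raise ValueError("data must be (nz, ny, nx) with one z per plane")
    meta: Dict = {
        "axes": "ZYX",
        "Plane": {
            "PositionZ": [float(v) for v in z],
            "PositionZUnit": ["µm"] * z.size,
        },
    }
    if pixel_size is not None:
        meta["PhysicalSizeX"] = pixel_size
        meta["PhysicalSizeXUnit"] = "µm"
        meta["PhysicalSizeY"] = pixel_size
        meta["PhysicalSizeYUnit"] = "µm"
    if channel_name is not None:
        meta["Channel"] = {"Name": [channel_name]}
    tifffile.imwrite(path, data, ome=True, metadata=meta)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of one analysis run (CLI and report plumbing)."""

    input: Optional[str] = None
    kind: str = "layer"  # layer | solution | grid
    shape: str = "gauss"
    bin: int = 4
    channel: Optional[Union[int, str]] = None
    dark: Optional[str] = None
    z_sidecar: Optional[str] = None
    center_fraction: float = 0.33
    lc_unit: str = "mm^-1"  # display unit for LC in summary tables
    seed: int = 0
    outdir: str = "esip_out"
    extra: Dict = field(default_factory=dict)

    def __post_init__(self):
        if self.bin < 2:
            raise ValueError("bin size must be >= 2")
        if self.kind not in ("layer", "solution", "grid"):
            raise ValueError(f"unknown sample kind {self.kind!r}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        kw = {k: v for k, v in raw.items() if k in known}
        kw["extra"] = {k: v for k, v in raw.items() if k not in known}
        kw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kw)

    def hash(self) -> str:
        """Stable hash of the configuration (embedded in every report)."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
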
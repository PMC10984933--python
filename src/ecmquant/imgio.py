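"""Reading and writing of masks, z-stacks, tables and run reports."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

from .biovolume import VolumeGrid

__all__ = [
    "read_mask",
    "write_mask",
    "read_stack",
    "write_stack",
    "sha256_file",
    "RunReport",
    "write_report",
]

log = logging.getLogger(__name__)


def read_mask(path) -> np.ndarray:
    """Read a 2-D binary mask from TIFF or PNG; returns a bool array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: binary mask required (got shape {arr.shape})")
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1, 255))):
        raise ValueError(f"{path}: binary mask required (found values {vals[:5]})")
    return arr > 0


def write_mask(path, mask: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


def _pitch_from_tiff(tf: tifffile.TiffFile):
    """Best-effort (z, y, x) pitch in µm from ImageJ metadata."""
    meta = tf.imagej_metadata or {}
    z = meta.get("spacing")
    page = tf.pages[0]
    tags = page.tags
    y = x = None
    if "XResolution" in tags and "YResolution" in tags:
        xr = tags["XResolution"].value
        yr = tags["YResolution"].value
        unit = meta.get("unit", "")
        if unit in ("micron", "um", "µm") and xr[0] and yr[0]:
            x = xr[1] / xr[0]
            y = yr[1] / yr[0]
    if z is not None and y is not None and x is not None:
        return (float(z), float(y), float(x))
    return None


def read_stack(
    path,
    voxel_pitch: tuple[float, float, float] | None = None,
    channel_names: tuple[str, ...] | None = None,
) -> list[VolumeGrid]:
    """Read a z-stack as one :class:`VolumeGrid` per channel.

    Axes are resolved from TIFF series metadata to (z, y, x) with an
    optional leading channel axis. An explicit ``voxel_pitch`` (z, y, x
    in µm) wins over file metadata, with a logged warning on conflict;
    if neither is available an error is raised.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        arr = series.asarray()
        axes = series.axes
        meta_pitch = _pitch_from_tiff(tf)
    axes = axes.replace("S", "C").replace("Q", "Z").replace("I", "Z")
    if set(axes) - set("CZYX"):
        raise ValueError(f"{path}: unsupported axes {axes!r}")
    # reorder to CZYX
    order = [axes.index(a) for a in "CZYX" if a in axes]
    arr = np.transpose(arr, order)
    if "C" not in axes:
        arr = arr[None, ...]
    if arr.ndim != 4:
        raise ValueError(f"{path}: expected a (C)ZYX stack, got shape {arr.shape}")
    if voxel_pitch is not None and meta_pitch is not None:
        if not np.allclose(voxel_pitch, meta_pitch, rtol=1e-3):
            log.warning(
                "%s: config voxel pitch %s overrides file metadata %s",
                path,
                voxel_pitch,
                meta_pitch,
            )
    pitch = voxel_pitch or meta_pitch
    if pitch is None:
        raise ValueError(f"{path}: voxel pitch missing from both config and metadata")
    names = channel_names or tuple(f"ch{c}" for c in range(arr.shape[0]))
    return [
        VolumeGrid(arr[c].astype(float), tuple(pitch), channel=names[c])
        for c in range(arr.shape[0])
    ]


def write_stack(path, grids: list[VolumeGrid]) -> Path:
    """Write channels as a CZYX uint16 TIFF (values are rounded)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.stack(
        [np.clip(np.round(g.intensities), 0, 65535).astype(np.uint16) for g in grids]
    )
    data = np.moveaxis(data, 0, 1)  # ImageJ hyperstack wants ZCYX
    zp, yp, xp = grids[0].voxel_pitch
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / xp, 1.0 / yp),
        metadata={"axes": "ZCYX", "spacing": zp, "unit": "um"},
    )
    return path


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunReport:
    """Reproducibility record written next to every stage's outputs."""

    stage: str
    config: dict
    config_hash: str
    software_version: str
    input_checksums: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_report(path, report: RunReport) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(asdict(report), indent=2, sort_keys=True, default=str))
    return path
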
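"""Image and table I/O.

All pipelines consume :class:`ImageScene` objects: one or more equally
shaped intensity channels plus an isotropic physical pixel size in µm.
Time-lapse channels are 3D ``(t, y, x)``; single frames are 2D ``(y, x)``.

TIFF files written by this package carry the pixel size both in the
standard resolution tags (pixels per centimeter) and in the JSON metadata
block of tifffile's "shaped" format, together with the channel names and
frame interval, so a write/read round trip is lossless.  For foreign TIFFs
the pixel size is recovered from the resolution tags; files whose
ResolutionUnit is NONE are interpreted as pixels per micrometer (the
convention of the example data this package targets).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageScene",
    "ResultTable",
    "read_image",
    "write_image",
    "write_results",
    "read_results",
]

_CM_PER_UM = 1e-4


@dataclass
class ImageScene:
    """A multichannel fluorescence scene with physical calibration.

    Parameters
    ----------
    channels
        Mapping of channel name to intensity array.  Arrays are 2D
        ``(y, x)`` for single frames or 3D ``(t, y, x)`` for time-lapse;
        all channels must share one shape.
    pixel_size
        Isotropic pixel size in µm per pixel; must be positive.
    frame_interval
        Minutes between frames for time-lapse data, else ``None``.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("scene needs at least one channel")
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim not in (2, 3):
                raise ValueError(f"channel {name!r} must be 2D or 3D, got {arr.ndim}D")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"channel {name!r} has non-finite or negative intensities")

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    @property
    def is_timelapse(self) -> bool:
        return next(iter(self.channels.values())).ndim == 3

    def channel(self, name: str | None = None) -> np.ndarray:
        """Return a channel by name, or the only channel if unnamed."""
        if name is None:
            if len(self.channels) != 1:
                raise ValueError(
                    f"scene has {len(self.channels)} channels; name one of {self.channel_names}"
                )
            return next(iter(self.channels.values()))
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(f"no channel {name!r}; available: {self.channel_names}") from None


@dataclass
class ResultTable:
    """Measurement records plus the provenance needed to reproduce them."""

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if len(cols) != len(set(cols)):
            raise ValueError("column names must be unique")

    def __len__(self) -> int:
        return len(self.data)


def write_image(scene: ImageScene, path: str | Path) -> Path:
    """Write a scene as a multi-page TIFF with embedded calibration."""
    path = Path(path)
    arrs = list(scene.channels.values())
    stack = np.stack(arrs, axis=0)  # (c, y, x) or (c, t, y, x)
    px_per_cm = 1.0 / (scene.pixel_size * _CM_PER_UM)
    meta = {
        "pixel_size_um": scene.pixel_size,
        "channel_names": scene.channel_names,
        "frame_interval_min": scene.frame_interval,
        "axes_order": "ctyx" if scene.is_timelapse else "cyx",
    }
    tifffile.imwrite(
        path,
        stack,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        metadata=meta,
    )
    return path


def _pixel_size_from_tags(page: tifffile.TiffPage) -> float | None:
    """Physical pixel size in µm from standard TIFF resolution tags."""
    tag = page.tags.get("XResolution")
    if tag is None:
        return None
    num, den = tag.value
    if num == 0:
        return None
    px_per_unit = num / den
    unit_tag = page.tags.get("ResolutionUnit")
    unit = getattr(unit_tag, "value", None)
    unit = getattr(unit, "value", unit)  # enum -> int
    if unit == 3:  # centimeter
        return 1e4 / px_per_unit
    if unit == 2:  # inch
        return 25400.0 / px_per_unit
    if px_per_unit == 1:  # the (1, 1)/NONE placeholder many writers emit
        return None
    # ResolutionUnit NONE (1) or absent: pixels per micrometer by convention
    return 1.0 / px_per_unit


def read_image(
    path: str | Path,
    pixel_size_override: float | None = None,
    channel_names: list[str] | None = None,
    frame_interval: float | None = None,
) -> ImageScene:
    """Read a single- or multi-page TIFF into an :class:`ImageScene`.

    Pixel size is taken from file metadata when present, otherwise from
    ``pixel_size_override``; if neither is available this is an error.
    3D stacks without embedded metadata are interpreted as single-channel
    time-lapse ``(t, y, x)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        shaped = tif.shaped_metadata
        meta = dict(shaped[0]) if shaped else {}
        tag_px = _pixel_size_from_tags(tif.pages[0])

    pixel_size = meta.get("pixel_size_um") or tag_px or pixel_size_override
    if pixel_size is None:
        raise ValueError(f"pixel size unknown for {path}: no metadata and no override given")

    axes = meta.get("axes_order")
    names = channel_names or meta.get("channel_names")
    interval = frame_interval if frame_interval is not None else meta.get("frame_interval_min")

    if data.ndim == 2:
        planes = [data]
    elif axes in ("cyx", "ctyx"):
        planes = list(data)
    elif data.ndim == 3 and names is not None and len(names) == data.shape[0]:
        planes = list(data)
    elif data.ndim == 3:
        planes = [data]  # anonymous stack: single-channel time-lapse
    else:
        raise ValueError(f"cannot interpret TIFF of shape {data.shape}")

    if names is None:
        names = [f"ch{i}" for i in range(len(planes))]
    if len(names) != len(planes):
        raise ValueError(f"{len(names)} channel names for {len(planes)} channels")
    return ImageScene(
        channels=dict(zip(names, [np.asarray(p) for p in planes])),
        pixel_size=float(pixel_size),
        frame_interval=interval,
    )


def write_results(table: ResultTable, path: str | Path, allow_empty: bool = True) -> Path:
    """Write a result table to CSV, provenance as leading ``#`` comments."""
    if len(table) == 0 and not allow_empty:
        raise ValueError("refusing to write empty table (allow_empty=False)")
    path = Path(path)
    with open(path, "w") as fh:
        if table.provenance:
            fh.write("# provenance: " + json.dumps(table.provenance, default=str) + "\n")
        table.data.to_csv(fh, index=False)
    return path


def read_results(path: str | Path) -> ResultTable:
    path = Path(path)
    provenance: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# provenance: "):
            provenance = json.loads(first[len("# provenance: "):])
        else:
            fh.seek(0)
        data = pd.read_csv(fh)
    return ResultTable(data=data, provenance=provenance)
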
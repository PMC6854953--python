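"""Image and table input/output.

Images travel as :class:`ImageStack`: a mapping of named 2-D intensity
channels (``nuclear``, ``wfa``, ``comparison``, ``pv`` in a typical run)
plus the pixel size in micrometres.  On disk a stack is a multipage
grayscale TIFF with a JSON sidecar recording channel names and pixel
size; a directory of per-channel TIFFs is accepted as well, since
microscope export dialects vary.

All intensities are normalised to the ``[0, 1]`` float scale at read
time (integer inputs are divided by their dtype range); every threshold
downstream is expressed on that scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "read_stack",
    "write_stack",
    "write_measurements",
    "read_measurements",
]


@dataclass
class ImageStack:
    """Named 2-D intensity channels sharing one shape.

    Parameters
    ----------
    channels
        Mapping channel name -> 2-D float array.  All arrays must share
        one shape and contain finite, non-negative values.
    pixel_size
        Edge length of one pixel in micrometres.
    source_path
        Where the stack was read from, if anywhere.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = 1.0
    source_path: Path | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack requires at least one channel")
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")
        if any(arr.ndim != 2 for arr in self.channels.values()):
            raise ValueError("channels must be 2-D arrays")
        for name, arr in self.channels.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if arr.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValueError("pixel_size must be positive and finite")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def pixel_area_um2(self) -> float:
        return float(self.pixel_size) ** 2

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not in stack (have {sorted(self.channels)})"
            ) from None


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    """Rescale an integer image to [0, 1] by its dtype range."""
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / float(info.max)
    return np.asarray(arr, dtype=np.float64)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multipage 16-bit TIFF plus a JSON sidecar.

    Channel order in the file follows the stack's channel insertion
    order and is recorded, with the pixel size, in ``<path>.json``.
    Values are clipped to [0, 1] before 16-bit quantisation.
    """
    path = Path(path)
    names = list(stack.channels)
    planes = np.stack(
        [
            np.clip(stack.channels[n], 0.0, 1.0) * np.iinfo(np.uint16).max
            for n in names
        ]
    ).astype(np.uint16)
    tifffile.imwrite(path, planes, photometric="minisblack")
    sidecar = {"channels": names, "pixel_size": stack.pixel_size}
    _sidecar_path(path).write_text(json.dumps(sidecar, sort_keys=True, indent=1))
    return path


def read_stack(
    path: str | Path,
    channel_map: Mapping[int, str] | None = None,
    pixel_size: float | None = None,
) -> ImageStack:
    """Read an :class:`ImageStack` from disk.

    ``path`` may be a multipage TIFF or a directory of per-channel
    TIFFs (each file's stem becomes its channel name).  For a multipage
    file, ``channel_map`` maps plane index -> channel name; when absent
    the JSON sidecar written by :func:`write_stack` supplies the names.
    Integer pixel data are rescaled to [0, 1] by their dtype range.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")

    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF files in directory {path}")
        channels = {p.stem: _to_unit_float(tifffile.imread(p)) for p in files}
        if pixel_size is None:
            raise ValueError("pixel_size is required when reading a channel directory")
        return ImageStack(channels=channels, pixel_size=pixel_size, source_path=path)

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D or multipage image, got shape {arr.shape}")
    n_planes = arr.shape[0]

    if channel_map is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(
                "channel_map not given and no sidecar JSON found; "
                "cannot name the planes"
            )
        meta = json.loads(sidecar.read_text())
        names = meta["channels"]
        if len(names) != n_planes:
            raise ValueError(
                f"sidecar names {len(names)} channels but file has {n_planes} planes"
            )
        channel_map = dict(enumerate(names))
        if pixel_size is None:
            pixel_size = float(meta.get("pixel_size", 1.0))
    if pixel_size is None:
        pixel_size = 1.0

    seen: dict[str, int] = {}
    channels: dict[str, np.ndarray] = {}
    for idx, name in sorted(channel_map.items()):
        idx = int(idx)
        if idx < 0 or idx >= n_planes:
            raise IndexError(
                f"channel_map names plane {idx} but file has {n_planes} planes"
            )
        if name in seen:
            raise ValueError(f"duplicate channel name {name!r} (planes {seen[name]}, {idx})")
        seen[name] = idx
        channels[name] = _to_unit_float(arr[idx])
    return ImageStack(channels=channels, pixel_size=pixel_size, source_path=path)


def _flatten_record(rec) -> dict:
    d = dataclasses.asdict(rec) if dataclasses.is_dataclass(rec) else dict(rec)
    mean = d.pop("mean_intensity", {})
    for channel in sorted(mean):
        d[f"mean_{channel}"] = mean[channel]
    return d


def write_measurements(records: Sequence, path: str | Path) -> Path:
    """Write per-PNN measurement records as CSV, one row per PNN.

    Column order is stable across runs: the scalar fields in dataclass
    order followed by ``mean_<channel>`` columns sorted by channel name.
    An empty record list produces a header-only file with the scalar
    columns.
    """
    path = Path(path)
    rows = [_flatten_record(r) for r in records]
    if rows:
        df = pd.DataFrame(rows)
    else:
        from .quantify import MeasurementRecord  # local import: avoid cycle

        cols = [f.name for f in dataclasses.fields(MeasurementRecord) if f.name != "mean_intensity"]
        df = pd.DataFrame(columns=cols)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_measurements(path: str | Path):
    """Read a measurement CSV back into :class:`~pnnquant.quantify.MeasurementRecord` objects."""
    from .quantify import MeasurementRecord

    df = pd.read_csv(path, float_precision="round_trip")
    records = []
    mean_cols = [c for c in df.columns if c.startswith("mean_")]
    for _, row in df.iterrows():
        mean = {c[len("mean_"):]: float(row[c]) for c in mean_cols}
        records.append(
            MeasurementRecord(
                pnn_id=int(row["pnn_id"]),
                area_px=float(row["area_px"]),
                area_um2=float(row["area_um2"]),
                mean_intensity=mean,
                image_id=str(row["image_id"]),
                subject_id=str(row["subject_id"]),
            )
        )
    return records
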
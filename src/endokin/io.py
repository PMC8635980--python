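"""Reading and writing of time-lapse stacks, ROI series, trace tables and
configs.

Formats are deliberately plain: multi-page TIFF with axes T,C,Y,X (channel
names and frame interval stored in the TIFF description metadata), ROI series
as CSV (circles) or JSON (arbitrary polygons), trace tables as CSV with a
fixed schema, configs as YAML.  The binary ImageJ ``.roi`` format is not
parsed; the CSV/JSON schema below replaces it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .rim import Circle, Geometry, PolygonRoi, PolylineRoi
from .rim import TRACE_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "TimeLapseStack",
    "RoiSeries",
    "read_stack",
    "write_stack",
    "read_roi_series",
    "write_roi_series",
    "read_roi_json",
    "write_roi_json",
    "read_trace_table",
    "write_trace_table",
    "read_config",
    "write_config",
]


# ---------------------------------------------------------------------------
# Time-lapse stacks
# ---------------------------------------------------------------------------

@dataclass
class TimeLapseStack:
    """Pixel data with time and channel axes.

    ``pixels`` has shape (T, C, Y, X); intensities are finite and
    non-negative (arbitrary units).
    """

    pixels: np.ndarray
    channel_names: list[str]
    frame_interval_min: float
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 4:
            raise ValueError(f"pixels must be 4-D (T,C,Y,X), got {arr.ndim}-D")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("need at least one frame and one channel")
        if not np.isfinite(arr).all():
            raise ValueError("stack contains non-finite intensities")
        if (arr < 0).any():
            raise ValueError("stack contains negative intensities")
        if len(self.channel_names) != arr.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{arr.shape[1]} channels"
            )
        if self.frame_interval_min <= 0:
            raise ValueError("frame interval must be positive")
        self.pixels = arr
        self.channel_names = [str(c) for c in self.channel_names]

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min

    def channel(self, name: str) -> np.ndarray:
        """(T, Y, X) view of one named channel."""
        return self.pixels[:, self.channel_names.index(name)]


def write_stack(stack: TimeLapseStack, path) -> None:
    """Write a stack as a multi-page TIFF with metadata in the description."""
    md = {
        "axes_order": "TCYX",
        "channel_names": stack.channel_names,
        "frame_interval_min": stack.frame_interval_min,
        "pixel_size_um": stack.pixel_size_um,
    }
    tifffile.imwrite(path, stack.pixels, photometric="minisblack",
                     metadata=md)


def read_stack(path, frame_interval_min: float | None = None,
               channel_names: list[str] | None = None) -> TimeLapseStack:
    """Read a TIFF into a (T, C, Y, X) stack.

    Axis layout is taken from the embedded metadata when present; otherwise a
    3-D array is interpreted as (T, Y, X) unless ``channel_names`` identifies
    axis 0 as channels, and a 2-D image becomes a single frame/channel.
    Missing frame interval / channel names are filled from the arguments with
    a logged note.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            md: Mapping = {}
            if tif.shaped_metadata:
                md = tif.shaped_metadata[0]
    except tifffile.TiffFileError as exc:
        raise ValueError(f"{path} is not a readable TIFF: {exc}") from None

    names = channel_names or md.get("channel_names")
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        if names is not None and len(names) == arr.shape[0] and len(names) > 1:
            arr = arr[None, :]
        elif names is None or len(names) == 1:
            arr = arr[:, None]
        else:
            raise ValueError(
                f"cannot resolve axes of 3-D array {arr.shape}: candidate "
                "layouts are (T,Y,X) and (C,Y,X); pass channel_names"
            )
    elif arr.ndim != 4:
        raise ValueError(f"unsupported TIFF dimensionality {arr.ndim}")

    arr = np.asarray(arr, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError(f"{path}: NaN/inf intensities are not allowed")
    if (arr < 0).any():
        raise ValueError(f"{path}: negative intensities are not allowed")

    if names is None:
        names = [f"ch{i}" for i in range(arr.shape[1])]
        logger.info("%s: no channel names in metadata, using %s", path, names)
    interval = frame_interval_min or md.get("frame_interval_min")
    if interval is None:
        interval = 1.0
        logger.info("%s: no frame interval in metadata, assuming 1 min", path)
    return TimeLapseStack(arr, list(names), float(interval),
                          md.get("pixel_size_um"))


# ---------------------------------------------------------------------------
# ROI series
# ---------------------------------------------------------------------------

@dataclass
class RoiSeries:
    """Per-endosome boundary geometry for every frame it was identifiable."""

    endosome_id: str
    geometries: dict[int, Geometry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.geometries:
            raise ValueError("RoiSeries needs at least one frame")
        frames = sorted(self.geometries)
        if frames != list(range(frames[0], frames[-1] + 1)):
            raise ValueError(
                f"ROI frames must be contiguous, got gaps in {frames}"
            )

    @property
    def first_frame(self) -> int:
        return min(self.geometries)

    @property
    def last_frame(self) -> int:
        return max(self.geometries)


def write_roi_series(series: list[RoiSeries], path) -> None:
    """CSV schema: endosome_id, frame, cy, cx, radius_px (circular ROIs)."""
    rows = []
    for s in series:
        for frame, geom in sorted(s.geometries.items()):
            if not isinstance(geom, Circle):
                raise TypeError(
                    "CSV ROI format holds circles only; use write_roi_json"
                )
            rows.append({"endosome_id": s.endosome_id, "frame": frame,
                         "cy": geom.cy, "cx": geom.cx,
                         "radius_px": geom.radius_px})
    pd.DataFrame(rows, columns=["endosome_id", "frame", "cy", "cx",
                                "radius_px"]).to_csv(path, index=False)


def read_roi_series(path) -> list[RoiSeries]:
    df = pd.read_csv(path)
    required = {"endosome_id", "frame", "cy", "cx", "radius_px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ROI CSV missing columns: {sorted(missing)}")
    out = []
    for eid, grp in df.groupby("endosome_id", sort=True):
        geoms = {int(r.frame): Circle(r.cy, r.cx, r.radius_px)
                 for r in grp.itertuples()}
        out.append(RoiSeries(str(eid), geoms))
    return out


def _geom_to_obj(geom: Geometry) -> dict:
    if isinstance(geom, Circle):
        return {"type": "circle", "cy": geom.cy, "cx": geom.cx,
                "radius_px": geom.radius_px}
    if isinstance(geom, PolygonRoi):
        return {"type": "polygon", "vertices": geom.vertices.tolist()}
    if isinstance(geom, PolylineRoi):
        return {"type": "polyline", "vertices": geom.vertices.tolist()}
    raise TypeError(f"unsupported geometry {type(geom).__name__}")


def _geom_from_obj(obj: Mapping) -> Geometry:
    kind = obj.get("type")
    if kind == "circle":
        return Circle(obj["cy"], obj["cx"], obj["radius_px"])
    if kind == "polygon":
        return PolygonRoi(np.asarray(obj["vertices"], dtype=float))
    if kind == "polyline":
        return PolylineRoi(np.asarray(obj["vertices"], dtype=float))
    raise ValueError(f"unknown geometry type {kind!r}")


def write_roi_json(series: list[RoiSeries], path) -> None:
    """JSON ROI schema: list of {endosome_id, frames: {frame: geometry}}."""
    payload = [
        {"endosome_id": s.endosome_id,
         "frames": {str(f): _geom_to_obj(g)
                    for f, g in sorted(s.geometries.items())}}
        for s in series
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_roi_json(path) -> list[RoiSeries]:
    payload = json.loads(Path(path).read_text())
    return [
        RoiSeries(str(item["endosome_id"]),
                  {int(f): _geom_from_obj(g)
                   for f, g in item["frames"].items()})
        for item in payload
    ]


# ---------------------------------------------------------------------------
# Trace tables and configs
# ---------------------------------------------------------------------------

MANDATORY_TRACE_COLUMNS = ["endosome_id", "frame", "time_min", "channel",
                           "rim_mfi", "bg_mfi", "lumen_mean", "lumen_total"]


def _check_trace_schema(df: pd.DataFrame) -> None:
    missing = set(MANDATORY_TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")


def write_trace_table(df: pd.DataFrame, path) -> None:
    """Write a trace table as CSV (header always present, full precision)."""
    if df.empty and not set(MANDATORY_TRACE_COLUMNS) <= set(df.columns):
        df = pd.DataFrame(columns=TRACE_COLUMNS)
    _check_trace_schema(df)
    df.to_csv(path, index=False)


def read_trace_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_trace_schema(df)
    numeric = ["rim_mfi", "bg_mfi", "lumen_mean", "lumen_total"]
    vals = df[numeric].to_numpy(dtype=float)
    if len(df) and not np.isfinite(vals).all():
        raise ValueError(f"{path}: non-finite intensities in trace table")
    return df


def write_config(config: Mapping, path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(config), sort_keys=True))


def read_config(path) -> dict:
    obj = yaml.safe_load(Path(path).read_text())
    if not isinstance(obj, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return obj
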
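"""Core data containers and calibrated I/O.

Shared containers used throughout the pipeline: calibrated image stacks,
cell centroid tracks, the agarose-spot edge geometry, punctum detections
and tracks, and focal adhesions.  Pixel coordinates are 0-based ``(row,
col)`` with the origin at the top-left; calibrated quantities are in µm
(``x`` maps to columns, ``y`` to rows).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml


class ConfigurationError(ValueError):
    """Invalid configuration (unknown preset, bad parameter value, ...)."""


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given input (too few samples, zero duration, ...)."""


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

@dataclass
class TimelapseStack:
    """Calibrated fluorescence timelapse.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_frames, rows, cols)``.  Single
        channel / single frame inputs are promoted on construction.
    pixel_size_um
        Lateral pixel size in µm/px.
    frame_interval_s
        Time between frames in seconds.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[None]
        elif arr.ndim != 4:
            raise ValueError(f"expected 2-4 dimensional image data, got {arr.ndim}")
        self.data = arr
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ConfigurationError("pixel size and frame interval must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, c: int) -> np.ndarray:
        """Return the ``(n_frames, rows, cols)`` array of one channel."""
        return self.data[c]

    def frame(self, t: int, channel: int = 0) -> np.ndarray:
        return self.data[channel, t]

    def save(self, path: str | Path, interleaved: bool = True) -> list[Path]:
        """Write the stack as OME-TIFF.

        With ``interleaved=True`` one file holds all channels (axes CTYX);
        otherwise one file per channel is written with a ``_chN`` suffix.
        Returns the paths written.
        """
        path = Path(path)
        meta = {
            "axes": "CTYX",
            "PhysicalSizeX": self.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": self.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "TimeIncrement": self.frame_interval_s,
            "TimeIncrementUnit": "s",
        }
        if interleaved:
            tifffile.imwrite(path, self.data.astype(np.float32), ome=True,
                             metadata=meta)
            return [path]
        written = []
        for c in range(self.n_channels):
            p = path.with_name(f"{path.stem}_ch{c}{path.suffix}")
            m = dict(meta, axes="TYX")
            tifffile.imwrite(p, self.data[c].astype(np.float32), ome=True, metadata=m)
            written.append(p)
        return written

    @classmethod
    def load(cls, path: str | Path, pixel_size_um: float | None = None,
             frame_interval_s: float | None = None) -> "TimelapseStack":
        """Read a (OME-)TIFF stack; calibration read from OME metadata when present."""
        path = Path(path)
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            axes = None
            if tf.ome_metadata is not None:
                try:
                    axes = tf.series[0].axes
                except (IndexError, AttributeError):  # pragma: no cover
                    axes = None
                meta = _parse_ome_pixels(tf.ome_metadata)
                pixel_size_um = pixel_size_um or meta.get("PhysicalSizeX")
                frame_interval_s = frame_interval_s or meta.get("TimeIncrement")
        if pixel_size_um is None or frame_interval_s is None:
            raise ConfigurationError(
                "pixel size / frame interval missing from metadata; pass explicitly")
        if axes == "CTYX" and arr.ndim == 4:
            pass
        elif axes == "TCYX" and arr.ndim == 4:
            arr = np.swapaxes(arr, 0, 1)
        return cls(arr, pixel_size_um, frame_interval_s)


def _parse_ome_pixels(ome_xml: str) -> dict:
    import re

    out: dict = {}
    for key in ("PhysicalSizeX", "TimeIncrement"):
        m = re.search(rf'{key}="([0-9.eE+-]+)"', ome_xml)
        if m:
            out[key] = float(m.group(1))
    return out


# ---------------------------------------------------------------------------
# Cell tracks
# ---------------------------------------------------------------------------

@dataclass
class CellTrack:
    """Time-ordered centroid track of one cell, with optional shape descriptors.

    ``t_s`` is strictly increasing; positions are in µm.  ``width_um`` /
    ``length_um`` are per-frame fitted cell axes (width = minor axis).
    """

    id: int
    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    width_um: np.ndarray | None = None
    length_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if not (len(self.t_s) == len(self.x_um) == len(self.y_um)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t_s) > 1 and not np.all(np.diff(self.t_s) > 0):
            raise ValueError("track times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])


def tracks_to_frame(tracks: Iterable[CellTrack]) -> pd.DataFrame:
    """Flatten tracks to a tidy table (id, frame, t_s, x_um, y_um[, shape])."""
    rows = []
    for tr in tracks:
        for i in range(len(tr)):
            row = {"id": tr.id, "frame": i, "t_s": tr.t_s[i],
                   "x_um": tr.x_um[i], "y_um": tr.y_um[i]}
            if tr.width_um is not None:
                row["width_um"] = tr.width_um[i]
                row["length_um"] = tr.length_um[i]
            rows.append(row)
    return pd.DataFrame(rows)


def write_tracks_csv(tracks: Iterable[CellTrack], path: str | Path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> list[CellTrack]:
    df = pd.read_csv(path)
    required = {"id", "t_s", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"track CSV must contain columns {sorted(required)}")
    tracks = []
    has_shape = {"width_um", "length_um"}.issubset(df.columns)
    for tid, grp in df.groupby("id", sort=True):
        grp = grp.sort_values("t_s")
        tracks.append(CellTrack(
            id=int(tid),
            t_s=grp["t_s"].to_numpy(),
            x_um=grp["x_um"].to_numpy(),
            y_um=grp["y_um"].to_numpy(),
            width_um=grp["width_um"].to_numpy() if has_shape else None,
            length_um=grp["length_um"].to_numpy() if has_shape else None,
        ))
    return tracks


# ---------------------------------------------------------------------------
# Agarose spot geometry
# ---------------------------------------------------------------------------

@dataclass
class SpotGeometry:
    """Edge of the chemoattractant agarose spot, in µm coordinates.

    Two shapes are supported: a straight edge (``kind='line'``) defined by a
    point on the edge and the inward unit normal, and a circular spot
    (``kind='circle'``) defined by centre and radius with the interior being
    the disk.  The *perpendicular* at a position is the inward normal of the
    nearest edge point: for a line it is constant, for a circle it points
    from the position toward the centre.
    """

    kind: str = "line"
    point_um: tuple[float, float] = (0.0, 0.0)
    normal: tuple[float, float] = (1.0, 0.0)
    center_um: tuple[float, float] = (0.0, 0.0)
    radius_um: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("line", "circle"):
            raise ConfigurationError(f"unknown spot geometry kind {self.kind!r}")
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if self.kind == "line":
            if nn == 0:
                raise ConfigurationError("spot normal must be non-zero")
            self.normal = tuple(n / nn)
        if self.kind == "circle" and self.radius_um <= 0:
            raise ConfigurationError("spot radius must be positive")

    def signed_distance(self, points_um: np.ndarray) -> np.ndarray:
        """Signed distance to the edge, positive inside the spot."""
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        if self.kind == "line":
            d = (p - np.asarray(self.point_um)) @ np.asarray(self.normal)
        else:
            d = self.radius_um - np.linalg.norm(p - np.asarray(self.center_um), axis=1)
        return d if np.asarray(points_um).ndim > 1 else d[0]

    def is_inside(self, points_um: np.ndarray) -> np.ndarray:
        return self.signed_distance(points_um) > 0

    def perpendicular_at(self, points_um: np.ndarray) -> np.ndarray:
        """Inward unit normal of the nearest edge point."""
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        if self.kind == "line":
            u = np.broadcast_to(np.asarray(self.normal), p.shape).copy()
        else:
            v = np.asarray(self.center_um) - p
            norms = np.linalg.norm(v, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            u = v / norms
        return u if np.asarray(points_um).ndim > 1 else u[0]

    def reflect_inside(self, points_um: np.ndarray) -> np.ndarray:
        """Mirror any point that lies inside back across the edge (used to
        model cells blocked at the agarose interface)."""
        p = np.atleast_2d(np.asarray(points_um, dtype=float)).copy()
        d = self.signed_distance(p)
        inside = d > 0
        if np.any(inside):
            u = self.perpendicular_at(p[inside])
            p[inside] = p[inside] - 2.0 * d[inside, None] * u
        return p if np.asarray(points_um).ndim > 1 else p[0]

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        if self.kind == "line":
            return {"kind": "line",
                    "point_um": [float(v) for v in self.point_um],
                    "normal": [float(v) for v in self.normal]}
        return {"kind": "circle",
                "center_um": [float(v) for v in self.center_um],
                "radius_um": float(self.radius_um)}

    @classmethod
    def from_dict(cls, d: dict) -> "SpotGeometry":
        kind = d.get("kind", "line")
        if kind == "line":
            return cls(kind="line", point_um=tuple(d["point_um"]),
                       normal=tuple(d["normal"]))
        return cls(kind="circle", center_um=tuple(d["center_um"]),
                   radius_um=float(d["radius_um"]))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({"spot": self.to_dict()}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpotGeometry":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d["spot"] if "spot" in d else d)


# ---------------------------------------------------------------------------
# Puncta
# ---------------------------------------------------------------------------

@dataclass
class Punctum:
    """One diffraction-limited spot detection in one frame."""

    frame: int
    x_px: float
    y_px: float
    intensity: float          # peak intensity (raw counts)
    background: float         # local background estimate
    radius_px: float = 1.5

    def __post_init__(self) -> None:
        if self.intensity <= self.background:
            raise ValueError("punctum peak intensity must exceed background")

    def xy_um(self, pixel_size_um: float) -> tuple[float, float]:
        return self.x_px * pixel_size_um, self.y_px * pixel_size_um


FATES = ("static", "lateral", "disappearing", "censored")


@dataclass
class PunctaTrack:
    """Linked punctum detections over time with an optional fate label."""

    id: int
    frames: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    intensity: np.ndarray
    background: np.ndarray
    fate: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        for name in ("x_px", "y_px", "intensity", "background"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("track frames must be strictly increasing")
        if self.fate is not None and self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def last_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def start_xy(self) -> np.ndarray:
        return np.array([self.x_px[0], self.y_px[0]])

    @property
    def end_xy(self) -> np.ndarray:
        return np.array([self.x_px[-1], self.y_px[-1]])

    def net_displacement_um(self, pixel_size_um: float) -> float:
        return float(np.linalg.norm(self.end_xy - self.start_xy) * pixel_size_um)


@dataclass
class DisappearanceEvent:
    """A punctum disappearance accepted as an internalisation event.

    The three criteria flags (rapid fall to background, no reappearance in
    the evanescent field within the window, not attributable to global
    photobleaching) must all be true for an event to be emitted.
    """

    track_id: int
    frame: int
    x_px: float
    y_px: float
    rapid: bool
    no_reappearance: bool
    not_photobleaching: bool
    region: str | None = None

    @property
    def accepted(self) -> bool:
        return self.rapid and self.no_reappearance and self.not_photobleaching


# ---------------------------------------------------------------------------
# Focal adhesions
# ---------------------------------------------------------------------------

@dataclass
class FocalAdhesion:
    """A segmented elongated adhesion linked across frames.

    ``intensity`` holds the background-subtracted integrated intensity over
    the adhesion's reference footprint for every frame of the stack, so the
    trace extends below the detection threshold during disassembly.
    """

    id: int
    centroid_px: tuple[float, float]          # (x, y) at first detection
    major_axis_px: float
    minor_axis_px: float
    orientation_rad: float
    frames: np.ndarray                        # frames where detected
    intensity: np.ndarray                     # full-stack trace
    mask: np.ndarray | None = None            # reference boolean footprint
    area_um2: float | None = None

    @property
    def elongation(self) -> float:
        return self.major_axis_px / max(self.minor_axis_px, 1e-9)

    def centroid_um(self, pixel_size_um: float) -> tuple[float, float]:
        return (self.centroid_px[0] * pixel_size_um,
                self.centroid_px[1] * pixel_size_um)


@dataclass
class DisassemblyMeasurement:
    """Timing of one focal-adhesion disassembly."""

    fa_id: int
    onset_frame: int
    end_frame: int
    time_min: float

    def __post_init__(self) -> None:
        if self.end_frame <= self.onset_frame:
            raise ValueError("disassembly end must come after onset")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
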
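"""Migration metrics for the agarose-spot chemotactic invasion assay.

Per-track quantities mirror the panels of the overnight-timelapse
analysis: migrated-cell count, total path length, distance from origin,
average velocity, elliptical factor and migration angle relative to the
perpendicular to the spot edge, plus percent change between conditions and
the wound-healing distance.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import CellTrack, SpotGeometry, UndefinedMetricError


def _require_samples(track: CellTrack, n: int = 2) -> None:
    if len(track) < n:
        raise UndefinedMetricError(
            f"track {track.id}: needs >= {n} samples, has {len(track)}")


def count_migrated(tracks: Sequence[CellTrack], spot: SpotGeometry) -> int:
    """Number of tracks that crossed the spot edge and ended inside.

    Requiring both the crossing and the interior endpoint excludes cells
    that were seeded under the spot.  Tracks with no samples are rejected
    with their ids reported.
    """
    if not tracks:
        raise UndefinedMetricError("no tracks given")
    bad = [tr.id for tr in tracks if len(tr) < 1]
    if bad:
        raise UndefinedMetricError(f"tracks without samples: {bad}")
    n = 0
    for tr in tracks:
        d = spot.signed_distance(tr.xy)
        if d[-1] > 0 and np.any(d <= 0):
            n += 1
    return n


def migrated_ids(tracks: Sequence[CellTrack], spot: SpotGeometry) -> set[int]:
    """Ids of tracks counted as migrated (see :func:`count_migrated`)."""
    out = set()
    for tr in tracks:
        d = spot.signed_distance(tr.xy)
        if d[-1] > 0 and np.any(d <= 0):
            out.add(tr.id)
    return out


def path_length(track: CellTrack) -> float:
    """Total path length in µm: sum of Euclidean step distances."""
    _require_samples(track)
    return float(np.sum(np.linalg.norm(np.diff(track.xy, axis=0), axis=1)))


def distance_from_origin(track: CellTrack) -> float:
    """Net start-to-end Euclidean displacement in µm (always <= path length)."""
    _require_samples(track)
    return float(np.linalg.norm(track.xy[-1] - track.xy[0]))


def average_velocity(track: CellTrack, mode: str = "path") -> float:
    """Average velocity in µm/h.

    ``mode='path'`` (default) divides total path length by elapsed time,
    the convention of cell-tracking software when path length is reported
    alongside; ``mode='net'`` divides the start-to-end displacement
    instead.
    """
    _require_samples(track)
    if track.duration_s <= 0:
        raise UndefinedMetricError(f"track {track.id}: zero duration")
    num = path_length(track) if mode == "path" else distance_from_origin(track)
    if mode not in ("path", "net"):
        raise ValueError(f"unknown velocity mode {mode!r}")
    return num / (track.duration_s / 3600.0)


def elliptical_factor(width_um: float, length_um: float) -> float:
    """Cell width divided by length: a shape polarity index in (0, 1].

    Width is the minor axis by convention; swapped inputs are corrected
    with a warning.
    """
    if width_um <= 0 or length_um <= 0:
        raise UndefinedMetricError("width and length must be positive")
    if width_um > length_um:
        warnings.warn("width > length; swapping (width is the minor axis)",
                      stacklevel=2)
        width_um, length_um = length_um, width_um
    return width_um / length_um


def migration_angle(track: CellTrack, spot: SpotGeometry) -> float:
    """Unsigned angle (degrees, 0-180) between the track's origin-to-endpoint
    vector and the perpendicular to the spot edge at the origin."""
    _require_samples(track)
    v = track.xy[-1] - track.xy[0]
    norm = np.linalg.norm(v)
    if norm == 0:
        raise UndefinedMetricError(f"track {track.id}: zero net displacement")
    u = spot.perpendicular_at(track.xy[0])
    cosang = np.clip(np.dot(v / norm, u), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def percent_decrease(control_mean: float, treated_mean: float) -> float:
    """100 x (control - treated) / control; negative if treated exceeds control."""
    if control_mean <= 0:
        raise UndefinedMetricError("control mean must be positive")
    return 100.0 * (control_mean - treated_mean) / control_mean


def wound_distance(edge_t0: np.ndarray, edge_t1: np.ndarray) -> float:
    """Mean distance advanced between paired wound-edge measurement points.

    Accepts paired 1-D perpendicular positions or paired (n, 2) point
    coordinates in µm.
    """
    a = np.asarray(edge_t0, dtype=float)
    b = np.asarray(edge_t1, dtype=float)
    if a.shape != b.shape:
        raise ValueError("edge traces must have paired, equal-length points")
    if a.size == 0:
        raise UndefinedMetricError("no measurement points")
    if a.ndim == 1:
        return float(np.mean(np.abs(b - a)))
    return float(np.mean(np.linalg.norm(b - a, axis=1)))


def summarize_tracks(tracks: Iterable[CellTrack], spot: SpotGeometry,
                     velocity_mode: str = "path") -> pd.DataFrame:
    """Per-track metric table (one row per track).

    Columns: id, migrated, path_um, distance_um, velocity_um_h,
    elliptical_factor (mean over frames where shape is present),
    angle_deg (NaN for zero-displacement tracks).
    """
    mig = migrated_ids(list(tracks := list(tracks)), spot)
    rows = []
    for tr in tracks:
        ef = np.nan
        if tr.width_um is not None and tr.length_um is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ef = float(np.mean([elliptical_factor(w, l) for w, l
                                    in zip(tr.width_um, tr.length_um)]))
        try:
            ang = migration_angle(tr, spot)
        except UndefinedMetricError:
            ang = np.nan
        rows.append({
            "id": tr.id,
            "migrated": tr.id in mig,
            "path_um": path_length(tr),
            "distance_um": distance_from_origin(tr),
            "velocity_um_h": average_velocity(tr, mode=velocity_mode),
            "elliptical_factor": ef,
            "angle_deg": ang,
        })
    return pd.DataFrame(rows)
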
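"""Punctum detection, linking, fate classification and event calling.

Diffraction-limited spots ("clusters") are detected per frame by
scale-normalised Laplacian-of-Gaussian filtering with a threshold relative
to the robust noise level, refined to sub-pixel accuracy by
intensity-weighted centroiding, and linked over time by greedy
nearest-neighbour matching with bounded gap closing.

A linked track is classified as *static*, *laterally mobile* or
*disappearing*; a disappearance is accepted as an internalisation event
only if three criteria all hold: the intensity falls from its pre-event
plateau to background rapidly (within 10 frames), no punctum reappears
near the same position within 10 frames, and the loss is not attributable
to global photobleaching (cell-wide mean intensity stable to within 10%
over the event window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import DisappearanceEvent, Punctum, PunctaTrack, TimelapseStack
from .regions import RegionPartition, REGION_NAMES, assign_region, density_per_region

# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def _robust_sigma(arr: np.ndarray) -> float:
    """Noise sd via the median absolute deviation (Gaussian-consistent)."""
    med = np.median(arr)
    return float(1.4826 * np.median(np.abs(arr - med)))


def detect_puncta(frame: np.ndarray, sigma_px: float = 1.5,
                  threshold_sigma: float = 5.0, min_separation_px: int = 3,
                  saturation: float | None = None) -> list[Punctum]:
    """Detect diffraction-limited puncta in one frame.

    The frame is filtered with a scale-normalised LoG at ``sigma_px``;
    local maxima of the response exceeding ``threshold_sigma`` times the
    robust response noise are kept and refined by intensity-weighted
    centroiding of the background-subtracted neighbourhood.
    """
    img = np.asarray(frame, dtype=float)
    if saturation is not None and np.mean(img >= saturation) > 0.01:
        warnings.warn("frame appears saturated; detection proceeds", stacklevel=2)
    resp = -ndimage.gaussian_laplace(img, sigma_px) * sigma_px ** 2
    noise = _robust_sigma(resp)
    if noise == 0:
        return []
    thr = threshold_sigma * noise
    from skimage.feature import peak_local_max

    peaks = peak_local_max(resp, min_distance=min_separation_px,
                           threshold_abs=thr, exclude_border=2)
    bg_global = float(np.median(img))
    out = []
    h, w = img.shape
    r = max(int(round(2 * sigma_px)), 2)
    for row, col in peaks:
        y0, y1 = max(row - r, 0), min(row + r + 1, h)
        x0, x1 = max(col - r, 0), min(col + r + 1, w)
        patch = img[y0:y1, x0:x1]
        # local background from a wider window's median
        yb0, yb1 = max(row - 3 * r, 0), min(row + 3 * r + 1, h)
        xb0, xb1 = max(col - 3 * r, 0), min(col + 3 * r + 1, w)
        bg = float(np.median(img[yb0:yb1, xb0:xb1]))
        wgt = np.clip(patch - bg, 0, None)
        tot = wgt.sum()
        if tot <= 0:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        cy = float((wgt * ys).sum() / tot)
        cx = float((wgt * xs).sum() / tot)
        peak = float(patch.max())
        if peak <= bg:
            continue
        out.append(Punctum(frame=0, x_px=cx, y_px=cy, intensity=peak,
                           background=bg if bg < peak else bg_global,
                           radius_px=sigma_px))
    return out


def detect_stack(stack: TimelapseStack, channel: int = 0,
                 sigma_px: float = 1.5, threshold_sigma: float = 5.0,
                 min_separation_px: int = 3) -> pd.DataFrame:
    """Run :func:`detect_puncta` on every frame; tidy detection table."""
    rows = []
    for t in range(stack.n_frames):
        for p in detect_puncta(stack.frame(t, channel), sigma_px=sigma_px,
                               threshold_sigma=threshold_sigma,
                               min_separation_px=min_separation_px):
            rows.append({"frame": t, "x_px": p.x_px, "y_px": p.y_px,
                         "intensity": p.intensity, "background": p.background})
    return pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "intensity",
                                       "background"])


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------


def link_puncta(detections: pd.DataFrame, max_step_px: float = 3.0,
                max_gap: int = 2, n_frames: int | None = None
                ) -> list[PunctaTrack]:
    """Greedy nearest-neighbour linking of per-frame detections.

    Open track ends may bridge up to ``max_gap`` missing frames; the
    allowed step grows linearly with the bridged gap.  Ambiguous matches
    are resolved by smallest distance, then lowest track id.
    """
    if detections.empty:
        return []
    if n_frames is None:
        n_frames = int(detections["frame"].max()) + 1

    open_tracks: list[dict] = []   # {'id', 'frames', 'x', 'y', 'i', 'b'}
    closed: list[dict] = []
    next_id = 0
    for t in range(n_frames):
        dets = detections[detections["frame"] == t]
        xy = dets[["x_px", "y_px"]].to_numpy(dtype=float)
        # expire stale tracks
        still = []
        for tr in open_tracks:
            (closed if t - tr["frames"][-1] > max_gap else still).append(tr)
        open_tracks = still
        assigned_det: set[int] = set()
        assigned_trk: set[int] = set()
        if len(xy) and open_tracks:
            cand = []
            for ti, tr in enumerate(open_tracks):
                gap = t - tr["frames"][-1]
                limit = max_step_px * gap
                last = np.array([tr["x"][-1], tr["y"][-1]])
                d = np.linalg.norm(xy - last, axis=1)
                for di in np.flatnonzero(d <= limit):
                    cand.append((d[di], tr["id"], ti, int(di)))
            for dist, _tid, ti, di in sorted(cand):
                if ti in assigned_trk or di in assigned_det:
                    continue
                assigned_trk.add(ti)
                assigned_det.add(di)
                tr = open_tracks[ti]
                row = dets.iloc[di]
                tr["frames"].append(t)
                tr["x"].append(float(row["x_px"]))
                tr["y"].append(float(row["y_px"]))
                tr["i"].append(float(row["intensity"]))
                tr["b"].append(float(row["background"]))
        for di in range(len(xy)):
            if di in assigned_det:
                continue
            row = dets.iloc[di]
            open_tracks.append({"id": next_id, "frames": [t],
                                "x": [float(row["x_px"])], "y": [float(row["y_px"])],
                                "i": [float(row["intensity"])],
                                "b": [float(row["background"])]})
            next_id += 1
    closed.extend(open_tracks)
    closed.sort(key=lambda tr: tr["id"])
    return [PunctaTrack(id=tr["id"], frames=np.array(tr["frames"]),
                        x_px=np.array(tr["x"]), y_px=np.array(tr["y"]),
                        intensity=np.array(tr["i"]), background=np.array(tr["b"]))
            for tr in closed]


# ---------------------------------------------------------------------------
# Fate classification
# ---------------------------------------------------------------------------


def _sample_amp(stack_ch: np.ndarray, t: int, x: float, y: float,
                frame_bg: np.ndarray) -> float:
    """Background-subtracted 3x3 mean intensity at (x, y) in frame t."""
    h, w = stack_ch.shape[1:]
    row = int(np.clip(round(y), 1, h - 2))
    col = int(np.clip(round(x), 1, w - 2))
    return float(stack_ch[t, row - 1:row + 2, col - 1:col + 2].mean()
                 - frame_bg[t])


def classify_fate(track: PunctaTrack, stack: TimelapseStack, channel: int = 0,
                  lateral_threshold_um: float = 0.5) -> str:
    """Classify a linked track as static / lateral / disappearing / censored.

    Lateral: net displacement >= threshold.  A track that survives to the
    final frame is static (or lateral).  A track that ends early is
    *disappearing* if the intensity at its terminal position has fallen to
    background in the following frame, else *censored* (lost for reasons
    other than a clean disappearance).
    """
    ch = stack.channel(channel)
    if track.net_displacement_um(stack.pixel_size_um) >= lateral_threshold_um:
        return "lateral"
    if track.last_frame >= stack.n_frames - 1:
        return "static"
    frame_bg = np.median(ch, axis=(1, 2))
    noise = _robust_sigma(ch[0]) / 3.0   # sd of a 3x3 mean
    t_next = range(track.last_frame + 1,
                   min(track.last_frame + 3, stack.n_frames))
    amp = np.mean([_sample_amp(ch, t, track.end_xy[0], track.end_xy[1],
                               frame_bg) for t in t_next])
    return "disappearing" if amp <= 3.0 * noise else "censored"


def classify_all(tracks: list[PunctaTrack], stack: TimelapseStack,
                 channel: int = 0, lateral_threshold_um: float = 0.5
                 ) -> list[PunctaTrack]:
    for tr in tracks:
        tr.fate = classify_fate(tr, stack, channel, lateral_threshold_um)
    return tracks


# ---------------------------------------------------------------------------
# Disappearance-event calling
# ---------------------------------------------------------------------------


@dataclass
class EventCriteria:
    """Tunable parameters of the three-criterion event caller."""

    window: int = 10                 # frames, inclusive from plateau departure
    reappear_radius_px: float = 3.0
    bleach_tolerance: float = 0.10   # max fractional cell-wide decline
    plateau_fraction: float = 0.9    # departure threshold on the plateau
    floor_noise_mult: float = 2.0    # background+noise floor in smoothed sds
    min_track_frames: int = 3        # a spot must persist before it can vanish


def evaluate_disappearance(track: PunctaTrack, stack: TimelapseStack,
                           detections: pd.DataFrame, channel: int = 0,
                           criteria: EventCriteria | None = None,
                           cell_mask: np.ndarray | None = None
                           ) -> DisappearanceEvent | None:
    """Evaluate the three disappearance criteria for one track.

    Returns a :class:`DisappearanceEvent` carrying the individual criterion
    flags (whether or not all pass), or ``None`` if the track ends too
    close to the end of the stack for the reappearance window to be
    evaluated (censored).
    """
    crit = criteria or EventCriteria()
    ch = stack.channel(channel)
    nt = stack.n_frames
    e_last = track.last_frame
    if e_last >= nt - crit.window:
        return None  # censored: reappearance window extends past the stack
    if len(track) < crit.min_track_frames:
        return None  # too short-lived to distinguish from a noise blip

    frame_bg = np.median(ch, axis=(1, 2))
    # background-subtracted amplitude sampled at the track position every
    # frame (terminal position after the track ends)
    t_max = min(e_last + crit.window + 1, nt)
    amp = np.empty(t_max)
    pos_by_frame = dict(zip(track.frames.tolist(),
                            zip(track.x_px.tolist(), track.y_px.tolist())))
    x_cur, y_cur = track.x_px[0], track.y_px[0]
    for t in range(t_max):
        if t in pos_by_frame:
            x_cur, y_cur = pos_by_frame[t]
        amp[t] = _sample_amp(ch, t, x_cur, y_cur, frame_bg)
    # 3-frame moving average damps single-frame noise
    smooth = np.convolve(amp, np.ones(3) / 3.0, mode="same") if len(amp) >= 3 else amp

    sigma_amp = _robust_sigma(ch[0]) / 3.0
    sigma_smooth = sigma_amp / np.sqrt(3.0)
    plateau = float(np.percentile(amp[:e_last + 1], 75))
    floor = max(crit.floor_noise_mult * sigma_smooth, 0.1 * plateau)

    hi_idx = np.flatnonzero(smooth[:t_max] >= crit.plateau_fraction * plateau)
    t_hi = int(hi_idx[-1]) if len(hi_idx) else int(track.frames[0])
    lo_after = np.flatnonzero(smooth[t_hi + 1:t_max] <= floor)
    if len(lo_after):
        t_lo = t_hi + 1 + int(lo_after[0])
        rapid = (t_lo - t_hi) <= crit.window
    else:
        rapid = False

    # reappearance: any detection near the terminal position in the window
    # after the last bright frame
    t0, t1 = e_last + 1, e_last + crit.window
    nearby = detections[(detections["frame"] >= t0) & (detections["frame"] <= t1)]
    if len(nearby):
        d = np.linalg.norm(nearby[["x_px", "y_px"]].to_numpy(dtype=float)
                           - track.end_xy, axis=1)
        no_reappearance = not bool(np.any(d <= crit.reappear_radius_px))
    else:
        no_reappearance = True

    # photobleaching control: cell-wide mean intensity across the event window
    if cell_mask is not None:
        glob = ch[:, cell_mask].mean(axis=1)
    else:
        glob = ch.mean(axis=(1, 2))
    before = float(glob[max(t_hi - crit.window + 1, 0):t_hi + 1].mean())
    after = float(glob[t_hi + 1:min(t_hi + crit.window + 1, nt)].mean())
    not_photobleaching = (before - after) / max(before, 1e-12) <= crit.bleach_tolerance

    return DisappearanceEvent(track_id=track.id, frame=e_last + 1,
                              x_px=float(track.end_xy[0]),
                              y_px=float(track.end_xy[1]),
                              rapid=bool(rapid),
                              no_reappearance=bool(no_reappearance),
                              not_photobleaching=bool(not_photobleaching))


def call_disappearance(track: PunctaTrack, stack: TimelapseStack,
                       detections: pd.DataFrame, channel: int = 0,
                       criteria: EventCriteria | None = None,
                       cell_mask: np.ndarray | None = None
                       ) -> DisappearanceEvent | None:
    """Emit an event only if all three criteria hold (else ``None``)."""
    ev = evaluate_disappearance(track, stack, detections, channel, criteria,
                                cell_mask)
    return ev if ev is not None and ev.accepted else None


def call_events(tracks: list[PunctaTrack], stack: TimelapseStack,
                detections: pd.DataFrame, channel: int = 0,
                criteria: EventCriteria | None = None,
                cell_mask: np.ndarray | None = None,
                lateral_threshold_um: float = 0.5) -> list[DisappearanceEvent]:
    """Classify fates and call accepted disappearance events for all tracks."""
    classify_all(tracks, stack, channel, lateral_threshold_um)
    events = []
    for tr in tracks:
        if tr.fate != "disappearing":
            continue
        ev = call_disappearance(tr, stack, detections, channel, criteria,
                                cell_mask)
        if ev is not None:
            events.append(ev)
    return events


# ---------------------------------------------------------------------------
# Per-region statistics
# ---------------------------------------------------------------------------


def events_per_region(events: list[DisappearanceEvent],
                      partition: RegionPartition, pixel_size_um: float,
                      tracks: list[PunctaTrack] | None = None) -> pd.DataFrame:
    """Per-region event counts, area-normalised densities and (optionally)
    events as a fraction of total spots in each region."""
    counts = {name: 0 for name in REGION_NAMES}
    for ev in events:
        reg = assign_region((ev.x_px * pixel_size_um, ev.y_px * pixel_size_um),
                            partition)
        ev.region = reg
        if reg in counts:
            counts[reg] += 1
    dens = density_per_region(counts, partition)
    rows = []
    spot_counts = None
    if tracks is not None:
        spot_counts = {name: 0 for name in REGION_NAMES}
        for tr in tracks:
            reg = assign_region((tr.x_px[0] * pixel_size_um,
                                 tr.y_px[0] * pixel_size_um), partition)
            if reg in spot_counts:
                spot_counts[reg] += 1
    for name in REGION_NAMES:
        row = dict(region=name, **dens[name])
        if spot_counts is not None:
            tot = spot_counts[name]
            row["total_spots"] = tot
            row["event_fraction"] = counts[name] / tot if tot else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def dynamic_fraction(tracks: list[PunctaTrack], partition: RegionPartition,
                     pixel_size_um: float, first_frame_only: bool = True
                     ) -> pd.DataFrame:
    """Fraction of spots with a dynamic fate (lateral or disappearing) per
    region, following each spot present in the first frame when
    ``first_frame_only`` is set; per-area dynamic densities included."""
    sel = [tr for tr in tracks
           if not first_frame_only or tr.frames[0] == 0]
    totals = {name: 0 for name in REGION_NAMES}
    dynamic = {name: 0 for name in REGION_NAMES}
    for tr in sel:
        reg = assign_region((tr.x_px[0] * pixel_size_um,
                             tr.y_px[0] * pixel_size_um), partition)
        if reg not in totals:
            continue
        totals[reg] += 1
        if tr.fate in ("lateral", "disappearing"):
            dynamic[reg] += 1
    rows = []
    for name in REGION_NAMES:
        area = partition.areas_um2[name]
        rows.append({
            "region": name,
            "total_spots": totals[name],
            "dynamic_spots": dynamic[name],
            "dynamic_fraction": dynamic[name] / totals[name] if totals[name]
            else np.nan,
            "dynamic_per_um2": dynamic[name] / area,
        })
    return pd.DataFrame(rows)
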
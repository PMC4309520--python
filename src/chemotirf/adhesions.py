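"""Focal-adhesion detection, per-region counts, disassembly kinetics and
clathrin-recruitment testing.

Adhesions are segmented by background-subtracted thresholding with a size
filter, linked across frames by centroid proximity, and their
background-subtracted integrated intensity is traced over the full stack
so the disassembly decline can be followed below the detection threshold.
Disassembly time runs from the last frame at >= 90% of the pre-decline
plateau to the first frame at background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import dilation, disk

from .core import DisassemblyMeasurement, FocalAdhesion, TimelapseStack
from .regions import RegionPartition, REGION_NAMES, assign_region, density_per_region


def _robust_sigma(arr: np.ndarray) -> float:
    med = np.median(arr)
    return float(1.4826 * np.median(np.abs(arr - med)))


def _segment_frame(img: np.ndarray, pixel_size_um: float, smooth_sigma: float,
                   threshold_sigma: float, min_area_um2: float,
                   max_area_um2: float):
    sm = ndimage.gaussian_filter(np.asarray(img, dtype=float), smooth_sigma)
    bg = float(np.median(sm))
    noise = _robust_sigma(sm)
    mask = sm > bg + threshold_sigma * noise
    lbl = sk_label(mask)
    px_area = pixel_size_um ** 2
    objs = []
    for rp in regionprops(lbl, intensity_image=img):
        area = rp.area * px_area
        if not (min_area_um2 <= area <= max_area_um2):
            continue
        objs.append(rp)
    return objs, bg


def detect_fas(stack: TimelapseStack, channel: int = 0,
               smooth_sigma: float = 1.0, threshold_sigma: float = 4.0,
               min_area_um2: float = 0.25, max_area_um2: float = 15.0,
               link_radius_px: float = 5.0) -> list[FocalAdhesion]:
    """Detect and link focal adhesions across a (possibly 1-frame) stack.

    Per frame: Gaussian smoothing, threshold at background plus
    ``threshold_sigma`` robust noise sds, connected components within the
    size window.  Objects are linked frame-to-frame by centroid proximity;
    each adhesion's reference footprint (union of its detected masks) is
    used to integrate background-subtracted intensity over every frame of
    the stack.
    """
    ch = stack.channel(channel)
    px = stack.pixel_size_um
    tracks: list[dict] = []
    for t in range(stack.n_frames):
        objs, _bg = _segment_frame(ch[t], px, smooth_sigma, threshold_sigma,
                                   min_area_um2, max_area_um2)
        cents = np.array([[o.centroid[1], o.centroid[0]] for o in objs]) \
            if objs else np.empty((0, 2))
        open_idx = [i for i, tr in enumerate(tracks) if tr["last"] == t - 1]
        used = set()
        if len(cents) and open_idx:
            cand = []
            for i in open_idx:
                d = np.linalg.norm(cents - tracks[i]["centroid"], axis=1)
                for j in np.flatnonzero(d <= link_radius_px):
                    cand.append((d[j], i, int(j)))
            taken_tr = set()
            for dist, i, j in sorted(cand):
                if i in taken_tr or j in used:
                    continue
                taken_tr.add(i)
                used.add(j)
                tr = tracks[i]
                tr["frames"].append(t)
                tr["last"] = t
                tr["centroid"] = cents[j]
                tr["mask"] |= _obj_mask(objs[j], ch.shape[1:])
        for j, o in enumerate(objs):
            if j in used:
                continue
            tracks.append({
                "frames": [t], "last": t, "centroid": cents[j],
                "first_obj": o, "mask": _obj_mask(o, ch.shape[1:]),
            })

    frame_bg = np.median(ch, axis=(1, 2))
    out = []
    for i, tr in enumerate(tracks):
        o = tr["first_obj"]
        m = tr["mask"]
        trace = np.array([(ch[t][m] - frame_bg[t]).sum()
                          for t in range(stack.n_frames)])
        out.append(FocalAdhesion(
            id=i, centroid_px=(o.centroid[1], o.centroid[0]),
            major_axis_px=float(o.axis_major_length),
            minor_axis_px=float(max(o.axis_minor_length, 1e-6)),
            orientation_rad=float(o.orientation),
            frames=np.array(tr["frames"]), intensity=trace, mask=m,
            area_um2=float(m.sum()) * px ** 2))
    return out


def _obj_mask(rp, shape: tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    r0, c0, r1, c1 = rp.bbox
    m[r0:r1, c0:c1] = rp.image
    return m


def count_fas_per_region(fas: list[FocalAdhesion], partition: RegionPartition,
                         pixel_size_um: float) -> pd.DataFrame:
    """Adhesion counts by centroid region with area-normalised densities."""
    counts = {name: 0 for name in REGION_NAMES}
    for fa in fas:
        reg = assign_region(fa.centroid_um(pixel_size_um), partition)
        if reg in counts:
            counts[reg] += 1
    dens = density_per_region(counts, partition)
    return pd.DataFrame([dict(region=name, **dens[name])
                         for name in REGION_NAMES])


def disassembly_time(fa: FocalAdhesion, frame_interval_s: float,
                     stable_window: int = 10, plateau_fraction: float = 0.9,
                     noise_mult: float = 2.0) -> DisassemblyMeasurement | None:
    """Disassembly timing from the integrated-intensity trace.

    Plateau is the median of the initial stable window; onset is the last
    frame at >= ``plateau_fraction`` of the plateau; end is the first
    subsequent frame at or below the noise floor (``noise_mult`` times the
    robust sd of the post-end residual intensity scale).  Returns ``None``
    (censored) if the trace never falls to background.
    """
    trace = np.asarray(fa.intensity, dtype=float)
    if len(trace) < 3:
        return None
    plateau = float(np.median(trace[:max(stable_window, 2)]))
    if plateau <= 0:
        return None
    # noise floor: robust sd of the frame-to-frame trace increments
    sigma = _robust_sigma(np.diff(trace)) / np.sqrt(2.0)
    floor = max(noise_mult * sigma, 0.02 * plateau)
    below = np.flatnonzero(trace <= floor)
    below = below[below > 0]
    if len(below) == 0:
        return None
    end = int(below[0])
    hi = np.flatnonzero(trace[:end] >= plateau_fraction * plateau)
    if len(hi) == 0:
        return None
    onset = int(hi[-1])
    if end <= onset:
        return None
    return DisassemblyMeasurement(
        fa_id=fa.id, onset_frame=onset, end_frame=end,
        time_min=(end - onset) * frame_interval_s / 60.0)


def clathrin_at_fa(fas: list[FocalAdhesion], puncta_xy: np.ndarray,
                   radius_px: float = 2.0,
                   puncta_frames: np.ndarray | None = None,
                   measurements: dict[int, DisassemblyMeasurement] | None = None
                   ) -> pd.DataFrame:
    """Punctum occupancy of adhesion footprints.

    An adhesion is *positive* if any punctum centroid falls within its
    footprint dilated by ``radius_px``.  When per-punctum frames and
    disassembly measurements are supplied, a ``recruited`` flag records
    positivity specifically during the disassembly window.
    """
    pts = np.asarray(puncta_xy, dtype=float).reshape(-1, 2)
    selem = disk(int(round(radius_px)))
    rows = []
    for fa in fas:
        dil = dilation(fa.mask, selem)
        h, w = dil.shape
        inside = np.zeros(len(pts), dtype=bool)
        if len(pts):
            cols = np.round(pts[:, 0]).astype(int).clip(0, w - 1)
            rowsi = np.round(pts[:, 1]).astype(int).clip(0, h - 1)
            inside = dil[rowsi, cols]
        positive = bool(inside.any())
        recruited = None
        if measurements is not None and puncta_frames is not None:
            meas = measurements.get(fa.id)
            if meas is not None:
                fr = np.asarray(puncta_frames)
                in_window = (fr >= meas.onset_frame) & (fr <= meas.end_frame)
                recruited = bool(np.any(inside & in_window))
        rows.append({"fa_id": fa.id, "positive": positive,
                     "n_puncta_inside": int(inside.sum()),
                     "recruited": recruited})
    return pd.DataFrame(rows)


def compare_disassembly(groups: dict[str, list[DisassemblyMeasurement]],
                        test: str = "mannwhitney") -> pd.DataFrame:
    """Group means, dispersion and a two-sample test versus the first group.

    Mann-Whitney U by default (robust to the non-normal timing
    distributions typical of these assays); Welch's t by
    ``test='welch'``.  Requires >= 2 groups of >= 3 measurements each.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = list(groups)
    times = {k: np.array([m.time_min for m in v]) for k, v in groups.items()}
    for k, v in times.items():
        if len(v) < 3:
            raise ValueError(f"group {k!r} has fewer than 3 measurements")
    ref = times[names[0]]
    rows = []
    for k in names:
        v = times[k]
        if k == names[0]:
            p = np.nan
        elif test == "mannwhitney":
            p = float(stats.mannwhitneyu(ref, v, alternative="two-sided").pvalue)
        elif test == "welch":
            p = float(stats.ttest_ind(ref, v, equal_var=False).pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({"group": k, "n": len(v), "mean_min": float(v.mean()),
                     "sem_min": float(v.std(ddof=1) / np.sqrt(len(v))),
                     "p_vs_first": p})
    return pd.DataFrame(rows)
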
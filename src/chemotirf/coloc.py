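"""Colocalisation statistics and kymographs.

Two procedures: object-based colocalisation of circled clusters with a
shifted-region chance control (a sampled set of channel-A puncta is scored
for a channel-B punctum within a radius, then the same circles are
displaced to vacant positions to estimate the chance level), and the
pixel-shift Pearson correlation profile (the Pearson coefficient of the
two channels as one is translated one pixel at a time, which peaks at zero
shift for genuinely colocalised signals).  Kymographs sample intensity
along a fixed line through the stack, one position-by-time matrix per
channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .core import Punctum, TimelapseStack


def _as_xy(points) -> np.ndarray:
    if len(points) == 0:
        return np.empty((0, 2))
    if isinstance(points[0], Punctum):
        return np.array([[p.x_px, p.y_px] for p in points], dtype=float)
    return np.asarray(points, dtype=float).reshape(-1, 2)


@dataclass
class ColocResult:
    """Result of the circled-cluster colocalisation procedure."""

    n_query: int
    n_colocalised: int
    fraction: float
    radius_px: float
    control_fraction: float | None = None
    query_xy: np.ndarray | None = None    # the sampled circle centres

    def to_dict(self) -> dict:
        return {"n_query": self.n_query, "n_colocalised": self.n_colocalised,
                "fraction": self.fraction, "radius_px": self.radius_px,
                "control_fraction": self.control_fraction}


def circle_colocalisation(queries, targets, radius_px: float = 3.0,
                          n: int = 50,
                          rng: np.random.Generator | None = None) -> ColocResult:
    """Object colocalisation of ``n`` sampled query puncta against targets.

    ``n`` query puncta are sampled without replacement (all used, with the
    actual count recorded, if fewer are available); a query colocalises if
    any target centroid lies within ``radius_px`` of it.
    """
    rng = rng or np.random.default_rng()
    q = _as_xy(queries)
    t = _as_xy(targets)
    if len(q) == 0:
        raise ValueError("no query puncta")
    if len(q) > n:
        q = q[rng.choice(len(q), size=n, replace=False)]
    if len(t) == 0:
        return ColocResult(n_query=len(q), n_colocalised=0, fraction=0.0,
                           radius_px=radius_px, query_xy=q)
    d, _ = cKDTree(t).query(q, k=1)
    hit = int(np.sum(d <= radius_px))
    return ColocResult(n_query=len(q), n_colocalised=hit,
                       fraction=hit / len(q), radius_px=radius_px, query_xy=q)


def shifted_control(queries, targets, radius_px: float = 3.0,
                    n: int = 50, rng: np.random.Generator | None = None,
                    shift_radii: tuple[float, float] = (2.0, 4.0),
                    max_retries: int = 50,
                    sampled_xy: np.ndarray | None = None) -> float:
    """Chance colocalisation from slightly displaced circles.

    Each sampled circle (the same set scored by
    :func:`circle_colocalisation` when ``sampled_xy`` is passed) is moved
    by a random vector of magnitude ``shift_radii`` times the radius to a
    position containing no query punctum, and the displaced circles are
    scored against the targets.  Circles with no valid displacement after
    bounded retries are skipped.
    """
    rng = rng or np.random.default_rng()
    q_all = _as_xy(queries)
    t = _as_xy(targets)
    if sampled_xy is not None:
        q = np.asarray(sampled_xy, dtype=float)
    else:
        q = q_all
        if len(q) > n:
            q = q[rng.choice(len(q), size=n, replace=False)]
    if len(q) == 0:
        raise ValueError("no query puncta")
    qtree = cKDTree(q_all)
    moved = []
    for center in q:
        for _ in range(max_retries):
            mag = rng.uniform(*shift_radii) * radius_px
            phi = rng.uniform(0.0, 2.0 * np.pi)
            cand = center + mag * np.array([np.cos(phi), np.sin(phi)])
            if len(qtree.query_ball_point(cand, radius_px)) == 0:
                moved.append(cand)
                break
    if not moved:
        return 0.0
    moved = np.asarray(moved)
    if len(t) == 0:
        return 0.0
    d, _ = cKDTree(t).query(moved, k=1)
    return float(np.mean(d <= radius_px))


def coloc_with_control(queries, targets, radius_px: float = 3.0, n: int = 50,
                       rng: np.random.Generator | None = None) -> ColocResult:
    """Circled-cluster fraction plus the shifted-circle chance control,
    using the same sampled circles for both."""
    rng = rng or np.random.default_rng()
    res = circle_colocalisation(queries, targets, radius_px, n, rng)
    res.control_fraction = shifted_control(queries, targets, radius_px, n, rng,
                                           sampled_xy=res.query_xy)
    return res


# ---------------------------------------------------------------------------
# Pixel-shift Pearson profile
# ---------------------------------------------------------------------------


@dataclass
class PearsonShiftProfile:
    shifts: np.ndarray     # integer pixel offsets applied to channel B
    r: np.ndarray          # Pearson coefficient per shift (NaN if undefined)
    axis: str = "x"

    @property
    def r_at_zero(self) -> float:
        return float(self.r[np.flatnonzero(self.shifts == 0)[0]])


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def pearson_shift_profile(img_a: np.ndarray, img_b: np.ndarray,
                          max_shift: int = 10, axis: str = "x"
                          ) -> PearsonShiftProfile:
    """Pearson r of the overlap region as channel B is shifted -k..k px.

    Colocalised channels show a peak at zero decaying with |shift|;
    a constant image yields NaN coefficients.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    shifts = np.arange(-max_shift, max_shift + 1)
    rs = np.empty(len(shifts))
    for i, s in enumerate(shifts):
        if axis == "x":
            ov_a = a[:, max(-s, 0):a.shape[1] + min(-s, 0)]
            ov_b = b[:, max(s, 0):b.shape[1] + min(s, 0)]
        else:
            ov_a = a[max(-s, 0):a.shape[0] + min(-s, 0), :]
            ov_b = b[max(s, 0):b.shape[0] + min(s, 0), :]
        rs[i] = _pearson(ov_a, ov_b)
    return PearsonShiftProfile(shifts=shifts, r=rs, axis=axis)


# ---------------------------------------------------------------------------
# Kymograph
# ---------------------------------------------------------------------------


@dataclass
class Kymograph:
    """Intensity along a fixed line versus time, one matrix per channel.

    Each matrix has one row per sampled position (spacing = pixel size)
    and one column per frame of the window.
    """

    start_um: tuple[float, float]
    end_um: tuple[float, float]
    length_um: float
    duration_min: float
    matrices: list[np.ndarray] = field(default_factory=list)

    @property
    def n_positions(self) -> int:
        return self.matrices[0].shape[0]


def make_kymograph(stack: TimelapseStack, start_um: tuple[float, float],
                   end_um: tuple[float, float],
                   window: tuple[int, int] | None = None) -> Kymograph:
    """Bilinear line sampling per frame; positions spaced one pixel apart."""
    px = stack.pixel_size_um
    p0 = np.asarray(start_um, dtype=float) / px
    p1 = np.asarray(end_um, dtype=float) / px
    length_px = float(np.linalg.norm(p1 - p0))
    n_pos = max(int(round(length_px)), 2)
    frac = np.arange(n_pos) / n_pos
    xs = p0[0] + frac * (p1[0] - p0[0])
    ys = p0[1] + frac * (p1[1] - p0[1])
    h, w = stack.shape_px
    if (xs.min() < 0 or xs.max() > w - 1 or ys.min() < 0 or ys.max() > h - 1):
        raise ValueError("kymograph line exits the image")
    if window is None:
        window = (0, stack.n_frames)
    f0, f1 = window
    if not (0 <= f0 < f1 <= stack.n_frames):
        raise ValueError("kymograph window outside the stack")
    mats = []
    for c in range(stack.n_channels):
        mat = np.empty((n_pos, f1 - f0))
        for j, t in enumerate(range(f0, f1)):
            mat[:, j] = map_coordinates(stack.frame(t, c), [ys, xs], order=1)
        mats.append(mat)
    return Kymograph(start_um=tuple(start_um), end_um=tuple(end_um),
                     length_um=length_px * px,
                     duration_min=(f1 - f0) * stack.frame_interval_s / 60.0,
                     matrices=mats)
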
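"""Front/middle/back polarity partition of a migrating cell.

The migration axis is the perpendicular to the agarose-spot edge (pointing
into the spot, i.e. toward the front of the cell); the cell mask's extent
along this axis is divided into three equal lengths.  Counts of objects per
region are normalised to each region's area, since equal axial extents give
unequal areas on an irregular cell outline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import SpotGeometry

REGION_NAMES = ("front", "middle", "back")


@dataclass
class RegionPartition:
    """Three equal-length bands of a cell mask along the migration axis.

    ``axis`` points toward the spot interior (front).  ``boundaries`` are
    the two axis positions (µm) separating back|middle and middle|front.
    ``label_image`` uses 0=outside, 1=front, 2=middle, 3=back.
    """

    axis: np.ndarray
    boundaries: tuple[float, float]
    extent: tuple[float, float]
    label_image: np.ndarray
    pixel_size_um: float
    areas_um2: dict[str, float]

    @property
    def total_area_um2(self) -> float:
        return sum(self.areas_um2.values())


def partition_cell(cell_mask: np.ndarray, pixel_size_um: float,
                   spot: SpotGeometry) -> RegionPartition:
    """Partition a binary cell mask into front/middle/back bands.

    The mask's pixel coordinates are projected onto the migration axis
    (the spot-edge perpendicular evaluated at the mask centroid); the
    projected extent is split into three equal lengths, the frontmost band
    being nearest the spot interior.  Pixels exactly on a boundary are
    assigned frontward.  A disconnected mask is reduced to its largest
    connected component with a warning.
    """
    from scipy import ndimage

    mask = np.asarray(cell_mask).astype(bool)
    if not mask.any():
        raise ValueError("cell mask is empty")
    labeled, n_comp = ndimage.label(mask)
    if n_comp > 1:
        warnings.warn(f"cell mask has {n_comp} components; using the largest",
                      stacklevel=2)
        sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n_comp + 1))
        mask = labeled == (1 + int(np.argmax(sizes)))

    rows, cols = np.nonzero(mask)
    pts_um = np.column_stack([cols, rows]).astype(float) * pixel_size_um
    centroid = pts_um.mean(axis=0)
    axis = np.asarray(spot.perpendicular_at(centroid), dtype=float)

    s = pts_um @ axis
    smin, smax = float(s.min()), float(s.max())
    if smax <= smin:
        raise ValueError("cell mask has zero extent along the migration axis")
    third = (smax - smin) / 3.0
    b1, b2 = smin + third, smin + 2.0 * third  # back|middle, middle|front

    label_image = np.zeros(mask.shape, dtype=np.uint8)
    lab = np.where(s >= b2, 1, np.where(s >= b1, 2, 3))  # frontward tie-break
    label_image[rows, cols] = lab

    px_area = pixel_size_um ** 2
    areas = {name: float(np.count_nonzero(lab == i + 1)) * px_area
             for i, name in enumerate(REGION_NAMES)}
    return RegionPartition(axis=axis, boundaries=(b1, b2), extent=(smin, smax),
                           label_image=label_image, pixel_size_um=pixel_size_um,
                           areas_um2=areas)


def assign_region(point_um: tuple[float, float] | np.ndarray,
                  partition: RegionPartition) -> str:
    """Region label of a point (µm coordinates); 'outside' if off the mask."""
    p = np.asarray(point_um, dtype=float)
    col = int(round(p[0] / partition.pixel_size_um))
    row = int(round(p[1] / partition.pixel_size_um))
    h, w = partition.label_image.shape
    if not (0 <= row < h and 0 <= col < w) or partition.label_image[row, col] == 0:
        return "outside"
    s = float(p @ partition.axis)
    b1, b2 = partition.boundaries
    if s >= b2:
        return "front"
    if s >= b1:
        return "middle"
    return "back"


def density_per_region(counts: dict[str, int] | tuple[int, int, int],
                       partition: RegionPartition) -> dict[str, dict[str, float]]:
    """Area-normalised per-region densities (counts/µm²), raw counts retained."""
    if not isinstance(counts, dict):
        counts = dict(zip(REGION_NAMES, counts))
    out = {}
    for name in REGION_NAMES:
        area = partition.areas_um2[name]
        if area <= 0:
            raise ValueError(f"region {name!r} has zero area")
        c = float(counts.get(name, 0))
        out[name] = {"count": c, "area_um2": area, "density_per_um2": c / area}
    return out
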
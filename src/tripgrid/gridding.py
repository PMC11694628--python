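"""Trajectory segmentation, grid indexing, rotation augmentation, rasterization.

A trip of n per-second records is cut into overlapping windows of w records
(stride 1, so n - w + 1 segments). Each segment is shifted so its first
point becomes the local origin, projected to km offsets east/north, and
binned into integer grid cells of side ``cell_km``. The resulting index
sequence is rasterized into a G x G binary occupancy matrix — the input of
the convolutional stream — and optionally augmented with its 90/180/270
degree counterclockwise rotations.

Shift-to-origin makes the representation translation invariant; rotation
augmentation teaches the classifier orientation invariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geo import EARTH_RADIUS_KM

KM_PER_DEG = EARTH_RADIUS_KM * math.pi / 180.0  # meridian arc length per degree

ROTATION_ANGLES = (90, 180, 270)

__all__ = [
    "KM_PER_DEG",
    "ROTATION_ANGLES",
    "Segment",
    "GridIndexSequence",
    "OccupancyGrid",
    "GridOverflowError",
    "LocalProjection",
    "segment_trajectory",
    "shift_to_origin",
    "assign_grid_indices",
    "align_to_origin",
    "rotate_indices",
    "rasterize_occupancy",
    "augment_segment",
]


class GridOverflowError(ValueError):
    """Raised when a segment's grid bounding box exceeds the raster extent."""


@dataclass(frozen=True)
class LocalProjection:
    """Equirectangular projection from (lat, lon) degrees to km offsets.

    ``reference_lat_deg`` fixes the cos-latitude scale applied to longitude
    differences. Using one reference for a whole dataset (rather than each
    segment's own start latitude) makes grid indices *exactly* invariant
    under translation of a segment, because the degree-to-km scale then does
    not depend on where the segment sits. When None, the segment's first
    latitude is used (convenient for one-off segments, invariant only
    approximately).
    """

    reference_lat_deg: float | None = None
    radius_km: float = EARTH_RADIUS_KM

    def offsets(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        """(w, 2) array of (east_km, north_km) offsets from the first point."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        ref = self.reference_lat_deg if self.reference_lat_deg is not None else lat[0]
        k = self.radius_km * math.pi / 180.0
        east = (lon - lon[0]) * k * math.cos(math.radians(ref))
        north = (lat - lat[0]) * k
        return np.column_stack([east, north])


@dataclass(frozen=True)
class Segment:
    """A fixed-length window of consecutive records from one trip.

    ``records`` is a w-row slice of the trip's feature table (featurize_frame
    output); ``label`` is the driver-level weak label (0 normal, 1 abnormal)
    inherited by every segment of that driver.
    """

    records: pd.DataFrame
    driver_id: str
    trip_id: str
    label: int
    start_index: int
    window_w: int

    def __post_init__(self) -> None:
        if len(self.records) != self.window_w:
            raise ValueError(
                f"segment has {len(self.records)} records, expected w={self.window_w}"
            )


@dataclass(frozen=True)
class GridIndexSequence:
    """Ordered integer (x, y) grid cells visited by a segment.

    x indexes the longitude (east) axis, y the latitude (north) axis.
    The first index is (0, 0) by construction (shift-to-origin); later
    indices may be negative for travel west/south of the start.
    """

    indices: np.ndarray  # (w, 2) int array of (x, y)
    cell_size_km: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices)
        if idx.ndim != 2 or idx.shape[1] != 2:
            raise ValueError(f"indices must be (w, 2), got {idx.shape}")
        if self.cell_size_km <= 0:
            raise ValueError(f"cell_size_km must be positive, got {self.cell_size_km}")

    @property
    def occupied_cells(self) -> set[tuple[int, int]]:
        return {(int(x), int(y)) for x, y in self.indices}


@dataclass(frozen=True)
class OccupancyGrid:
    """G x G binary matrix of visited cells; matrix[y, x], row 0 southernmost."""

    matrix: np.ndarray
    extent_g: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.shape != (self.extent_g, self.extent_g):
            raise ValueError(f"matrix shape {m.shape} != ({self.extent_g}, {self.extent_g})")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("occupancy matrix entries must be 0 or 1")


def segment_trajectory(
    trip: pd.DataFrame,
    w: int,
    *,
    driver_id: str = "",
    trip_id: str = "",
    label: int = 0,
    stride: int = 1,
) -> list[Segment]:
    """Slide a w-record window over a trip; returns max(n - w + 1, 0) segments.

    The stride defaults to 1 (every offset), matching the segment-count law
    n - w + 1; larger strides exist only as a speedup for exploratory runs.
    """
    if w < 2:
        raise ValueError(f"window w must be >= 2, got {w}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    n = len(trip)
    return [
        Segment(
            records=trip.iloc[s : s + w],
            driver_id=driver_id,
            trip_id=trip_id,
            label=label,
            start_index=s,
            window_w=w,
        )
        for s in range(0, n - w + 1, stride)
    ]


def shift_to_origin(
    segment: Segment, projection: LocalProjection | None = None
) -> np.ndarray:
    """Local (east_km, north_km) offsets of each record from the segment start.

    The first row is exactly (0, 0); this is what makes the downstream grid
    representation translation invariant.
    """
    proj = projection or LocalProjection()
    return proj.offsets(
        segment.records["lat"].to_numpy(), segment.records["lon"].to_numpy()
    )


def assign_grid_indices(local_offsets: np.ndarray, c: float) -> GridIndexSequence:
    """Bin local km offsets into integer grid cells of side ``c`` km.

    index = floor(offset / c) per axis; the first index is (0, 0) because the
    first offset is the origin.
    """
    if c <= 0:
        raise ValueError(f"cell size c must be positive, got {c}")
    off = np.asarray(local_offsets, dtype=float)
    idx = np.floor(off / c).astype(np.int64)
    return GridIndexSequence(indices=idx, cell_size_km=float(c))


def align_to_origin(seq: GridIndexSequence) -> GridIndexSequence:
    """Translate indices so the minimum index per axis is 0."""
    idx = seq.indices - seq.indices.min(axis=0)
    return replace(seq, indices=idx)


def rotate_indices(seq: GridIndexSequence, angle: int) -> GridIndexSequence:
    """Rotate a grid-index sequence counterclockwise by 90, 180 or 270 degrees.

    90 degrees maps (x, y) -> (-y, x); the result is re-translated so the
    minimum index per axis is 0.
    """
    if angle not in ROTATION_ANGLES:
        raise ValueError(f"unsupported rotation angle {angle}; must be one of {ROTATION_ANGLES}")
    x, y = seq.indices[:, 0], seq.indices[:, 1]
    if angle == 90:
        rot = np.column_stack([-y, x])
    elif angle == 180:
        rot = np.column_stack([-x, -y])
    else:  # 270
        rot = np.column_stack([y, -x])
    return align_to_origin(replace(seq, indices=rot))


def rasterize_occupancy(seq: GridIndexSequence, extent_g: int) -> OccupancyGrid:
    """Rasterize an index sequence into a G x G binary occupancy matrix.

    The sequence is re-translated so its bounding box starts at (0, 0);
    matrix[y, x] = 1 for every visited cell (row 0 = southernmost). A
    bounding box larger than G x G raises GridOverflowError — callers drop
    and count such segments rather than clipping them.
    """
    if extent_g < 1:
        raise ValueError(f"extent_g must be >= 1, got {extent_g}")
    idx = align_to_origin(seq).indices
    span = idx.max(axis=0) + 1
    if span[0] > extent_g or span[1] > extent_g:
        raise GridOverflowError(
            f"segment spans {span[0]}x{span[1]} cells, exceeds extent {extent_g}"
        )
    m = np.zeros((extent_g, extent_g), dtype=np.uint8)
    m[idx[:, 1], idx[:, 0]] = 1
    return OccupancyGrid(matrix=m, extent_g=extent_g)


def augment_segment(seq: GridIndexSequence) -> list[GridIndexSequence]:
    """Identity plus the three counterclockwise rotations, origin-aligned."""
    return [align_to_origin(seq)] + [rotate_indices(seq, a) for a in ROTATION_ANGLES]
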
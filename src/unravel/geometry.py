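"""Streamline-to-voxel geometry: segment subdivision on an affine voxel grid.

Streamlines live in world (RAS) millimeter coordinates; the fixel field lives
on a voxel grid with an affine voxel-to-world transform. Each straight
streamline segment is split at voxel boundaries into intra-voxel subsegments
whose world-space lengths sum exactly to the segment length — these lengths
are the weights every downstream map accumulates.

Voxel convention: voxel (i, j, k) is the half-open box
[i-0.5, i+0.5) x [j-0.5, j+0.5) x [k-0.5, k+0.5) in voxel coordinates, i.e.
voxel centers sit at integer coordinates (the dominant neuroimaging
streamline convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["VoxelGrid", "Tract", "Subsegment", "split_segment", "split_tract"]

logger = logging.getLogger(__name__)

# pieces shorter than this fraction of the parent segment are dropped
_REL_LEN_EPS = 1e-12


@dataclass(frozen=True)
class VoxelGrid:
    """A voxel lattice with an invertible affine voxel-to-world transform."""

    shape: Tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        if len(self.shape) != 3 or any(n <= 0 for n in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        try:
            inv = np.linalg.inv(self.affine)
        except np.linalg.LinAlgError as exc:
            raise ValueError("affine is not invertible") from exc
        object.__setattr__(self, "_inv_affine", inv)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points to continuous voxel coordinates."""
        p = np.asarray(points, dtype=float)
        return p @ self._inv_affine[:3, :3].T + self._inv_affine[:3, 3]

    def voxel_to_world(self, coords: np.ndarray) -> np.ndarray:
        """Map continuous voxel coordinates to world mm."""
        c = np.asarray(coords, dtype=float)
        return c @ self.affine[:3, :3].T + self.affine[:3, 3]

    def contains(self, voxel: Sequence[int]) -> bool:
        return all(0 <= v < n for v, n in zip(voxel, self.shape))


@dataclass
class Tract:
    """An ordered set of streamlines (polylines in world mm).

    Consecutive duplicate points are removed on construction; streamlines left
    with fewer than two points are dropped with a warning. ``step_size`` is
    the nominal tractography step in mm and is informational only — no
    resampling is performed.
    """

    streamlines: List[np.ndarray]
    step_size: Optional[float] = None

    def __post_init__(self) -> None:
        cleaned: List[np.ndarray] = []
        n_dropped = 0
        for sl in self.streamlines:
            pts = np.asarray(sl, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 3:
                raise ValueError(f"streamline must be (N, 3), got {pts.shape}")
            if len(pts) > 1:
                keep = np.ones(len(pts), dtype=bool)
                keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
                pts = pts[keep]
            if len(pts) < 2:
                n_dropped += 1
                continue
            cleaned.append(pts)
        if n_dropped:
            logger.warning("dropped %d degenerate streamline(s) with < 2 distinct points", n_dropped)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass(frozen=True)
class Subsegment:
    """One intra-voxel piece of a straight streamline segment.

    ``direction`` is the (axial) unit direction of the parent segment in world
    space — identical for every piece of one segment; ``length`` is the piece's
    world-mm length restricted to its voxel.
    """

    voxel: Tuple[int, int, int]
    direction: np.ndarray
    length: float
    streamline_id: int = 0
    segment_id: int = 0
    in_volume: bool = True


def split_segment(
    p0: np.ndarray,
    p1: np.ndarray,
    grid: VoxelGrid,
    streamline_id: int = 0,
    segment_id: int = 0,
) -> List[Subsegment]:
    """Split the straight segment [p0, p1] (world mm) at voxel boundaries.

    Returns the ordered intra-voxel pieces; their lengths sum to |p1 - p0|.
    Pieces whose voxel lies outside ``grid.shape`` carry ``in_volume=False``.
    Identical endpoints yield an empty list.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    seg = p1 - p0
    seg_len = float(np.linalg.norm(seg))
    if seg_len == 0.0:
        return []
    direction = seg / seg_len

    a0 = grid.world_to_voxel(p0)
    a1 = grid.world_to_voxel(p1)
    d = a1 - a0

    # parameters t in (0, 1) where a voxel coordinate crosses a half-integer
    # boundary plane c = n + 0.5
    crossings: List[float] = []
    for ax in range(3):
        if d[ax] == 0.0:
            continue
        lo, hi = sorted((a0[ax], a1[ax]))
        first = np.floor(lo - 0.5) + 1.5  # smallest boundary value > lo
        for c in np.arange(first, hi, 1.0):
            t = (c - a0[ax]) / d[ax]
            if 0.0 < t < 1.0:
                crossings.append(float(t))

    ts = np.concatenate(([0.0], np.sort(crossings), [1.0])) if crossings else np.array([0.0, 1.0])

    pieces: List[Subsegment] = []
    for ta, tb in zip(ts[:-1], ts[1:]):
        if tb - ta <= _REL_LEN_EPS:
            continue
        tm = 0.5 * (ta + tb)
        voxel = tuple(int(v) for v in np.floor(a0 + tm * d + 0.5))
        length = (tb - ta) * seg_len
        if pieces and pieces[-1].voxel == voxel:
            prev = pieces.pop()  # tangential boundary touch: merge same-voxel neighbors
            length += prev.length
        pieces.append(
            Subsegment(
                voxel=voxel,
                direction=direction,
                length=length,
                streamline_id=streamline_id,
                segment_id=segment_id,
                in_volume=grid.contains(voxel),
            )
        )
    return pieces


def split_tract(tract: Tract, grid: VoxelGrid, keep_out_of_volume: bool = False) -> List[Subsegment]:
    """Split every segment of every streamline of a tract at voxel boundaries.

    Ordering is streamline-major, then along-streamline. Out-of-volume pieces
    are excluded (and logged) unless ``keep_out_of_volume`` is set.
    """
    if len(tract) == 0:
        raise ValueError("cannot split an empty tract")
    out: List[Subsegment] = []
    n_outside = 0
    for sid, sl in enumerate(tract.streamlines):
        n_in_before = len(out)
        for gid in range(len(sl) - 1):
            for piece in split_segment(sl[gid], sl[gid + 1], grid, sid, gid):
                if piece.in_volume or keep_out_of_volume:
                    out.append(piece)
                if not piece.in_volume:
                    n_outside += 1
        if len(out) == n_in_before:
            logger.warning("streamline %d contributed no in-volume subsegments", sid)
    if n_outside:
        logger.info("excluded %d out-of-volume subsegment(s)", n_outside)
    return out
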
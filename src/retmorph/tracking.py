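"""Centerline tracking: walk a vessel segment along the skeleton with A*.

The skeleton is treated as an 8-connected pixel graph with Euclidean step
costs (1 for axial moves, sqrt(2) for diagonal) and the straight-line
distance to the goal as the admissible heuristic, so the recovered path is a
true shortest path along the vessel centerline. Operator endpoints rarely
land exactly on the 1-px skeleton, so they are first snapped to the nearest
skeleton pixel.

Determinism: frontier ties are broken by (smaller heuristic, then row-major
pixel order), which makes the search — and therefore every downstream
measurement — fully reproducible.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import NoPathError, SnapError

__all__ = ["SegmentPath", "snap_to_skeleton", "track_segment", "path_length"]

_SQRT2 = math.sqrt(2.0)

# 8-neighborhood offsets in row-major scan order with per-step cost
_NEIGHBORS = [
    (-1, -1, _SQRT2), (-1, 0, 1.0), (-1, 1, _SQRT2),
    (0, -1, 1.0), (0, 1, 1.0),
    (1, -1, _SQRT2), (1, 0, 1.0), (1, 1, _SQRT2),
]


def path_length(points: np.ndarray) -> float:
    """Polyline length: sum of per-step Euclidean distances."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


@dataclass
class SegmentPath:
    """Ordered centerline pixel chain between two (snapped) endpoints."""

    points: np.ndarray  # (N, 2) int array of (row, col)
    vessel_class: str | None = None
    length: float = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=int)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (N, 2), got {pts.shape}")
        self.points = pts
        self.length = path_length(pts)

    def reversed(self) -> "SegmentPath":
        return SegmentPath(self.points[::-1].copy(), self.vessel_class)


def snap_to_skeleton(
    point: tuple[int, int],
    skeleton: np.ndarray,
    max_snap: float = 10.0,
) -> tuple[int, int]:
    """Nearest skeleton pixel by Euclidean distance.

    Ties are broken by smaller row, then smaller column. Raises
    :class:`SnapError` if the skeleton is empty or the nearest pixel is
    farther than ``max_snap``.
    """
    sk = np.asarray(skeleton, dtype=bool)
    rows, cols = np.nonzero(sk)
    if rows.size == 0:
        raise SnapError(f"cannot snap {tuple(point)}: skeleton is empty")
    pr, pc = point
    d2 = (rows - pr) ** 2.0 + (cols - pc) ** 2.0
    # lexsort: last key is primary -> order by distance, then row, then col
    best = np.lexsort((cols, rows, d2))[0]
    if d2[best] > max_snap ** 2:
        raise SnapError(
            f"nearest skeleton pixel to {tuple(point)} is "
            f"{math.sqrt(d2[best]):.1f} px away (max_snap={max_snap})"
        )
    return int(rows[best]), int(cols[best])


def track_segment(
    start: tuple[int, int],
    end: tuple[int, int],
    skeleton: np.ndarray,
    vessel_class: str | None = None,
    snap: bool = True,
    max_snap: float = 10.0,
) -> SegmentPath:
    """Shortest 8-connected skeleton path between two endpoints via A*.

    The search is restricted to skeleton pixels; off-skeleton shortcuts are
    not allowed. Raises :class:`NoPathError` when the endpoints lie on
    different connected components.
    """
    sk = np.asarray(skeleton, dtype=bool)
    if snap:
        start = snap_to_skeleton(start, sk, max_snap)
        end = snap_to_skeleton(end, sk, max_snap)
    else:
        for p in (start, end):
            if not sk[p[0], p[1]]:
                raise SnapError(f"endpoint {tuple(p)} is not a skeleton pixel")
    start = (int(start[0]), int(start[1]))
    end = (int(end[0]), int(end[1]))

    h0 = math.hypot(start[0] - end[0], start[1] - end[1])
    # heap entries: (f, h, row, col) -- h then row-major order break ties
    open_heap: list[tuple[float, float, int, int]] = [(h0, h0, *start)]
    g_score: dict[tuple[int, int], float] = {start: 0.0}
    came_from: dict[tuple[int, int], tuple[int, int]] = {}
    closed: set[tuple[int, int]] = set()
    H, W = sk.shape

    while open_heap:
        f, h, r, c = heapq.heappop(open_heap)
        node = (r, c)
        if node in closed:
            continue
        if node == end:
            pts = [node]
            while node in came_from:
                node = came_from[node]
                pts.append(node)
            return SegmentPath(np.array(pts[::-1], dtype=int), vessel_class)
        closed.add(node)
        g = g_score[node]
        for dr, dc, cost in _NEIGHBORS:
            nr, nc = r + dr, c + dc
            if nr < 0 or nr >= H or nc < 0 or nc >= W or not sk[nr, nc]:
                continue
            nb = (nr, nc)
            if nb in closed:
                continue
            tentative = g + cost
            if tentative < g_score.get(nb, math.inf) - 1e-12:
                g_score[nb] = tentative
                came_from[nb] = node
                nh = math.hypot(nr - end[0], nc - end[1])
                heapq.heappush(open_heap, (tentative + nh, nh, nr, nc))

    raise NoPathError(
        f"no skeleton path between {start} and {end}: endpoints lie on "
        "disconnected components"
    )
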
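"""The borderline function: a 1-D signature of the lesion boundary.

After the lesion is rotated so its major axis is horizontal, the boundary is
traced, split into four segments at the boundary points nearest the rays
from the centroid to the bounding-box vertices, and each segment is turned
into a distance-to-canvas-edge profile swept along its natural axis (top and
bottom segments per column, left and right per row).  Concatenating the four
profiles and subtracting the junction offsets yields a single continuous
function in which every outward protrusion of the border is a local maximum.

Sign convention: raw distances to the top/left canvas edges make outward
bumps minima on those sides, so the top and left profiles are negated (and
offset by the canvas dimension); on the right and bottom the extremal
coordinate itself is used.  Constant offsets are immaterial because assembly
subtracts the junction gaps anyway.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np

from .segment import LesionMask

__all__ = [
    "BorderlineError",
    "QuadrantSplit",
    "SegmentProfile",
    "BorderlineSignal",
    "trace_boundary",
    "split_quadrants",
    "segment_profile",
    "assemble_borderline",
    "borderline_from_mask",
]

SIDES = ("top", "right", "bottom", "left")


class BorderlineError(ValueError):
    """The borderline construction failed (degenerate or pathological mask)."""


# Moore neighbourhood in clockwise raster order: N, NE, E, SE, S, SW, W, NW.
_MOORE = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


def trace_boundary(mask: np.ndarray | LesionMask) -> np.ndarray:
    """Moore boundary trace of the (single-component) mask.

    Starts at the topmost, then leftmost foreground pixel and walks
    clockwise; the result is a closed (first adjacent to last) (N, 2) array
    of (row, col) pixels.  A 1-pixel mask yields a length-1 trace.
    """
    if isinstance(mask, LesionMask):
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool)
    pts = np.argwhere(mask)
    if pts.size == 0:
        raise BorderlineError("cannot trace an empty mask")
    start = (int(pts[0, 0]), int(pts[0, 1]))  # argwhere is row-major sorted
    H, W = mask.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < H and 0 <= c < W and mask[r, c]

    if not any(fg(start[0] + dr, start[1] + dc) for dr, dc in _MOORE):
        return np.array([start])

    # backtrack starts at the W neighbour of the start pixel, which is
    # guaranteed background because the start is topmost-then-leftmost
    trace = [start]
    cur = start
    back = (start[0], start[1] - 1)
    start_back = back
    limit = 8 * int(mask.sum()) + 16
    for _ in range(limit):
        d0 = _MOORE.index((back[0] - cur[0], back[1] - cur[1]))
        nxt = None
        last_bg = back
        for k in range(1, 9):
            d = (d0 + k) % 8
            cand = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if fg(*cand):
                nxt = cand
                break
            last_bg = cand
        assert nxt is not None  # start has a foreground neighbour
        cur, back = nxt, last_bg
        if cur == start and back == start_back:
            break
        trace.append(cur)
    else:  # pragma: no cover - safety net
        raise BorderlineError("boundary trace did not close")
    return np.array(trace)


@dataclass(frozen=True)
class QuadrantSplit:
    """Four cyclic index ranges cutting the closed trace into segments.

    ``ranges[i] = (start, stop)`` with stop > start; indices are taken modulo
    the trace length, so the last range may wrap.  Order: top, right,
    bottom, left (clockwise).
    """

    ranges: tuple[tuple[int, int], ...]
    split_indices: tuple[int, int, int, int]  # UL, UR, LR, LL trace indices
    bbox: tuple[int, int, int, int]  # min_row, min_col, max_row, max_col
    centroid: tuple[float, float]

    def segment(self, trace: np.ndarray, which: int | str) -> np.ndarray:
        if isinstance(which, str):
            which = SIDES.index(which)
        start, stop = self.ranges[which]
        idx = np.arange(start, stop) % len(trace)
        return trace[idx]


def _split_point(
    trace: np.ndarray, centroid: np.ndarray, vertex: np.ndarray
) -> int:
    """Trace index of the boundary point on the centroid->vertex ray.

    Among points on the vertex's side of the centroid, minimizes the
    perpendicular distance to the ray; where the ray crosses the boundary
    several times (within rasterization width of the minimum), the crossing
    farthest from the centroid wins.
    """
    u = vertex - centroid
    u = u / np.linalg.norm(u)
    w = trace - centroid
    along = w @ u
    perp = np.abs(w[:, 0] * u[1] - w[:, 1] * u[0])
    side = along > 0
    if not side.any():
        raise BorderlineError("no boundary points on the vertex side of centroid")
    dmin = perp[side].min()
    cand = side & (perp <= dmin + 0.75)
    radial = np.where(cand, np.linalg.norm(w, axis=1), -np.inf)
    return int(np.argmax(radial))  # argmax takes the smallest index on ties


def split_quadrants(
    trace: np.ndarray, mask: np.ndarray | LesionMask
) -> QuadrantSplit:
    """Split the closed trace into top/right/bottom/left segments.

    The four split points are the boundary pixels nearest the rays from the
    centroid to the bounding-box vertices; segments are the clockwise trace
    arcs between consecutive split points.  The centroid must lie inside the
    mask (the construction presumes it; strongly concave lesions where it
    does not are rejected with a diagnostic).
    """
    if isinstance(mask, LesionMask):
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool)
    if len(trace) < 4:
        raise BorderlineError("trace too short to split into four segments")
    rows, cols = np.nonzero(mask)
    centroid = np.array([rows.mean(), cols.mean()])
    ir, ic = int(round(centroid[0])), int(round(centroid[1]))
    if not mask[ir, ic]:
        raise BorderlineError(
            f"centroid {tuple(np.round(centroid, 2))} lies outside the mask; "
            "the quadrant construction requires an interior centroid"
        )
    bbox = (int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max()))
    min_r, min_c, max_r, max_c = bbox
    vertices = {
        "UL": np.array([min_r, min_c], dtype=float),
        "UR": np.array([min_r, max_c], dtype=float),
        "LR": np.array([max_r, max_c], dtype=float),
        "LL": np.array([max_r, min_c], dtype=float),
    }
    splits = {k: _split_point(trace, centroid, v) for k, v in vertices.items()}
    order = ["UL", "UR", "LR", "LL"]
    idx = [splits[k] for k in order]
    if len(set(idx)) != 4:
        raise BorderlineError("degenerate quadrant split: coincident split points")
    # the clockwise trace must meet the split points in cyclic UL,UR,LR,LL order
    rel = [(i - idx[0]) % len(trace) for i in idx]
    if not (rel[0] < rel[1] < rel[2] < rel[3]):
        raise BorderlineError(
            "quadrant split points are not in clockwise order along the trace"
        )
    N = len(trace)
    ranges = []
    for a, b in zip(idx, idx[1:] + idx[:1]):
        stop = b if b > a else b + N
        ranges.append((a, stop))
    return QuadrantSplit(
        ranges=tuple(ranges),
        split_indices=tuple(idx),
        bbox=bbox,
        centroid=(float(centroid[0]), float(centroid[1])),
    )


@dataclass(frozen=True)
class SegmentProfile:
    """Single-valued height profile of one boundary segment.

    ``values[i]`` is the sign-adjusted distance-derived height of the
    segment at sweep position i; ``coords[i]`` is the extremal boundary
    pixel realizing it.  ``overhangs`` counts sweep positions where the
    segment was not single-valued by more than rasterization width (the
    boundary detail collapsed onto the outermost pixel).
    """

    values: np.ndarray
    coords: np.ndarray
    side: str
    overhangs: int


def segment_profile(
    segment: np.ndarray, side: str, canvas: tuple[int, int]
) -> SegmentProfile:
    """Distance-to-edge profile of one segment, outward bumps as maxima.

    The profile is parameterized by the boundary walk itself: one sample per
    trace pixel, in clockwise order, whose value is the pixel's distance
    from the canvas edge the segment faces (measured along the canvas axis
    perpendicular to that edge).  Arc-order parameterization keeps every
    boundary irregularity in the profile even where the segment overhangs
    itself in the sweep direction; ``overhangs`` counts the sweep positions
    (columns for top/bottom, rows for left/right) the walk visits more than
    twice, quantifying how non-single-valued the segment was.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    if len(segment) == 0:
        raise BorderlineError("empty segment has no profile")
    H, W = canvas
    seg = np.asarray(segment)
    if side == "top":
        values = (H - 1) - seg[:, 0].astype(np.float64)
    elif side == "bottom":
        values = seg[:, 0].astype(np.float64)
    elif side == "left":
        values = (W - 1) - seg[:, 1].astype(np.float64)
    else:  # right
        values = seg[:, 1].astype(np.float64)
    key = seg[:, 1] if side in ("top", "bottom") else seg[:, 0]
    _, counts = np.unique(key, return_counts=True)
    overhangs = int((counts > 2).sum())
    return SegmentProfile(
        values=values, coords=seg.copy(), side=side, overhangs=overhangs
    )


@dataclass(frozen=True)
class BorderlineSignal:
    """Assembled borderline function with junction bookkeeping."""

    values: np.ndarray  # 1-D float, pixels of height
    coords: np.ndarray  # (N, 2) boundary pixel per sample (rotated frame)
    junctions: tuple[int, int, int]  # interior indices of segment joins
    segment_labels: np.ndarray  # side name per sample
    closure_gap: float  # uncorrected gap between last and first sample
    overhangs: int

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("index,value\n")
        for i, v in enumerate(self.values):
            buf.write(f"{i},{v:.6f}\n")
        return buf.getvalue()

    def sidecar_json(self) -> str:
        return json.dumps(
            {
                "junctions": list(self.junctions),
                "closure_gap": round(float(self.closure_gap), 6),
                "overhang_positions": int(self.overhangs),
                "length": len(self.values),
            },
            sort_keys=True,
        )


def assemble_borderline(
    profiles: list[SegmentProfile] | tuple[SegmentProfile, ...]
) -> BorderlineSignal:
    """Concatenate the four profiles, subtracting junction gaps.

    At each junction the incoming segment is shifted by (last value of the
    previous segment - first value of the next), applied cumulatively
    left-to-right, so the assembled signal is exactly continuous at the
    three interior junctions.  The residual closure gap between the end and
    the start is recorded but not corrected (the borderline is an open
    curve).
    """
    if len(profiles) != 4:
        raise ValueError("assemble_borderline expects four profiles")
    for p in profiles:
        if len(p.values) == 0:
            raise BorderlineError("cannot assemble an empty profile")
    pieces = [profiles[0].values.astype(np.float64)]
    junctions = []
    for p in profiles[1:]:
        prev_last = pieces[-1][-1]
        shift = prev_last - p.values[0]
        junctions.append(sum(len(x) for x in pieces))
        pieces.append(p.values.astype(np.float64) + shift)
    values = np.concatenate(pieces)
    coords = np.concatenate([p.coords for p in profiles])
    labels = np.concatenate(
        [np.full(len(p.values), p.side, dtype=object) for p in profiles]
    )
    return BorderlineSignal(
        values=values,
        coords=coords,
        junctions=tuple(junctions),
        segment_labels=labels,
        closure_gap=float(values[0] - values[-1]),
        overhangs=sum(p.overhangs for p in profiles),
    )


def borderline_from_mask(mask: np.ndarray | LesionMask) -> BorderlineSignal:
    """Convenience: trace, split, profile, and assemble in one call.

    The mask is expected to be the *rotated* lesion mask; the canvas is the
    mask's own shape.
    """
    m = mask.mask if isinstance(mask, LesionMask) else np.asarray(mask, dtype=bool)
    trace = trace_boundary(m)
    split = split_quadrants(trace, m)
    profiles = [
        segment_profile(split.segment(trace, side), side, m.shape) for side in SIDES
    ]
    return assemble_borderline(profiles)
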
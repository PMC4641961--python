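"""Radial-distance baseline and detection evaluation.

The centroid (radial) distance curve is the classical contour signature the
borderline method is compared against: distance from the lesion centroid to
the boundary as a function of angle.  For non-round lesions a ray can cross
the boundary several times; the curve takes the outermost crossing and the
per-angle crossing count is reported so that failure mode is visible.

Evaluation matches detected irregularities to ground-truth positions
one-to-one, greedily by increasing circular arc distance along the boundary,
and reports sensitivity TP/(TP+FN) and precision TP/(TP+FP).  True negatives
are undefined for this task, so no accuracy is computed.
"""

from __future__ import annotations

import csv
import io
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .segment import LesionMask

__all__ = [
    "EvalCounts",
    "RadialCurve",
    "radial_distance_curve",
    "radial_baseline_calls",
    "match_calls",
    "sensitivity",
    "precision",
    "jaccard",
    "mean_boundary_distance",
    "project_to_boundary",
    "evaluation_report",
]


@dataclass(frozen=True)
class EvalCounts:
    """Detection tallies; TP+FN = truths, TP+FP = detections."""

    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class RadialCurve:
    """Centroid-to-boundary distance per angle, with crossing diagnostics."""

    angles: np.ndarray  # radians, uniformly spaced in [0, 2pi)
    distances: np.ndarray  # outermost boundary crossing per angle, pixels
    crossing_counts: np.ndarray  # inside->outside transitions per ray
    outer_points: np.ndarray  # (n, 2) boundary point realizing each distance
    centroid: tuple[float, float]


def radial_distance_curve(
    mask: np.ndarray | LesionMask,
    n_samples: int = 360,
    step: float = 0.5,
) -> RadialCurve:
    """March rays from the centroid and record the outermost boundary crossing.

    ``crossing_counts[i]`` is the number of inside->outside transitions along
    ray i; values above 1 flag the multi-crossing geometry where a purely
    radial signature loses information.
    """
    m = mask.mask if isinstance(mask, LesionMask) else np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(m)
    if rows.size == 0:
        raise ValueError("empty mask")
    cr, cc = float(rows.mean()), float(cols.mean())
    if not m[int(round(cr)), int(round(cc))]:
        raise ValueError("centroid lies outside the mask")
    H, W = m.shape
    max_t = float(math.hypot(H, W))
    ts = np.arange(step, max_t, step)
    angles = np.linspace(0.0, 2.0 * math.pi, n_samples, endpoint=False)
    distances = np.zeros(n_samples)
    counts = np.zeros(n_samples, dtype=int)
    outer = np.zeros((n_samples, 2))
    for i, ang in enumerate(angles):
        dr, dc = math.sin(ang), math.cos(ang)
        rr = np.rint(cr + ts * dr).astype(int)
        cc_ = np.rint(cc + ts * dc).astype(int)
        valid = (rr >= 0) & (rr < H) & (cc_ >= 0) & (cc_ < W)
        inside = np.zeros(len(ts), dtype=bool)
        inside[valid] = m[rr[valid], cc_[valid]]
        # single-sample flickers are rasterization artifacts of a jagged
        # boundary, not crossings; close them before counting transitions
        # (edge-padded so the closing cannot erode the ray's endpoints)
        padded = np.concatenate(([inside[0]] * 2, inside, [inside[-1]] * 2))
        inside = ndi.binary_closing(padded, structure=np.ones(3, bool))[2:-2]
        inside = np.concatenate(([True], inside))  # centroid itself is inside
        exits = np.nonzero(inside[:-1] & ~inside[1:])[0]
        counts[i] = len(exits)
        if len(exits):
            k = exits[-1]  # outermost crossing
            t = ts[k - 1] if k > 0 else step / 2
            distances[i] = t
            outer[i] = (cr + t * dr, cc + t * dc)
        else:  # pragma: no cover - lesion reaching the canvas edge
            distances[i] = ts[-1]
            outer[i] = (cr + ts[-1] * dr, cc + ts[-1] * dc)
    return RadialCurve(
        angles=angles,
        distances=distances,
        crossing_counts=counts,
        outer_points=outer,
        centroid=(cr, cc),
    )


def radial_baseline_calls(
    mask: np.ndarray | LesionMask,
    n_samples: int = 360,
    smoothing_kernel: np.ndarray | None = None,
    min_prominence: float = 0.5,
) -> tuple[np.ndarray, RadialCurve]:
    """Irregularity detection with the radial-distance baseline.

    The centroid-distance curve is smoothed circularly with the given 1-D
    kernel (the same Gaussian the borderline pipeline uses, by default) and
    its turning points become calls; each call is returned as the (row, col)
    boundary point at the outermost crossing of its ray.  Serves as the
    comparison method; its blindness to radially occluded boundary detail is
    exactly the failure mode the borderline function avoids.
    """
    from .detect import SmoothingConfig, turning_points

    if smoothing_kernel is None:
        smoothing_kernel = SmoothingConfig().kernel()
    curve = radial_distance_curve(mask, n_samples=n_samples)
    v = curve.distances
    half = len(smoothing_kernel) // 2
    padded = np.concatenate([v[-half:], v, v[:half]])  # circular padding
    smoothed = np.convolve(padded, smoothing_kernel, mode="valid")
    # open-signal turning points on the curve rolled to start at its global
    # minimum, so no peak straddles the cut
    shift = int(np.argmin(smoothed))
    idx, _ = turning_points(np.roll(smoothed, -shift), min_prominence)
    angle_idx = [(i + shift) % len(smoothed) for i in idx]
    return curve.outer_points[angle_idx], curve


def _circ_dist(a: float, b: float, period: float | None) -> float:
    d = abs(a - b)
    if period is not None:
        d = min(d, period - d)
    return d


def match_calls(
    detected: list[float] | np.ndarray,
    truth: list[float] | np.ndarray,
    tol: float,
    period: float | None = None,
) -> EvalCounts:
    """Greedy one-to-one matching of detections to truths by arc distance.

    Pairs are considered in order of increasing (circular, if ``period`` is
    given) distance; pairs within ``tol`` become TP, leftover detections FP,
    leftover truths FN.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    detected = list(map(float, detected))
    truth = list(map(float, truth))
    pairs = sorted(
        (( _circ_dist(d, t, period), di, ti)
         for di, d in enumerate(detected)
         for ti, t in enumerate(truth)),
    )
    used_d: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for dist, di, ti in pairs:
        if dist > tol:
            break
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        tp += 1
    return EvalCounts(tp=tp, fp=len(detected) - tp, fn=len(truth) - tp)


def sensitivity(c: EvalCounts) -> float:
    """TP / (TP + FN); NaN (with a warning) when no truths exist."""
    if c.tp + c.fn == 0:
        warnings.warn("sensitivity undefined: no ground-truth irregularities",
                      stacklevel=2)
        return float("nan")
    return c.tp / (c.tp + c.fn)


def precision(c: EvalCounts) -> float:
    """TP / (TP + FP); NaN (with a warning) when there are no detections."""
    if c.tp + c.fp == 0:
        warnings.warn("precision undefined: no detections", stacklevel=2)
        return float("nan")
    return c.tp / (c.tp + c.fp)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def _boundary(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    eroded = ndi.binary_erosion(m, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
    return m & ~eroded


def mean_boundary_distance(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Mean symmetric distance (pixels) between two mask boundaries."""
    ba = _boundary(mask_a)
    bb = _boundary(mask_b)
    if not ba.any() or not bb.any():
        raise ValueError("cannot measure boundary distance of an empty mask")
    da = ndi.distance_transform_edt(~ba)
    db = ndi.distance_transform_edt(~bb)
    return float((da[bb].mean() + db[ba].mean()) / 2.0)


def project_to_boundary(
    points: np.ndarray, trace: np.ndarray
) -> np.ndarray:
    """Arc positions (trace indices) of the trace points nearest each input point."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    trace = np.asarray(trace, dtype=float)
    out = np.empty(len(points))
    for i, p in enumerate(points):
        d2 = ((trace - p) ** 2).sum(axis=1)
        out[i] = int(np.argmin(d2))
    return out


_BINS = ((0, 3), (4, 10), (10, 20), (20, None))


def evaluation_report(records: list[dict]) -> str:
    """CSV report: one row per image plus binned and overall aggregates.

    Each record needs keys: image, truth_count, tp, fp, fn.  Aggregates pool
    counts within the truth-count bins 0-3, 4-10, 10-20, >20.
    """
    buf = io.StringIO()
    w = csv.writer(buf)
    w.writerow(["image", "truth_count", "tp", "fp", "fn",
                "sensitivity", "precision"])

    def _rates(tp: int, fp: int, fn: int) -> tuple[str, str]:
        s = f"{tp / (tp + fn):.4f}" if tp + fn else "nan"
        p = f"{tp / (tp + fp):.4f}" if tp + fp else "nan"
        return s, p

    for rec in records:
        s, p = _rates(rec["tp"], rec["fp"], rec["fn"])
        w.writerow([rec["image"], rec["truth_count"],
                    rec["tp"], rec["fp"], rec["fn"], s, p])
    for lo, hi in _BINS:
        sel = [r for r in records
               if r["truth_count"] >= lo and (hi is None or r["truth_count"] <= hi)]
        if not sel:
            continue
        tp = sum(r["tp"] for r in sel)
        fp = sum(r["fp"] for r in sel)
        fn = sum(r["fn"] for r in sel)
        s, p = _rates(tp, fp, fn)
        label = f"{lo}-{hi}" if hi is not None else f">{lo}"
        w.writerow([f"aggregate[{label}]", len(sel), tp, fp, fn, s, p])
    tp = sum(r["tp"] for r in records)
    fp = sum(r["fp"] for r in records)
    fn = sum(r["fn"] for r in records)
    s, p = _rates(tp, fp, fn)
    w.writerow(["aggregate[all]", len(records), tp, fp, fn, s, p])
    return buf.getvalue()
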
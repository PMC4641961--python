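"""Lesion alignment: principal-axis angle, rotation, and coordinate mapping.

The borderline construction measures distances along the canvas axes, so the
lesion is first rotated about its centroid until the major axis is
horizontal.  The canvas is enlarged (never clipped) to hold the rotated
lesion, and the affine record is kept so detections can be mapped back to
the raw input frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .preprocess import CropRecord
from .segment import LesionMask

__all__ = [
    "RotationRecord",
    "principal_axis_angle",
    "rotation_record",
    "rotate_image",
    "map_to_original",
    "map_from_original",
]

_AXIS_TOL = 1e-6


def principal_axis_angle(mask: np.ndarray | LesionMask) -> float:
    """Rotation angle (radians) that makes the mask's major axis horizontal.

    Computed from central second moments: theta = 0.5 * atan2(2 mu11,
    mu20 - mu02) with x = columns, y = rows.  Positive angles are
    counterclockwise in the (x right, y down) raster convention.  A mask with
    equal second moments (circle) has no preferred axis and returns 0.
    """
    if isinstance(mask, LesionMask):
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size < 3:
        raise ValueError("mask too small for a principal axis (area >= 3 required)")
    r = rows - rows.mean()
    c = cols - cols.mean()
    mu20 = float(np.mean(c * c))   # x-variance
    mu02 = float(np.mean(r * r))   # y-variance
    mu11 = float(np.mean(r * c))
    if abs(mu11) < _AXIS_TOL and abs(mu20 - mu02) < _AXIS_TOL:
        return 0.0
    theta = 0.5 * math.atan2(2.0 * mu11, mu20 - mu02)
    if theta <= -math.pi / 2:
        theta += math.pi
    return theta


def _rot_matrix(theta: float) -> np.ndarray:
    """Rotation acting on (row, col) vectors."""
    ct, st = math.cos(theta), math.sin(theta)
    return np.array([[ct, -st], [st, ct]])


@dataclass(frozen=True)
class RotationRecord:
    """Affine record of one alignment rotation.

    Forward map (input -> rotated canvas): q = R(theta) (p - center) + center
    + shift, where shift is the translation that places the enlarged output
    canvas at non-negative coordinates.
    """

    angle: float
    center: tuple[float, float]
    shift: tuple[float, float]
    output_shape: tuple[int, int]
    input_shape: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "angle_rad": round(self.angle, 9),
            "center": [round(v, 4) for v in self.center],
            "shift": [round(v, 4) for v in self.shift],
            "output_shape": list(self.output_shape),
            "input_shape": list(self.input_shape),
        }


def rotation_record(
    shape: tuple[int, int],
    angle: float,
    center: tuple[float, float],
) -> RotationRecord:
    """Build the rotation record for rotating a canvas of ``shape`` by ``angle``."""
    H, W = shape
    R = _rot_matrix(angle)
    corners = np.array(
        [[0.0, 0.0], [0.0, W - 1.0], [H - 1.0, 0.0], [H - 1.0, W - 1.0]]
    )
    c = np.asarray(center, dtype=float)
    rotated = (corners - c) @ R.T + c
    lo = np.floor(rotated.min(axis=0))
    hi = np.ceil(rotated.max(axis=0))
    shift = -lo
    out_shape = (int(hi[0] - lo[0]) + 1, int(hi[1] - lo[1]) + 1)
    return RotationRecord(
        angle=float(angle),
        center=(float(c[0]), float(c[1])),
        shift=(float(shift[0]), float(shift[1])),
        output_shape=out_shape,
        input_shape=(int(H), int(W)),
    )


def align_record(mask: np.ndarray | LesionMask) -> RotationRecord:
    """Rotation record that aligns the lesion's major axis horizontally,
    rotating about the lesion centroid."""
    m = mask.mask if isinstance(mask, LesionMask) else np.asarray(mask, dtype=bool)
    theta = principal_axis_angle(m)
    rows, cols = np.nonzero(m)
    center = (float(rows.mean()), float(cols.mean()))
    return rotation_record(m.shape, theta, center)


def rotate_image(
    img: np.ndarray,
    rec: RotationRecord,
    interpolation: str = "bilinear",
) -> np.ndarray:
    """Rotate a raster onto the enlarged output canvas of ``rec``.

    Continuous rasters (gray or RGB) use bilinear interpolation with border
    replication; boolean masks use nearest neighbour and re-binarize, with
    the background (healthy-skin) label as fill.
    """
    if interpolation not in ("bilinear", "nearest"):
        raise ValueError("interpolation must be 'bilinear' or 'nearest'")
    img = np.asarray(img)
    R = _rot_matrix(rec.angle)
    c = np.asarray(rec.center)
    shift = np.asarray(rec.shift)
    # affine_transform computes input_coord = matrix @ output_coord + offset
    matrix = R.T
    offset = c - R.T @ (c + shift)

    if img.dtype == bool:
        out = ndi.affine_transform(
            img.astype(np.uint8),
            matrix,
            offset=offset,
            output_shape=rec.output_shape,
            order=0,
            mode="constant",
            cval=0,
        )
        return out > 0
    order = 1 if interpolation == "bilinear" else 0
    if img.ndim == 2:
        return ndi.affine_transform(
            img.astype(np.float64),
            matrix,
            offset=offset,
            output_shape=rec.output_shape,
            order=order,
            mode="nearest",
        )
    channels = [
        ndi.affine_transform(
            img[..., ch].astype(np.float64),
            matrix,
            offset=offset,
            output_shape=rec.output_shape,
            order=order,
            mode="nearest",
        )
        for ch in range(img.shape[2])
    ]
    return np.stack(channels, axis=-1)


def map_to_original(
    coord: tuple[float, float],
    rec: RotationRecord,
    crop: CropRecord | None = None,
) -> tuple[float, float]:
    """Map a (row, col) point in the rotated frame back to the raw input image.

    Applies the inverse rotation, then adds the frame-crop offset.
    Real-valued output.
    """
    R = _rot_matrix(rec.angle)
    q = np.asarray(coord, dtype=float)
    p = R.T @ (q - np.asarray(rec.shift) - np.asarray(rec.center)) + np.asarray(
        rec.center
    )
    if crop is not None:
        p = p + np.asarray(crop.offset, dtype=float)
    return (float(p[0]), float(p[1]))


def map_from_original(
    coord: tuple[float, float],
    rec: RotationRecord,
    crop: CropRecord | None = None,
) -> tuple[float, float]:
    """Inverse of :func:`map_to_original` (raw frame -> rotated frame)."""
    p = np.asarray(coord, dtype=float)
    if crop is not None:
        p = p - np.asarray(crop.offset, dtype=float)
    R = _rot_matrix(rec.angle)
    q = R @ (p - np.asarray(rec.center)) + np.asarray(rec.center) + np.asarray(
        rec.shift
    )
    return (float(q[0]), float(q[1]))
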
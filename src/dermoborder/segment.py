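"""Lesion segmentation by seeded region growing of the healthy skin.

The lesion must lie entirely inside the image, so the surrounding healthy
skin is one connected region reachable from the upper-left corner.  Growing
the skin from that corner seed and taking the complement yields the lesion
candidate; the largest 4-connected component with interior holes filled is
the lesion mask.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from ._grow import grow

__all__ = [
    "GrowConfig",
    "LesionMask",
    "SegmentationError",
    "LesionTouchesBorderWarning",
    "region_grow",
    "extract_lesion",
]


class SegmentationError(ValueError):
    """Segmentation produced no usable lesion region."""


class LesionTouchesBorderWarning(UserWarning):
    """The extracted lesion touches the image edge (lesion not fully inside)."""


@dataclass(frozen=True)
class GrowConfig:
    """Parameters of the healthy-skin grower.

    tolerance=None selects the adaptive default, 0.1 x (intensity range of
    the image), which tracks exposure differences between acquisitions.
    Connectivity is fixed at 4 neighbours.
    """

    seed: tuple[int, int] = (0, 0)
    tolerance: float | None = None
    pre_smooth_sigma: float = 0.0

    connectivity: int = field(default=4, init=False)

    def resolve_tolerance(self, gray: np.ndarray) -> float:
        if self.tolerance is not None:
            if self.tolerance < 0:
                raise ValueError("tolerance must be >= 0")
            return float(self.tolerance)
        rng = float(gray.max() - gray.min())
        return 0.1 * rng


def region_grow(gray: np.ndarray, cfg: GrowConfig | None = None) -> np.ndarray:
    """Grow the healthy-skin region from the seed; returns a boolean mask.

    Best-first growth: the 4-connected frontier pixel with the smallest
    delta = |intensity - region mean| is admitted while delta <= tolerance,
    with the region mean updated after every admission.  Ties are broken in
    row-major scan order.  Deterministic: identical masks across runs.
    """
    cfg = cfg or GrowConfig()
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("region_grow expects a 2-D grayscale image")
    r, c = cfg.seed
    if not (0 <= r < gray.shape[0] and 0 <= c < gray.shape[1]):
        raise SegmentationError(f"seed {cfg.seed} outside image {gray.shape}")
    if cfg.pre_smooth_sigma > 0:
        gray = ndi.gaussian_filter(gray, cfg.pre_smooth_sigma)
    tol = cfg.resolve_tolerance(gray)
    return grow(gray, (r, c), tol)


@dataclass(frozen=True)
class LesionMask:
    """Binary lesion raster with derived geometry."""

    mask: np.ndarray  # H x W bool, True = lesion
    touches_border: bool = False

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.mask)
        return (float(rows.mean()), float(cols.mean()))

    def to_rle_json(self) -> str:
        """Row-major run-length encoding as a compact JSON string."""
        flat = self.mask.ravel()
        # runs of (start, length) over True pixels
        padded = np.diff(np.concatenate(([0], flat.astype(np.int8), [0])))
        starts = np.nonzero(padded == 1)[0]
        ends = np.nonzero(padded == -1)[0]
        runs = [[int(s), int(e - s)] for s, e in zip(starts, ends)]
        return json.dumps(
            {"shape": list(self.mask.shape), "runs": runs}, separators=(",", ":")
        )

    @classmethod
    def from_rle_json(cls, text: str) -> "LesionMask":
        obj = json.loads(text)
        flat = np.zeros(int(np.prod(obj["shape"])), dtype=bool)
        for start, length in obj["runs"]:
            flat[start : start + length] = True
        return cls(mask=flat.reshape(obj["shape"]))


def extract_lesion(healthy: np.ndarray) -> LesionMask:
    """Complement the healthy-skin mask and clean it into a single lesion.

    Keeps the largest 4-connected component of the complement and fills its
    interior holes (4-connected background).  A lesion touching the image
    edge violates the fully-inside assumption and is reported as a warning,
    not an error.
    """
    healthy = np.asarray(healthy, dtype=bool)
    candidate = ~healthy
    if not candidate.any():
        raise SegmentationError("no lesion found: healthy region covers the image")
    if not healthy.any():
        raise SegmentationError("healthy-skin mask is empty; cannot segment")
    labels, n = ndi.label(candidate)  # default structure = 4-connectivity
    if n > 1:
        sizes = ndi.sum_labels(candidate, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        candidate = labels == keep
    candidate = ndi.binary_fill_holes(candidate)
    touches = bool(
        candidate[0, :].any()
        or candidate[-1, :].any()
        or candidate[:, 0].any()
        or candidate[:, -1].any()
    )
    if touches:
        warnings.warn(
            "lesion touches the image edge; borderline distances may be clipped",
            LesionTouchesBorderWarning,
            stacklevel=2,
        )
    return LesionMask(mask=candidate, touches_border=touches)
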
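"""Dermoscopic image cleanup: black digitization frame removal and hair removal.

Two artifact classes are handled before segmentation:

* the black frame some dermatoscopes add during digitization, detected on the
  HSL lightness channel and cropped away side by side, and
* dark thick hairs, detected with a black top-hat transform on the NTSC
  grayscale image, discriminated from dots/globules by component elongation,
  and inpainted from their unmasked neighbourhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk

__all__ = [
    "CropRecord",
    "FrameRemovalError",
    "InpaintError",
    "compute_lightness",
    "to_grayscale_ntsc",
    "remove_black_frame",
    "black_tophat",
    "detect_hairs",
    "inpaint_hairs",
]

log = logging.getLogger(__name__)

#: NTSC 1953 luma weights for R, G, B.
NTSC_WEIGHTS = (0.299, 0.587, 0.114)


class FrameRemovalError(ValueError):
    """The frame crop would leave an empty image (frame-dominated input)."""


class InpaintError(ValueError):
    """Inpainting is impossible (no donor pixels outside the hair mask)."""


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {img.shape}")
    return img


def compute_lightness(img: np.ndarray) -> np.ndarray:
    """HSL lightness, L = (max(R,G,B) + min(R,G,B)) / 2, on the [0, 255] scale."""
    img = _check_rgb(img).astype(np.float64)
    return (img.max(axis=2) + img.min(axis=2)) / 2.0


def to_grayscale_ntsc(img: np.ndarray) -> np.ndarray:
    """NTSC 1953 luma: 0.299 R + 0.587 G + 0.114 B."""
    img = _check_rgb(img).astype(np.float64)
    return img @ np.asarray(NTSC_WEIGHTS)


@dataclass(frozen=True)
class CropRecord:
    """Per-side pixel counts removed by frame cropping (0-based, half-open)."""

    top: int = 0
    bottom: int = 0
    left: int = 0
    right: int = 0

    @property
    def offset(self) -> tuple[int, int]:
        """(row, col) offset of the cropped image inside the original."""
        return (self.top, self.left)

    def to_dict(self) -> dict:
        return {
            "top": self.top,
            "bottom": self.bottom,
            "left": self.left,
            "right": self.right,
        }


def _band_length(fractions: np.ndarray, threshold: float) -> int:
    """Length of the run of qualifying rows starting at index 0."""
    n = 0
    for f in fractions:
        if f >= threshold:
            n += 1
        else:
            break
    return n


def remove_black_frame(
    img: np.ndarray,
    lightness_thresh: float = 15.0,
    black_row_fraction: float = 0.5,
    extra_rows: int = 10,
) -> tuple[np.ndarray, CropRecord]:
    """Crop away the black digitization frame.

    A pixel is black when its HSL lightness is below ``lightness_thresh``.
    Scanning inward from each of the four sides, consecutive rows/columns
    whose black fraction reaches ``black_row_fraction`` form the frame band;
    the band plus ``extra_rows`` additional rows/columns (the light inner rim
    of the frame) are removed on every side that has a band.  Interior dark
    rows are never touched: the scan stops at the first non-qualifying line.
    """
    img = _check_rgb(img)
    black = compute_lightness(img) < lightness_thresh
    row_frac = black.mean(axis=1)
    col_frac = black.mean(axis=0)

    def side(fracs: np.ndarray) -> int:
        band = _band_length(fracs, black_row_fraction)
        return band + extra_rows if band > 0 else 0

    top = side(row_frac)
    bottom = side(row_frac[::-1])
    left = side(col_frac)
    right = side(col_frac[::-1])

    H, W = img.shape[:2]
    if top + bottom >= H or left + right >= W:
        raise FrameRemovalError(
            "frame crop would remove the whole image "
            "(all-black or frame-dominated input)"
        )
    rec = CropRecord(top=top, bottom=bottom, left=left, right=right)
    cropped = img[top : H - bottom, left : W - right]
    return cropped, rec


def black_tophat(gray: np.ndarray, selem_radius: int = 5) -> np.ndarray:
    """Black top-hat transform: morphological closing minus the image.

    Responds strongly at dark structures narrower than the disc structuring
    element (thick hairs); wide dark regions (the lesion itself) survive the
    closing and give no response.  Output is everywhere >= 0.
    """
    if selem_radius < 1:
        raise ValueError("selem_radius must be >= 1")
    gray = np.asarray(gray, dtype=np.float64)
    closed = closing(gray, disk(selem_radius))
    return np.maximum(closed - gray, 0.0)


def detect_hairs(
    tophat: np.ndarray,
    binarize_thresh: float = 20.0,
    min_elongation: float = 4.0,
    min_length: float = 30.0,
    use_otsu: bool = False,
) -> np.ndarray:
    """Binarize the top-hat response and keep only elongated components.

    A connected component is a hair iff major_axis / max(minor_axis, 1) >=
    ``min_elongation`` and major_axis >= ``min_length``; round responders
    (dots, globules) fail the elongation test.  Component perimeters are
    logged for inspection but carry no criterion.
    """
    tophat = np.asarray(tophat, dtype=np.float64)
    if use_otsu and tophat.max() > 0:
        binarize_thresh = float(threshold_otsu(tophat))
    binary = tophat >= binarize_thresh
    if binarize_thresh <= 0:
        binary &= tophat > 0
    mask = np.zeros(tophat.shape, dtype=bool)
    if not binary.any():
        return mask
    labels = measure.label(binary, connectivity=2)
    for region in measure.regionprops(labels):
        major = region.axis_major_length
        minor = region.axis_minor_length
        elong = major / max(minor, 1.0)
        log.debug(
            "hair candidate: area=%d major=%.1f minor=%.1f elongation=%.1f "
            "perimeter=%.1f",
            region.area, major, minor, elong, region.perimeter,
        )
        if elong >= min_elongation and major >= min_length:
            mask[labels == region.label] = True
    return mask


def inpaint_hairs(
    img: np.ndarray,
    hairs: np.ndarray,
    neighborhood_radius: int = 5,
) -> np.ndarray:
    """Replace hair pixels by the per-channel mean of nearby non-hair pixels.

    Works from the mask boundary inward: in each pass every masked pixel with
    at least one unmasked pixel inside a disc of ``neighborhood_radius`` is
    filled, then treated as a donor for the next pass, so arbitrarily thick
    hairs are eventually covered.  Pixels outside the mask are never modified.
    """
    img = _check_rgb(img)
    hairs = np.asarray(hairs, dtype=bool)
    if hairs.shape != img.shape[:2]:
        raise ValueError("hair mask shape does not match image")
    if not hairs.any():
        return img.copy()
    if hairs.all():
        raise InpaintError("hair mask covers the entire image; no donor pixels")

    out = img.astype(np.float64).copy()
    remaining = hairs.copy()
    footprint = disk(neighborhood_radius).astype(np.float64)
    while remaining.any():
        known = ~remaining
        counts = ndi.correlate(known.astype(np.float64), footprint, mode="constant")
        fillable = remaining & (counts > 0)
        if not fillable.any():  # pragma: no cover - cannot happen for a finite mask
            raise InpaintError("no reachable donor pixels")
        for ch in range(3):
            sums = ndi.correlate(out[..., ch] * known, footprint, mode="constant")
            out[..., ch][fillable] = sums[fillable] / counts[fillable]
        remaining &= ~fillable
    result = img.copy()
    filled = np.clip(np.rint(out), 0, 255).astype(img.dtype)
    result[hairs] = filled[hairs]
    return result
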
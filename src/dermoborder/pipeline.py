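"""Full border-irregularity pipeline: preprocessing through detection.

Stage order: frame removal -> hair removal -> seeded region growing ->
lesion extraction -> principal-axis rotation -> borderline function ->
Gaussian smoothing -> turning-point detection -> border (B) score.  The
result record carries every stage's metadata so detections can be audited
and mapped back to the raw input frame.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import borderline as bl
from . import detect as dt
from . import geometry as geo
from . import preprocess as pp
from . import segment as sg
from .config import PipelineConfig

__all__ = ["PipelineResult", "run_pipeline", "load_image"]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


def load_image(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    if img.shape[2] == 4:
        img = img[:, :, :3]
    return img


@dataclass
class PipelineResult:
    calls: list[dt.IrregularityCall]
    irregularity_count: int
    border_score: int
    signal: bl.BorderlineSignal
    raw_signal: bl.BorderlineSignal
    crop: pp.CropRecord
    rotation: geo.RotationRecord
    lesion: sg.LesionMask
    rotated_mask: np.ndarray
    hair_mask: np.ndarray
    config: PipelineConfig
    warnings: list[str] = field(default_factory=list)
    stage_seconds: dict = field(default_factory=dict)
    abcd: dt.AbcdScores | None = None

    def to_record(self) -> dict:
        rec = {
            "schema_version": SCHEMA_VERSION,
            "irregularity_count": self.irregularity_count,
            "border_score": self.border_score,
            "calls": [c.to_dict() for c in self.calls],
            "crop": self.crop.to_dict(),
            "rotation": self.rotation.to_dict(),
            "lesion_area": self.lesion.area,
            "lesion_centroid": [round(v, 4) for v in self.lesion.centroid],
            "lesion_touches_border": self.lesion.touches_border,
            "signal_length": len(self.signal),
            "junctions": list(self.signal.junctions),
            "closure_gap": round(float(self.signal.closure_gap), 6),
            "overhang_positions": int(self.signal.overhangs),
            "warnings": self.warnings,
            "config": _jsonable(self.config.to_dict()),
        }
        if self.abcd is not None:
            rec["abcd"] = {
                "A": self.abcd.A, "B": self.abcd.B,
                "C": self.abcd.C, "D": self.abcd.D,
                "tds": round(self.abcd.tds, 4),
                "classification": dt.classify_tds(self.abcd),
            }
        return rec

    def to_json(self) -> str:
        return json.dumps(self.to_record(), sort_keys=True, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, float):
        return round(obj, 6)
    return obj


def run_pipeline(
    image: np.ndarray | str | Path,
    cfg: PipelineConfig | None = None,
    abcd_acd: tuple[int, int, int] | None = None,
) -> PipelineResult:
    """Run every stage on one RGB image and return the result record.

    ``abcd_acd`` optionally supplies the manually assessed (A, C, D)
    components; the border component B is computed here and the record then
    includes the TDS and its classification.
    """
    cfg = cfg or PipelineConfig()
    if isinstance(image, (str, Path)):
        image = load_image(image)
    image = np.asarray(image)
    caught: list[str] = []
    timings: dict = {}

    def _stage(name):
        timings[name] = time.perf_counter()

    def _done(name):
        timings[name] = round(time.perf_counter() - timings[name], 4)
        log.info("stage %-12s %.3fs", name, timings[name])

    _stage("preprocess")
    cropped, crop = pp.remove_black_frame(
        image,
        lightness_thresh=cfg.frame_lightness_thresh,
        black_row_fraction=cfg.frame_black_row_fraction,
        extra_rows=cfg.frame_extra_rows,
    )
    gray = pp.to_grayscale_ntsc(cropped)
    tophat = pp.black_tophat(gray, cfg.hair_tophat_radius)
    hair_mask = pp.detect_hairs(
        tophat,
        binarize_thresh=cfg.hair_binarize_thresh,
        min_elongation=cfg.hair_min_elongation,
        min_length=cfg.hair_min_length,
        use_otsu=cfg.hair_use_otsu,
    )
    if hair_mask.any():
        cropped = pp.inpaint_hairs(cropped, hair_mask, cfg.hair_inpaint_radius)
        gray = pp.to_grayscale_ntsc(cropped)
    _done("preprocess")

    _stage("segment")
    seed = (0, 0)
    if tophat[0, 0] > cfg.hair_binarize_thresh:
        # slide along the top row to the first artifact-free pixel
        clean = np.nonzero(tophat[0] <= cfg.hair_binarize_thresh)[0]
        if len(clean):
            seed = (0, int(clean[0]))
    # the lesion lies inside the image, so the healthy region must cover a
    # substantial share of it; a seed sitting on a noise outlier can stall
    # the growth immediately, in which case deterministic fallback seeds
    # along the border are tried in order
    Hc, Wc = gray.shape
    fallbacks = [
        seed, (0, Wc // 4), (0, Wc // 2), (0, 3 * Wc // 4),
        (Hc // 2, 0), (Hc // 2, Wc - 1), (Hc - 1, Wc // 2),
    ]
    healthy = None
    for s in fallbacks:
        grow_cfg = sg.GrowConfig(
            seed=s,
            tolerance=cfg.grow_tolerance,
            pre_smooth_sigma=cfg.grow_pre_smooth_sigma,
        )
        grown = sg.region_grow(gray, grow_cfg)
        if healthy is None or grown.sum() > healthy.sum():
            healthy = grown
        if grown.mean() >= 0.25:
            healthy = grown
            break
        caught.append(f"region growth from seed {s} stalled; trying fallback")
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        lesion = sg.extract_lesion(healthy)
    caught.extend(str(w.message) for w in wlist)
    _done("segment")

    _stage("rotate")
    rec = geo.align_record(lesion)
    rotated = geo.rotate_image(lesion.mask, rec, interpolation="nearest")
    _done("rotate")

    _stage("borderline")
    raw_signal = bl.borderline_from_mask(rotated)
    _done("borderline")

    _stage("detect")
    smooth_cfg = dt.SmoothingConfig(size=cfg.smoothing_size, sigma=cfg.smoothing_sigma)
    signal = dt.gaussian_smooth(raw_signal, smooth_cfg)
    calls = dt.detect_turning_points(
        signal,
        min_prominence=cfg.min_prominence,
        rotation=rec,
        crop=crop,
        count_minima=cfg.count_minima,
        merge_window=cfg.smoothing_size,
    )
    b_score = dt.border_score(calls, signal)
    _done("detect")

    abcd = None
    if abcd_acd is not None:
        a, c, d = abcd_acd
        abcd = dt.AbcdScores(A=a, B=b_score, C=c, D=d)

    return PipelineResult(
        calls=calls,
        irregularity_count=len(calls),
        border_score=b_score,
        signal=signal,
        raw_signal=raw_signal,
        crop=crop,
        rotation=rec,
        lesion=lesion,
        rotated_mask=rotated,
        hair_mask=hair_mask,
        config=cfg,
        warnings=caught,
        stage_seconds=timings,
        abcd=abcd,
    )
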
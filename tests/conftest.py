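import numpy as np
import pytest

import dermoborder as db


def full_frame_mask(result, image_shape) -> np.ndarray:
    """Embed the cropped-frame lesion mask back into the original canvas."""
    H, W = image_shape[:2]
    crop = result.crop
    full = np.zeros((H, W), dtype=bool)
    full[crop.top : H - crop.bottom, crop.left : W - crop.right] = result.lesion.mask
    return full


def match_against_truth(result, truth_points, truth_mask, tol_fraction=0.02):
    """Project calls and truth apexes onto the ground-truth boundary and match."""
    trace = db.trace_boundary(truth_mask)
    tpos = db.project_to_boundary(np.asarray(truth_points, float).reshape(-1, 2), trace)
    coords = np.array([c.coord for c in result.calls], float).reshape(-1, 2)
    cpos = db.project_to_boundary(coords, trace) if len(coords) else []
    tol = tol_fraction * len(trace)
    return db.match_calls(cpos, tpos, tol=tol, period=len(trace)), trace


def brute_force_maxima(values):
    """Independent local-maximum oracle: index i is a turning point when the
    signal strictly rises into its plateau and strictly falls out of it, and
    i is the floor midpoint of the plateau.  Endpoints are never called."""
    v = np.asarray(values, float)
    n = len(v)
    out = []
    for i in range(1, n - 1):
        left = i - 1
        while left >= 0 and v[left] == v[i]:
            left -= 1
        right = i + 1
        while right < n and v[right] == v[i]:
            right += 1
        if left < 0 or right >= n:
            continue
        if v[left] < v[i] and v[right] < v[i]:
            lo, hi = left + 1, right - 1
            if i == (lo + hi) // 2:
                out.append(i)
    return out


@pytest.fixture(scope="session")
def default_config():
    return db.PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def disc_mask(radius: int, pad: int = 6) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def ellipse_mask(a: int, b: int, pad: int = 6) -> np.ndarray:
    H = 2 * (b + pad) + 1
    W = 2 * (a + pad) + 1
    yy, xx = np.mgrid[0:H, 0:W]
    return ((xx - (W - 1) / 2) / a) ** 2 + ((yy - (H - 1) / 2) / b) ** 2 <= 1.0
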
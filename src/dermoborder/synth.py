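"""Phantom dermoscopic images with exactly known ground truth.

Phantoms emulate the image classes the pipeline manipulates: a dark,
roughly elliptical lesion on lighter homogeneous skin, boundary bumps of
controllable count and amplitude, optional dark hair strokes, and an
optional black digitization frame.  Everything is determined by the spec and
its seed, so every stage of the pipeline can be validated without external
data.

Two families are provided:

* :func:`render_phantom` - star-shaped lesions whose polar radius is an
  ellipse plus a sinusoidal bump train with exactly ``k`` maxima per
  revolution at known angles (the bump apexes are the ground-truth
  irregularities);
* :func:`make_lobed_phantom` - lesions with overhanging shelf lobes whose
  centroid rays cross the boundary three times, the geometry where a purely
  radial contour signature breaks down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon

__all__ = [
    "PhantomSpec",
    "Contour",
    "PhantomTruth",
    "LobedTruth",
    "tier_spec",
    "make_contour",
    "render_phantom",
    "make_lobed_phantom",
    "TIERS",
]

TIERS = ("clean", "standard", "hard")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; (spec, seed) determines every pixel.

    Units: pixels and [0, 255] intensities.  Defaults are the standard test
    tier: moderate additive noise and a digitization frame, no hairs.
    """

    height: int = 280
    width: int = 280
    a: float = 72.0          # ellipse semi-major axis
    b: float = 52.0          # ellipse semi-minor axis
    phi: float = 0.0         # major-axis orientation, radians CCW (y down)
    k: int = 8               # bump count per revolution
    bump_amplitude: float = 12.0
    bump_sharpness: float = 1.0  # exponent on the raised-cosine bump train
    skin: float = 200.0
    lesion: float = 70.0
    noise_sigma: float = 8.0
    n_hairs: int = 0
    hair_width: int = 2      # stroke width 1-3 px
    frame_width: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.a > self.b > 0):
            raise ValueError("require a > b > 0")
        if self.bump_amplitude < 0 or self.bump_amplitude >= self.b / 2:
            raise ValueError("require 0 <= bump_amplitude < b/2")
        if self.k < 0:
            raise ValueError("bump count k must be >= 0")
        if self.noise_sigma > 0 and abs(self.skin - self.lesion) <= 4 * self.noise_sigma:
            raise ValueError("contrast |skin - lesion| must exceed 4 * noise_sigma")
        if self.hair_width < 1 or self.hair_width > 3:
            raise ValueError("hair stroke width must be 1-3 px")


def tier_spec(tier: str, seed: int = 0, **overrides) -> PhantomSpec:
    """Named difficulty tiers: clean, standard (noise + frame), hard
    (noise + hairs + frame + 30 degree rotation)."""
    if tier not in TIERS:
        raise ValueError(f"tier must be one of {TIERS}")
    base = dict(seed=seed)
    if tier == "clean":
        base.update(noise_sigma=0.0, frame_width=0, n_hairs=0)
    elif tier == "standard":
        base.update(noise_sigma=8.0, frame_width=18, n_hairs=0)
    else:  # hard
        base.update(noise_sigma=8.0, frame_width=18, n_hairs=3,
                    phi=math.radians(30.0))
    base.update(overrides)
    return PhantomSpec(**base)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, stream]))


@dataclass(frozen=True)
class Contour:
    """Rasterization-ready closed polygon with analytic bump ground truth."""

    points: np.ndarray          # (n, 2) float (row, col), closed implicitly
    radii: np.ndarray           # polar radius samples r(t)
    angles: np.ndarray          # parameter t per sample
    center: tuple[float, float]
    apex_angles: np.ndarray     # bump apex parameters t_j
    apex_points: np.ndarray     # (k, 2) apex coordinates (row, col)
    apex_arc_fractions: np.ndarray  # arc-length fractions of the apexes
    perimeter: float


def _ellipse_radius(t: np.ndarray, a: float, b: float, phi: float) -> np.ndarray:
    psi = t - phi
    return a * b / np.sqrt((b * np.cos(psi)) ** 2 + (a * np.sin(psi)) ** 2)


def make_contour(spec: PhantomSpec, n_points: int = 2048) -> Contour:
    """Polar contour r(t) = ellipse + bump train, with exactly k maxima.

    The bump train is A * ((1 + cos(k (t - phase))) / 2) ** sharpness with a
    seeded random phase, so apexes sit at k uniformly spaced, known angles.
    The construction is verified: if the sampled r(t) does not have exactly
    k local maxima (bumps too weak against the ellipse slope), a ValueError
    is raised rather than emitting wrong ground truth.
    """
    rng = _rng(spec.seed, 0)
    phase = float(rng.uniform(0.0, 2.0 * math.pi))
    t = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
    r = _ellipse_radius(t, spec.a, spec.b, spec.phi)
    if spec.k > 0 and spec.bump_amplitude > 0:
        bump = ((1.0 + np.cos(spec.k * (t - phase))) / 2.0) ** spec.bump_sharpness
        r = r + spec.bump_amplitude * bump
        apex_angles = (phase + 2.0 * math.pi * np.arange(spec.k) / spec.k) % (
            2.0 * math.pi
        )
        apex_angles.sort()
        maxima = _circular_maxima_count(r)
        if maxima != spec.k:
            raise ValueError(
                f"contour construction invalid: r(t) has {maxima} maxima, "
                f"expected k={spec.k} (bumps too weak for this ellipse)"
            )
    else:
        apex_angles = np.empty(0)
    center = ((spec.height - 1) / 2.0, (spec.width - 1) / 2.0)
    rows = center[0] + r * np.sin(t)
    cols = center[1] + r * np.cos(t)
    points = np.column_stack([rows, cols])
    seg = np.sqrt((np.diff(points, axis=0, append=points[:1]) ** 2).sum(axis=1))
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    perimeter = float(cum[-1])
    apex_r = (
        _ellipse_radius(apex_angles, spec.a, spec.b, spec.phi) + spec.bump_amplitude
        if len(apex_angles)
        else np.empty(0)
    )
    apex_points = np.column_stack(
        [center[0] + apex_r * np.sin(apex_angles),
         center[1] + apex_r * np.cos(apex_angles)]
    ) if len(apex_angles) else np.empty((0, 2))
    apex_fracs = (
        np.interp(apex_angles, t, cum[:-1]) / perimeter
        if len(apex_angles)
        else np.empty(0)
    )
    return Contour(
        points=points,
        radii=r,
        angles=t,
        center=center,
        apex_angles=apex_angles,
        apex_points=apex_points,
        apex_arc_fractions=apex_fracs,
        perimeter=perimeter,
    )


def _circular_maxima_count(r: np.ndarray) -> int:
    """Local maxima of a circular sequence (strict against both neighbours,
    plateaus counted once)."""
    n = len(r)
    shift = int(np.argmin(r))
    v = np.roll(r, -shift)
    d = np.diff(v)
    count = 0
    rising = False
    for x in d:
        if x > 0:
            rising = True
        elif x < 0:
            if rising:
                count += 1
            rising = False
    # closure: v starts and ends at the global minimum region
    if rising and v[0] < v[-1]:
        count += 1
    return count


@dataclass(frozen=True)
class PhantomTruth:
    """Everything known about a rendered phantom."""

    mask: np.ndarray            # H x W bool lesion mask
    contour: Contour
    hair_mask: np.ndarray       # H x W bool
    frame_width: int
    spec: PhantomSpec


def _draw_hairs(spec: PhantomSpec, shape: tuple[int, int]) -> np.ndarray:
    """Dark-stroke ground truth: quadratic Bezier curves, one per hair,
    placed in disjoint horizontal bands so the component count equals
    ``n_hairs``."""
    rng = _rng(spec.seed, 1)
    H, W = shape
    mask = np.zeros(shape, dtype=bool)
    margin = spec.frame_width + 14
    bands = np.linspace(margin, H - margin, spec.n_hairs + 1).astype(int)
    for h in range(spec.n_hairs):
        lo, hi = bands[h], bands[h + 1]
        span = max(hi - lo - 6, 4)
        p0 = np.array([rng.integers(lo + 2, lo + 2 + span // 2), margin], float)
        p2 = np.array([rng.integers(lo + 2, lo + 2 + span // 2), W - margin], float)
        ctrl = np.array(
            [rng.integers(lo + 2, hi - 2), rng.integers(W // 4, 3 * W // 4)], float
        )
        s = np.linspace(0.0, 1.0, 4 * W)[:, None]
        pts = (1 - s) ** 2 * p0 + 2 * s * (1 - s) * ctrl + s**2 * p2
        rr = np.clip(np.rint(pts[:, 0]).astype(int), 0, H - 1)
        cc = np.clip(np.rint(pts[:, 1]).astype(int), 0, W - 1)
        stroke = np.zeros(shape, dtype=bool)
        stroke[rr, cc] = True
        if spec.hair_width > 1:
            stroke = ndi.binary_dilation(
                stroke, iterations=spec.hair_width - 1
            )
        mask |= stroke
    return mask


def render_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render the phantom RGB image and its complete ground truth."""
    contour = make_contour(spec)
    H, W = spec.height, spec.width
    rr, cc = draw_polygon(contour.points[:, 0], contour.points[:, 1], shape=(H, W))
    mask = np.zeros((H, W), dtype=bool)
    mask[rr, cc] = True

    img = np.full((H, W), spec.skin, dtype=np.float64)
    img[mask] = spec.lesion

    hair_mask = (
        _draw_hairs(spec, (H, W)) if spec.n_hairs > 0 else np.zeros((H, W), bool)
    )
    img[hair_mask] = 25.0

    rgb = np.repeat(img[:, :, None], 3, axis=2)
    if spec.noise_sigma > 0:
        noise_rng = _rng(spec.seed, 2)
        rgb = rgb + noise_rng.normal(0.0, spec.noise_sigma, size=rgb.shape)

    if spec.frame_width > 0:
        f = spec.frame_width
        rgb[:f, :] = 0.0
        rgb[-f:, :] = 0.0
        rgb[:, :f] = 0.0
        rgb[:, -f:] = 0.0

    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    truth = PhantomTruth(
        mask=mask,
        contour=contour,
        hair_mask=hair_mask,
        frame_width=spec.frame_width,
        spec=spec,
    )
    return rgb, truth


# ---------------------------------------------------------------------------
# lobed phantoms: overhanging shelves where radial signatures fail
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LobedTruth:
    """Ground truth for a lobed phantom.

    ``truth_points`` holds one (row, col) apex per irregularity: ordinary
    radial bumps, the outward tip of each shelf lobe, and the bumps tucked
    radially underneath the shelves (hidden from a centroid-ray signature
    but present on the boundary).
    """

    mask: np.ndarray
    truth_points: np.ndarray  # (m, 2)
    shelf_sectors: list[tuple[float, float]]  # angular extent of each shelf
    center: tuple[float, float]
    spec: PhantomSpec = field(repr=False, default=None)


def make_lobed_phantom(
    seed: int,
    n_lobes: int = 2,
    n_bumps: int = 3,
    a: float = 72.0,
    b: float = 52.0,
    canvas: int = 300,
    noise_sigma: float = 8.0,
    skin: float = 200.0,
    lesion: float = 70.0,
) -> tuple[np.ndarray, LobedTruth]:
    """Ellipse body + overhanging shelf lobes + radial bumps.

    Each shelf is a thick arc at constant centroid radius, attached to the
    body by a neck at the start of its sector and open at the far end, so
    centroid rays through the sector cross the boundary three times.  One
    ordinary bump is tucked under the far end of each shelf: it is occluded
    radially (the outermost crossing is the shelf) but protrudes beyond the
    body boundary, so a distance-to-edge signature still sees it.
    """
    rng = _rng(seed, 3)
    H = W = canvas
    cr = cc = (canvas - 1) / 2.0
    yy, xx = np.mgrid[0:H, 0:W]
    dy = yy - cr
    dx = xx - cc
    R = np.hypot(dy, dx)
    T = np.mod(np.arctan2(dy, dx), 2 * math.pi)

    def angdiff(t, t0):
        return np.abs(np.mod(t - t0 + math.pi, 2 * math.pi) - math.pi)

    # shelves centred near diagonal directions (jittered); pairs sit on
    # perpendicular diagonals so their second moments roughly cancel and the
    # principal-axis alignment stays close to the body's own axes
    _d0 = float(rng.choice([math.pi / 4, 3 * math.pi / 4, 5 * math.pi / 4,
                            7 * math.pi / 4]))
    base_dirs = [(_d0 + j * math.pi / 2) % (2 * math.pi) for j in range(n_lobes)]
    sector_width = math.radians(38.0)
    shelf_sectors = []
    r_body = _ellipse_radius(T, a, b, 0.0)
    body = R <= r_body

    bump_sigma = math.radians(9.0)
    bump_amp = 14.0
    bump_terms = np.zeros_like(R)
    truth_pts: list[tuple[float, float]] = []

    # ordinary visible bumps near the axis directions (mid-segment after the
    # quadrant split), kept clear of the shelf sectors and of each other
    axis_dirs = [0.0, math.pi / 2, math.pi, 3 * math.pi / 2]
    visible_angles = []
    for j in range(n_bumps):
        for _ in range(200):
            t0 = float(
                (rng.choice(axis_dirs)
                 + rng.uniform(-math.radians(20), math.radians(20)))
                % (2 * math.pi)
            )
            if all(angdiff(np.array([t0]), d)[0] > sector_width * 1.3
                   for d in base_dirs) and all(
                       angdiff(np.array([t0]), v)[0] > math.radians(25)
                       for v in visible_angles):
                visible_angles.append(t0)
                break
    for t0 in visible_angles:
        bump_terms += bump_amp * np.exp(-(angdiff(T, t0) / bump_sigma) ** 2 / 2)
        r_apex = float(_ellipse_radius(np.array([t0]), a, b, 0.0)[0]) + bump_amp
        truth_pts.append((cr + r_apex * math.sin(t0), cc + r_apex * math.cos(t0)))

    shelf = np.zeros_like(body)
    neck = np.zeros_like(body)
    for d in base_dirs:
        jitter = float(rng.uniform(-math.radians(6), math.radians(6)))
        t_start = (d - sector_width / 2 + jitter) % (2 * math.pi)
        t_end = (t_start + sector_width) % (2 * math.pi)
        mid = (t_start + sector_width / 2) % (2 * math.pi)
        r_attach = float(_ellipse_radius(np.array([t_start]), a, b, 0.0)[0])
        # shelf arc at constant-ish centroid radius, ramping outward toward
        # the open end so the tip is the outermost point of the lobe
        w_s = 14.0
        extension = 40.0
        ramp = 10.0
        frac = np.clip(
            (np.mod(T - t_start, 2 * math.pi)) / sector_width, 0.0, 1.0
        )
        R_outer = r_attach + extension + ramp * frac
        in_sector = angdiff(T, mid) <= sector_width / 2
        shelf |= in_sector & (R >= R_outer - w_s) & (R <= R_outer)
        neck_width = math.radians(9.0)
        in_neck = angdiff(T, t_start) <= neck_width / 2
        neck |= in_neck & (R <= r_attach + extension)
        shelf_sectors.append((t_start, t_end))
        # shelf truth: outward tip at the far (open) end of the arc
        tip_t = (t_end - math.radians(4.0)) % (2 * math.pi)
        truth_pts.append((cr + (r_attach + extension + ramp - 2) * math.sin(tip_t),
                          cc + (r_attach + extension + ramp - 2) * math.cos(tip_t)))
        # hidden bump under the far end of the shelf: radially occluded (the
        # outermost crossing is the shelf), but it protrudes past the
        # shelf's row/col extent, so the edge-distance profiles still see it
        t_h = (t_end - math.radians(9.0)) % (2 * math.pi)
        bump_terms += bump_amp * np.exp(-(angdiff(T, t_h) / bump_sigma) ** 2 / 2)
        r_h = float(_ellipse_radius(np.array([t_h]), a, b, 0.0)[0]) + bump_amp
        truth_pts.append((cr + r_h * math.sin(t_h), cc + r_h * math.cos(t_h)))

    body = R <= r_body + bump_terms
    mask = body | shelf | neck
    mask = ndi.binary_fill_holes(
        mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
    )

    img = np.full((H, W), skin)
    img[mask] = lesion
    rgb = np.repeat(img[:, :, None], 3, axis=2)
    if noise_sigma > 0:
        rgb = rgb + _rng(seed, 4).normal(0.0, noise_sigma, size=rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    spec = PhantomSpec(height=H, width=W, a=a, b=b, k=0, bump_amplitude=0.0,
                       skin=skin, lesion=lesion, noise_sigma=noise_sigma,
                       frame_width=0, seed=seed)
    truth = LobedTruth(
        mask=mask,
        truth_points=np.array(truth_pts),
        shelf_sectors=shelf_sectors,
        center=(cr, cc),
        spec=spec,
    )
    return rgb, truth
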
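"""Synthetic coronary-angiogram phantoms with ground truth.

The generator emulates the salient features of a contrast-injected X-ray
frame: a branching tree of dark tubes of tapering caliber (the contrast
agent absorbs X-rays, so vessels are dark on a brighter background), smooth
multiplicative non-uniform illumination, broad low-contrast "bony"
structures, thin tool-like curves (guide wire, stent markers), and photon
counting (Poisson) noise whose strength is set by ``photon_scale`` -- the
mean photon count at unit intensity, so lower values emulate low-radiation
acquisition.  ``contrast_dilution`` scales the vessel attenuation depth and
emulates dye clearance.

Every phantom ships with binary ground-truth masks (vessels, tools, and a
background sampling region disjoint from both) so that visibility metrics
such as the contrast-to-noise ratio can be computed without manual
annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import InputError, ParameterError
from .gabor import Frame

__all__ = ["PhantomSpec", "GroundTruth", "generate_phantom", "cnr",
           "cnr_improvement", "gap_fixture"]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic angiogram frame (all intensities on [0,1])."""

    size: int = 256
    background_level: float = 0.65
    tree_depth: int = 4                   # branching generations
    branch_angle_range: tuple[float, float] = (20.0, 50.0)   # degrees
    root_caliber: float = 6.0             # radius of the root tube (pixels)
    caliber_taper: float = 0.72           # per-generation radius multiplier
    vessel_contrast: float = 0.35         # attenuation depth of the tube core
    illumination_amplitude: float = 0.15  # relative multiplicative field
    bone_blobs: int = 2
    bone_contrast: float = 0.08
    include_tools: bool = True
    tool_contrast: float = 0.3
    photon_scale: float = 5000.0          # mean photons at unit intensity
    contrast_dilution: float = 1.0        # 1 = full dye, 0 = washed out
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        if self.size < 32:
            raise ParameterError("phantom size must be >= 32")
        if self.root_caliber * self.caliber_taper ** (self.tree_depth - 1) < 1.0:
            raise ParameterError("finest vessel caliber falls below 1 pixel")
        if self.photon_scale <= 0:
            raise ParameterError("photon_scale must be positive")
        if not 0.0 <= self.contrast_dilution:
            raise ParameterError("contrast_dilution must be >= 0")
        return self


@dataclass
class GroundTruth:
    vessel_mask: np.ndarray
    tool_mask: np.ndarray
    background_sample_region: np.ndarray
    clean: np.ndarray | None = None            # noise-free composite
    clean_no_vessels: np.ndarray | None = None  # same scene without vessels
    meta: dict = field(default_factory=dict)


def _draw_segment(canvas_r: np.ndarray, p0, p1, radius: float) -> None:
    """Rasterise a centerline segment into the per-pixel radius map."""
    n = max(2, int(np.hypot(p1[0] - p0[0], p1[1] - p0[1]) * 2))
    rr = np.linspace(p0[0], p1[0], n)
    cc = np.linspace(p0[1], p1[1], n)
    rr = np.clip(np.round(rr).astype(int), 0, canvas_r.shape[0] - 1)
    cc = np.clip(np.round(cc).astype(int), 0, canvas_r.shape[1] - 1)
    np.maximum.at(canvas_r, (rr, cc), radius)


def _grow_tree(radius_map: np.ndarray, rng: np.random.Generator,
               spec: PhantomSpec) -> None:
    """Recursive branching polylines with midpoint jitter, caliber taper."""
    size = spec.size
    segment_len = size / (spec.tree_depth + 1)

    def branch(point, direction, caliber, depth):
        if depth == 0 or caliber < 1.0:
            return
        # polyline of 3 jittered sub-segments per branch
        pos = np.array(point, dtype=float)
        ang = direction
        for _ in range(3):
            ang += rng.uniform(-12, 12)
            step = segment_len / 3
            nxt = pos + step * np.array([math.sin(math.radians(ang)),
                                         math.cos(math.radians(ang))])
            _draw_segment(radius_map, pos, nxt, caliber)
            pos = nxt
        lo, hi = spec.branch_angle_range
        for sign in (-1.0, 1.0):
            child_ang = ang + sign * rng.uniform(lo, hi)
            branch(pos, child_ang, caliber * spec.caliber_taper, depth - 1)

    start = (2.0, rng.uniform(0.3, 0.7) * size)
    branch(start, rng.uniform(-25, 25), spec.root_caliber, spec.tree_depth)


def _tube_render(radius_map: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-profile tube attenuation and the binary vessel mask from a
    centerline radius map."""
    centerline = radius_map > 0
    if not centerline.any():
        shape = radius_map.shape
        return np.zeros(shape), np.zeros(shape, dtype=bool)
    dist, (ir, ic) = ndi.distance_transform_edt(~centerline,
                                                return_indices=True)
    near_radius = radius_map[ir, ic]
    sigma_t = near_radius / 1.5
    profile = np.exp(-0.5 * (dist / sigma_t) ** 2)
    profile[dist > 3.0 * near_radius] = 0.0
    mask = dist <= near_radius
    return profile, mask


def _illumination(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    fld = ndi.gaussian_filter(rng.standard_normal((spec.size, spec.size)),
                              spec.size / 4.0)
    peak = np.abs(fld).max()
    if peak > 0:
        fld /= peak
    return 1.0 + spec.illumination_amplitude * fld


def _bones(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    """Broad low-frequency absorbers (vertebra-like blobs)."""
    size = spec.size
    y, x = np.mgrid[0:size, 0:size].astype(float)
    out = np.zeros((size, size))
    for _ in range(spec.bone_blobs):
        cy, cx = rng.uniform(0.2, 0.8, 2) * size
        sy = rng.uniform(0.25, 0.45) * size
        sx = rng.uniform(0.08, 0.18) * size
        t = rng.uniform(0, math.pi)
        xr = (x - cx) * math.cos(t) + (y - cy) * math.sin(t)
        yr = (y - cy) * math.cos(t) - (x - cx) * math.sin(t)
        out += spec.bone_contrast * np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2))
    return out


def _tools(rng: np.random.Generator, spec: PhantomSpec
           ) -> tuple[np.ndarray, np.ndarray]:
    """A 1-px dark wire (smooth quadratic curve) plus two marker dots."""
    size = spec.size
    depth = np.zeros((size, size))
    mask = np.zeros((size, size), dtype=bool)
    if not spec.include_tools:
        return depth, mask
    # wire: quadratic Bezier across the frame
    p0 = np.array([rng.uniform(0.1, 0.3) * size, 0.0])
    p1 = np.array([rng.uniform(0.3, 0.7) * size, rng.uniform(0.3, 0.7) * size])
    p2 = np.array([rng.uniform(0.6, 0.9) * size, size - 1.0])
    t = np.linspace(0, 1, 4 * size)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2
    rr = np.clip(np.round(pts[:, 0]).astype(int), 0, size - 1)
    cc = np.clip(np.round(pts[:, 1]).astype(int), 0, size - 1)
    mask[rr, cc] = True
    depth[rr, cc] = spec.tool_contrast * 0.8
    # stent markers: two small dots on the wire
    for frac in (0.35, 0.55):
        i = int(frac * len(rr))
        rr_d, cc_d = np.mgrid[-2:3, -2:3]
        keep = rr_d ** 2 + cc_d ** 2 <= 4
        r_idx = np.clip(rr[i] + rr_d[keep], 0, size - 1)
        c_idx = np.clip(cc[i] + cc_d[keep], 0, size - 1)
        mask[r_idx, c_idx] = True
        depth[r_idx, c_idx] = spec.tool_contrast * 1.3
    return depth, mask


def generate_phantom(spec: PhantomSpec) -> tuple[Frame, GroundTruth]:
    """Render one seeded phantom frame and its ground truth.

    The composite is ``illumination * (background - bones - vessels - tools)``
    followed by Poisson noise ``Poisson(photon_scale * I) / photon_scale``.
    Fully deterministic per seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.size

    radius_map = np.zeros((size, size))
    _grow_tree(radius_map, rng, spec)
    profile, vessel_mask = _tube_render(radius_map)
    vessel_depth = spec.vessel_contrast * spec.contrast_dilution * profile

    bones = _bones(rng, spec)
    tool_depth, tool_mask = _tools(rng, spec)
    illum = _illumination(rng, spec)

    base = spec.background_level - bones - tool_depth
    clean_no_vessels = np.clip(illum * base, 0.01, 1.0)
    clean = np.clip(illum * (base - vessel_depth), 0.01, 1.0)

    noisy = rng.poisson(spec.photon_scale * clean) / spec.photon_scale
    noisy = np.clip(noisy, 0.0, 1.0)

    foreground = vessel_mask | tool_mask
    dist_fg = ndi.distance_transform_edt(~foreground)
    background_region = dist_fg > 8.0
    background_region[:4, :] = background_region[-4:, :] = False
    background_region[:, :4] = background_region[:, -4:] = False

    gt = GroundTruth(
        vessel_mask=vessel_mask, tool_mask=tool_mask,
        background_sample_region=background_region,
        clean=clean, clean_no_vessels=clean_no_vessels,
        meta={"photon_scale": spec.photon_scale, "seed": spec.seed})
    return Frame(noisy, bit_depth_source=16), gt


def cnr(frame: Frame | np.ndarray, ground_truth: GroundTruth) -> float:
    """Contrast-to-noise ratio |mu_bg - mu_vessel| / sigma_bg.

    This is the common angiography visibility convention: the target is the
    vessel mask, noise is measured on the background sampling region.
    """
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    vessel = ground_truth.vessel_mask
    bg = ground_truth.background_sample_region
    if not vessel.any() or not bg.any():
        raise InputError("cnr requires non-empty vessel and background masks")
    sigma_bg = float(pixels[bg].std())
    if sigma_bg == 0:
        raise InputError("background region has zero variance")
    return abs(float(pixels[bg].mean()) - float(pixels[vessel].mean())) / sigma_bg


def cnr_improvement(frame_before, frame_after, ground_truth: GroundTruth) -> float:
    """Relative CNR change in percent: 100 * (after - before) / before."""
    before = cnr(frame_before, ground_truth)
    after = cnr(frame_after, ground_truth)
    if before == 0:
        raise InputError("CNR of the reference frame is zero")
    return 100.0 * (after - before) / before


def _bar_mask(shape: tuple[int, int], origin: tuple[float, float],
              angle: float, length: float, half_w: float) -> np.ndarray:
    """Flat-capped oriented rectangle: pixels whose along-axis projection is
    in [0, length] and whose off-axis distance is <= half_w."""
    y, x = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    t = math.radians(angle)
    u = (-math.sin(t), math.cos(t))       # along the bar (0 deg = +col)
    dy, dx = y - origin[0], x - origin[1]
    s = dy * u[0] + dx * u[1]
    d = np.abs(dy * u[1] - dx * u[0])
    return (s >= 0) & (s <= length) & (d <= half_w)


def gap_fixture(bar_length: int = 40, bar_width: int = 3, gap: int = 4,
                angle_between: float = 0.0, size: int = 128,
                background: float = 0.7, contrast: float = 0.4
                ) -> tuple[Frame, np.ndarray]:
    """Two dark bars separated by ``gap`` empty pixel columns, for
    facilitation tests.

    The first bar is horizontal and ends at the gap; the second starts
    ``gap`` pixels further on, rotated by ``angle_between`` degrees
    (0 = collinear continuation, 90 = perpendicular).  Returns the frame and
    the binary gap-region mask (the strip between the bars).
    """
    r0 = size // 2
    c_end = size // 2 - gap // 2          # last column of the first bar
    half_w = bar_width / 2.0

    bar1 = _bar_mask((size, size), (r0, c_end - bar_length), 0.0,
                     bar_length, half_w)
    origin2 = (float(r0), float(c_end + gap + 1))
    bar2 = _bar_mask((size, size), origin2, angle_between, bar_length, half_w)
    bars = bar1 | bar2

    img = np.full((size, size), background)
    img[bars] = background - contrast

    gap_region = np.zeros((size, size), dtype=bool)
    if gap > 0:
        w = int(half_w)
        gap_region[r0 - w:r0 + w + 1, c_end + 1:c_end + gap + 1] = True
        gap_region &= ~bars
    return Frame(img), gap_region
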
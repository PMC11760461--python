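"""Multiscale oriented edge extraction.

A frame is decomposed into a Gaussian image pyramid; every level is
correlated with a bank of cosine-phase Gabor kernels at evenly spaced
orientations.  Per pixel and scale the strongest (signed) response across
orientations is kept, split into its positive and negative polarity, gated by
a per-scale noise floor, and passed through Naka-Rushton divisive gain
control.  Kernels are 180-degree periodic, so the bank spans [0, 180).

Coordinates are 0-based (row, col), origin top-left.  The two polarity
channels are processed independently from here on and recombined only at the
end of the lateral-facilitation stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from ._resample import lanczos_resize
from .config import PipelineConfig
from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "Frame", "GaborBank", "Pyramid", "EdgeResponseStack",
    "build_gabor_bank", "build_pyramid", "oriented_responses",
    "optimal_orientation", "split_polarity", "noise_floor", "naka_rushton",
    "compute_edge_stack",
]

# Responses below this magnitude are numerical residue of the DC-corrected
# kernels (a genuine contrast response is orders of magnitude larger than
# this; the gain-control semi-saturation alone is 0.1).
RESPONSE_ATOL = 1e-9

#: std-dev of the Gaussian smoothing applied before each factor-2 downsample
PYRAMID_SMOOTH_SIGMA = 1.0


@dataclass
class Frame:
    """One grayscale image with intensities on [0, 1]."""

    pixels: np.ndarray
    bit_depth_source: int = 8

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise InputError("Frame.pixels must be 2-D")
        # 8 is the coarsest pyramid level; pipeline inputs must be >= 16
        # (enforced in build_pyramid)
        if self.pixels.shape[0] < 8 or self.pixels.shape[1] < 8:
            raise InputError("Frame must be at least 8x8 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("Frame contains non-finite values")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise InputError("Frame intensities must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class GaborBank:
    kernels: list[np.ndarray]
    sigma: float
    wavelength: float
    orientations: np.ndarray      # degrees, strictly increasing on [0, 180)
    center: tuple[float, float] = (0.0, 0.0)
    norm_factor: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def support(self) -> int:
        return self.kernels[0].shape[0]

    @property
    def n_orientations(self) -> int:
        return len(self.kernels)


@dataclass
class Pyramid:
    levels: list[Frame]           # index 0 is scale j=1 (the input)

    @property
    def n_scales(self) -> int:
        return len(self.levels)


@dataclass
class EdgeResponseStack:
    """Per-scale oriented responses and their derived polarity channels.

    Lists are indexed by scale (0-based index = scale j-1); entries of scales
    whose level is smaller than the kernel support are all-zero and flagged in
    ``active``.
    """

    raw: list[np.ndarray]                 # (n_theta, h_j, w_j) signed
    optimal_signed: list[np.ndarray]      # S(x, y, j)
    optimal_angle: list[np.ndarray]       # winning orientation index
    pos: list[np.ndarray]                 # c_P, noise-gated
    neg: list[np.ndarray]                 # c_N, noise-gated
    noise_threshold: list[tuple[float, float]]   # (thr_pos, thr_neg) per scale
    nr_response: list[tuple[np.ndarray, np.ndarray]]  # (R_pos, R_neg)
    active: list[bool]
    orientations: np.ndarray              # degrees


def build_gabor_bank(sigma: float, wavelength: float, n_orientations: int = 8,
                     support: int | None = None) -> GaborBank:
    """Cosine-phase Gabor kernels at ``n_orientations`` angles on [0, 180).

    Each kernel is DC-corrected (mean subtracted, so constant input yields
    zero response) and scaled to unit L2 norm, making responses comparable
    across orientations.
    """
    if sigma <= 0 or wavelength <= 0:
        raise ParameterError("sigma and wavelength must be positive")
    if n_orientations < 2:
        raise ParameterError("n_orientations must be >= 2")
    if support is None:
        support = int(4 * sigma) + 1
        if support % 2 == 0:
            support += 1
    if support % 2 == 0:
        raise ParameterError("support must be odd")

    half = support // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)
    envelope = np.exp(-(x ** 2 + y ** 2) / sigma ** 2)
    angles = np.arange(n_orientations) * (180.0 / n_orientations)
    kernels, norms = [], []
    for theta in angles:
        t = math.radians(theta)
        carrier = np.cos(2 * np.pi / wavelength * (x * math.cos(t) + y * math.sin(t)))
        k = envelope * carrier
        k -= k.mean()
        g = float(np.linalg.norm(k))
        kernels.append(k / g)
        norms.append(g)
    return GaborBank(kernels=kernels, sigma=sigma, wavelength=wavelength,
                     orientations=angles, norm_factor=np.asarray(norms))


def build_pyramid(frame: Frame, n_scales: int) -> Pyramid:
    """Gaussian image pyramid: smooth, Lanczos-downsample by 2 per level.

    The coarsest level is kept at >= 8x8; if ``n_scales`` would go below
    that, the pyramid is truncated with a logged warning.
    """
    if n_scales < 1:
        raise ParameterError("n_scales must be >= 1")
    if frame.height < 16 or frame.width < 16:
        raise InputError("pipeline input frame must be at least 16x16 pixels")
    levels = [frame]
    current = frame.pixels
    for j in range(1, n_scales):
        target = (math.ceil(current.shape[0] / 2), math.ceil(current.shape[1] / 2))
        if min(target) < 8:
            logger.warning(
                "pyramid truncated at %d scales (coarsest level below 8x8)", j)
            break
        smoothed = gaussian_filter(current, PYRAMID_SMOOTH_SIGMA, mode="reflect")
        current = np.clip(lanczos_resize(smoothed, target), 0.0, 1.0)
        levels.append(Frame(current, bit_depth_source=frame.bit_depth_source))
    return Pyramid(levels=levels)


def _correlate_same(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same'-size 2-D correlation with reflective border handling."""
    half = kernel.shape[0] // 2
    padded = np.pad(image, half, mode="reflect")
    return fftconvolve(padded, kernel[::-1, ::-1], mode="valid")


def oriented_responses(pyramid: Pyramid, bank: GaborBank) -> tuple[list[np.ndarray], list[bool]]:
    """Correlate every pyramid level with every bank kernel.

    Levels smaller than the kernel support are skipped (all-zero responses)
    with a logged warning.  Returns the raw stack and per-scale activity
    flags.
    """
    raw, active = [], []
    for j, level in enumerate(pyramid.levels, start=1):
        if min(level.shape) < bank.support:
            logger.warning(
                "scale %d (%dx%d) smaller than kernel support %d; skipped",
                j, level.height, level.width, bank.support)
            raw.append(np.zeros((bank.n_orientations,) + level.shape))
            active.append(False)
            continue
        stack = np.stack([_correlate_same(level.pixels, k) for k in bank.kernels])
        stack[np.abs(stack) < RESPONSE_ATOL] = 0.0
        raw.append(stack)
        active.append(True)
    return raw, active


def optimal_orientation(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per pixel, the signed response of the orientation maximising |s|.

    Ties are broken toward the lowest orientation index (argmax takes the
    first maximum).
    """
    idx = np.argmax(np.abs(raw), axis=0)
    signed = np.take_along_axis(raw, idx[None], axis=0)[0]
    return signed, idx


def split_polarity(optimal_signed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Half-wave rectification into positive and negative channels;
    ``pos - neg`` reconstructs the signed field exactly."""
    pos = np.maximum(optimal_signed, 0.0)
    neg = np.maximum(-optimal_signed, 0.0)
    return pos, neg


def noise_floor(c: np.ndarray, percentile: float = 0.05,
                use_max_fraction: bool = False) -> tuple[np.ndarray, float]:
    """Hard noise gate on a nonnegative polarity map.

    The threshold is the ``percentile`` quantile (lower order statistic) of
    the *nonzero* magnitudes; entries strictly below it are zeroed, all
    others pass unchanged.  The ``use_max_fraction`` variant gates at
    ``(1 - percentile) * max`` instead.
    """
    if not 0.0 < percentile < 1.0:
        raise ParameterError("percentile must be in (0, 1)")
    nonzero = c[c > 0]
    if nonzero.size == 0:
        return c.copy(), 0.0
    if use_max_fraction:
        thr = float(nonzero.max() * (1.0 - percentile))
    else:
        thr = float(np.quantile(nonzero, percentile, method="lower"))
    out = np.where(c < thr, 0.0, c)
    return out, thr


def naka_rushton(c_clean: np.ndarray, n: float = 2.0, sigma_nr: float = 0.1,
                 sigma_is_power: bool = False) -> np.ndarray:
    """Naka-Rushton gain control R = c^n / (c^n + sigma^n), on [0, 1).

    ``sigma_is_power`` reads ``sigma_nr`` as the value of sigma^n directly.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if sigma_nr <= 0:
        raise ParameterError("sigma_nr must be positive")
    if np.any(c_clean < 0):
        raise InputError("naka_rushton expects a nonnegative response map")
    sig_pow = sigma_nr if sigma_is_power else sigma_nr ** n
    cn = np.power(c_clean, n)
    return cn / (cn + sig_pow)


def compute_edge_stack(frame: Frame, config: PipelineConfig) -> tuple[Pyramid, GaborBank, EdgeResponseStack]:
    """Run the full oriented-edge stage of the pipeline on one frame."""
    bank = build_gabor_bank(config.gabor.sigma, config.gabor.wavelength,
                            config.gabor.n_orientations, config.gabor.support)
    pyramid = build_pyramid(frame, config.pyramid.n_scales)
    raw, active = oriented_responses(pyramid, bank)

    optimal_signed, optimal_angle = [], []
    pos_l, neg_l, thr_l, nr_l = [], [], [], []
    for stack in raw:
        signed, idx = optimal_orientation(stack)
        pos, neg = split_polarity(signed)
        pos, thr_p = noise_floor(pos, config.noise.percentile,
                                 config.noise.use_max_fraction)
        neg, thr_n = noise_floor(neg, config.noise.percentile,
                                 config.noise.use_max_fraction)
        r_pos = naka_rushton(pos, config.nr.n, config.nr.sigma,
                             config.nr.sigma_is_power)
        r_neg = naka_rushton(neg, config.nr.n, config.nr.sigma,
                             config.nr.sigma_is_power)
        optimal_signed.append(signed)
        optimal_angle.append(idx)
        pos_l.append(pos)
        neg_l.append(neg)
        thr_l.append((thr_p, thr_n))
        nr_l.append((r_pos, r_neg))
    stack = EdgeResponseStack(
        raw=raw, optimal_signed=optimal_signed, optimal_angle=optimal_angle,
        pos=pos_l, neg=neg_l, noise_threshold=thr_l, nr_response=nr_l,
        active=active, orientations=bank.orientations)
    return pyramid, bank, stack
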
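"""Lateral-facilitation line completion.

Every supra-noise oriented response projects a sub-threshold "additive
signal" along its preferred orientation: an anisotropic Gaussian mask whose
central disk (the classical receptive field, radius ``rf_radius``) is zeroed
so a response does not facilitate itself.  Summing each response with the
additive fields of its same-orientation neighbours yields the lateral
facilitation field LF; where the additive signals of collinear flankers
overlap (e.g. across a gap in a vessel), LF rises above the per-scale
percentile threshold and the line is completed.  The thresholded fields are
recombined over polarity (signed difference), orientation (power-sum with
exponent m1, then the inverse root), and scale (Lanczos upsampling, weighted
power-sum with exponent m2, inverse root, global gain) into the compound
texture image TE.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from ._resample import lanczos_resize
from .config import PipelineConfig
from .errors import ParameterError
from .gabor import EdgeResponseStack, Pyramid

logger = logging.getLogger(__name__)

__all__ = [
    "AdditiveSignalSpec", "LFStack", "additive_mask", "induce_additive",
    "collinear_sum", "percentile_soft_threshold", "recombine_polarities",
    "recombine_orientations", "recombine_scales", "compute_lf_stack",
]


@dataclass
class AdditiveSignalSpec:
    """Geometry and strength of the oriented additive signal at one scale.

    ``sigma_x``/``sigma_y`` are the collinear / orthogonal Gaussian decays in
    relative units (fractions of the scale image's linear dimension);
    ``pixel_scale`` converts them to pixels.
    """

    sigma_x: float
    sigma_y: float
    strength: float = 1.0         # a, gain of the induced facilitation
    rf_radius: float = 8.0        # classical RF radius (pixels)
    support: int | None = None    # odd mask size; None -> 6 sigma, rounded odd
    pixel_scale: float = 1.0

    def __post_init__(self):
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ParameterError("sigma_x and sigma_y must be positive")
        if self.rf_radius < 0:
            raise ParameterError("rf_radius must be >= 0")
        if self.support is not None and self.support % 2 == 0:
            raise ParameterError("support must be odd")

    @property
    def sigma_x_pixels(self) -> float:
        return self.sigma_x * self.pixel_scale

    @property
    def sigma_y_pixels(self) -> float:
        return self.sigma_y * self.pixel_scale


@dataclass
class LFStack:
    """Facilitation fields and their recombination, per scale."""

    lf: list[dict[str, np.ndarray]]          # polarity -> (n_theta, h, w)
    lf_thr: list[dict[str, np.ndarray]]
    thr_per_scale: list[dict[str, float]]
    signed_combined: list[np.ndarray]        # LF_thr^O, (n_theta, h, w)
    t_per_scale: list[np.ndarray]            # T_j' at native scale
    t_resized: list[np.ndarray]              # T_j'' at full resolution
    compound: np.ndarray                     # T
    texture: np.ndarray                      # TE
    m1: int
    m2: int
    tau: list[float]
    gamma_norm: float


def additive_mask(theta: float, spec: AdditiveSignalSpec) -> np.ndarray:
    """Oriented additive-signal mask at orientation ``theta`` (degrees).

    An anisotropic Gaussian elongated along the collinear axis
    x' = x cos(theta) + y sin(theta), zeroed inside the classical RF disk
    (d <= rf_radius), normalised to unit sum over its nonzero support.
    Returns an all-zero mask (with a logged warning) when the RF disk
    swallows the whole support.
    """
    sx, sy = spec.sigma_x_pixels, spec.sigma_y_pixels
    support = spec.support
    if support is None:
        support = 2 * math.ceil(3.0 * max(sx, sy)) + 1
    half = support // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)
    t = math.radians(theta)
    xp = x * math.cos(t) + y * math.sin(t)
    yp = y * math.cos(t) - x * math.sin(t)
    mask = np.exp(-0.5 * ((xp / sx) ** 2 + (yp / sy) ** 2))
    mask[np.hypot(x, y) <= spec.rf_radius] = 0.0
    total = mask.sum()
    if total <= 0:
        logger.warning("additive mask empty: rf_radius %.1f covers the whole "
                       "support %d", spec.rf_radius, support)
        return mask
    return mask / total


def induce_additive(nr_response: np.ndarray, optimal_angle: np.ndarray,
                    spec: AdditiveSignalSpec,
                    orientations: np.ndarray) -> np.ndarray:
    """Additive fields per orientation: a * R (restricted to pixels whose
    optimal orientation is theta) correlated with the oriented mask.

    The dense correlation realises the superposition over all neighbouring
    same-orientation responses in one pass.
    """
    fields = np.zeros((len(orientations),) + nr_response.shape)
    if spec.strength == 0:
        return fields
    for i, theta in enumerate(orientations):
        source = np.where(optimal_angle == i, nr_response, 0.0)
        if not source.any():
            continue
        mask = additive_mask(float(theta), spec)
        if not mask.any():
            continue
        fields[i] = spec.strength * fftconvolve(source, mask[::-1, ::-1],
                                                mode="same")
    return fields


def collinear_sum(nr_response: np.ndarray, optimal_angle: np.ndarray,
                  additive_fields: np.ndarray) -> np.ndarray:
    """LF per orientation: the cRF response (restricted to that orientation)
    plus the summed additive spill of its same-orientation neighbours."""
    n_theta = additive_fields.shape[0]
    own = np.stack([np.where(optimal_angle == i, nr_response, 0.0)
                    for i in range(n_theta)])
    return own + additive_fields


def percentile_soft_threshold(lf: np.ndarray, gamma_j: float,
                              steepness: float | None = None
                              ) -> tuple[np.ndarray, float]:
    """Soft-threshold LF at its gamma_j-th percentile (pooled over the whole
    scale image, all orientations).

    LF_thr = max(0, LF * H(LF - thr_j)) with H a logistic step of slope
    ``steepness`` (default 10/thr_j; ``inf`` recovers the hard gate
    LF * [LF > thr_j]).
    """
    if not 0.0 < gamma_j < 100.0:
        raise ParameterError("gamma_j must be in (0, 100)")
    thr = float(np.percentile(lf, gamma_j))
    if lf.max() == lf.min():
        if lf.max() != 0.0:
            logger.warning("constant LF field (value %.3g); soft threshold "
                           "halves it", lf.max())
        else:
            return np.zeros_like(lf), thr
    u = lf - thr
    if steepness is None:
        steepness = 10.0 / thr if thr > 0 else math.inf
    if math.isinf(steepness):
        h = (u > 0).astype(np.float64)
    else:
        h = 1.0 / (1.0 + np.exp(np.clip(-steepness * u, -700, 700)))
    return np.maximum(0.0, lf * h), thr


def recombine_polarities(lf_thr_pos: np.ndarray,
                         lf_thr_neg: np.ndarray) -> np.ndarray:
    """Signed facilitation field LF^O = LF^P - LF^N."""
    return lf_thr_pos - lf_thr_neg


def recombine_orientations(signed_combined: np.ndarray, m1: int = 1) -> np.ndarray:
    """Collapse orientations: signed power-sum with exponent m1, then the
    inverse 1/m1 root to restore the intensity range."""
    if m1 < 1:
        raise ParameterError("m1 must be >= 1")
    t = np.sum(np.abs(signed_combined) ** m1 * np.sign(signed_combined), axis=0)
    return np.sign(t) * np.abs(t) ** (1.0 / m1)


def recombine_scales(t_per_scale: list[np.ndarray], tau: list[float],
                     m2: int, gamma_norm: float, target_shape: tuple[int, int],
                     literal_te_power: bool = False
                     ) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Collapse scales into the compound texture image TE.

    Each T_j' is Lanczos-upsampled to the full resolution (T_j''), the
    signed 1/tau_j-weighted m2-power sum forms T, and
    TE = gamma * sign(T) * |T|^(1/m2).
    """
    if m2 < 1:
        raise ParameterError("m2 must be >= 1")
    resized = [t if t.shape == tuple(target_shape)
               else lanczos_resize(t, target_shape) for t in t_per_scale]
    compound = np.zeros(target_shape)
    for j, t in enumerate(resized):
        w = 1.0 / tau[min(j, len(tau) - 1)]
        compound += w * np.abs(t) ** m2 * np.sign(t)
    exponent = m2 if literal_te_power else 1.0 / m2
    texture = gamma_norm * np.sign(compound) * np.abs(compound) ** exponent
    return resized, compound, texture


def compute_lf_stack(pyramid: Pyramid, edges: EdgeResponseStack,
                     config: PipelineConfig) -> LFStack:
    """Run the full line-completion stage on an edge-response stack."""
    lf_all, lf_thr_all, thr_all, signed_all, t_all = [], [], [], [], []
    n_theta = len(edges.orientations)
    for j, level in enumerate(pyramid.levels, start=1):
        shape = level.shape
        if config.lf.pixel_scale_mode == "width":
            pixel_scale = level.width
        elif config.lf.pixel_scale_mode == "height":
            pixel_scale = level.height
        else:
            pixel_scale = min(shape)
        spec = AdditiveSignalSpec(
            sigma_x=config.per_scale("lf.sigma_x", j),
            sigma_y=config.per_scale("lf.sigma_y", j),
            strength=config.lf.a, rf_radius=config.lf.rf_radius,
            pixel_scale=pixel_scale)
        gamma_j = config.per_scale("lf.gamma_percentile", j)
        lf_j, lf_thr_j, thr_j = {}, {}, {}
        for pol, response in zip(("pos", "neg"), edges.nr_response[j - 1]):
            if edges.active[j - 1] and response.any():
                fields = induce_additive(response, edges.optimal_angle[j - 1],
                                         spec, edges.orientations)
                lf = collinear_sum(response, edges.optimal_angle[j - 1], fields)
            else:
                lf = np.zeros((n_theta,) + shape)
            lf_thr, thr = percentile_soft_threshold(
                lf, gamma_j, config.lf.soft_step_steepness)
            lf_j[pol], lf_thr_j[pol], thr_j[pol] = lf, lf_thr, thr
        signed = recombine_polarities(lf_thr_j["pos"], lf_thr_j["neg"])
        t_prime = recombine_orientations(signed, config.lf.m1)
        lf_all.append(lf_j)
        lf_thr_all.append(lf_thr_j)
        thr_all.append(thr_j)
        signed_all.append(signed)
        t_all.append(t_prime)
    resized, compound, texture = recombine_scales(
        t_all, config.lf.tau, config.lf.m2, config.lf.gamma_norm,
        pyramid.levels[0].shape, config.lf.literal_te_power)
    return LFStack(lf=lf_all, lf_thr=lf_thr_all, thr_per_scale=thr_all,
                   signed_combined=signed_all, t_per_scale=t_all,
                   t_resized=resized, compound=compound, texture=texture,
                   m1=config.lf.m1, m2=config.lf.m2, tau=list(config.lf.tau),
                   gamma_norm=config.lf.gamma_norm)
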
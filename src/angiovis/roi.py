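"""Multiscale blood-vessel region-of-interest extraction.

Each per-scale compound signal T_j' is Otsu-binarised, morphologically
closed with a per-scale disk, reduced to its largest connected component(s),
and Lanczos-upsampled to full resolution.  A width-L sliding median across
the ordered scale masks regroups the scale information, and the per-pixel
vote count of the median masks, thresholded at tau, yields the final binary
ROI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from ._resample import lanczos_resize
from .config import PipelineConfig
from .errors import DegenerateInputError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "ScaleMaskSet", "otsu_threshold", "binarize_scale", "morph_close",
    "largest_components", "median_scale_windows", "combine_scale_masks",
    "extract_roi",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class ScaleMaskSet:
    otsu_masks: list[np.ndarray]
    otsu_thresholds: list[float | None]
    closed_masks: list[np.ndarray]
    cc_masks: list[np.ndarray]
    resized_masks: list[np.ndarray]     # cc masks on the full-resolution grid
    disk_radius: list[int]
    median_masks: list[np.ndarray]
    window_width: int
    vote_image: np.ndarray
    roi: np.ndarray
    vote_threshold: int


def otsu_threshold(values: np.ndarray) -> float:
    """Threshold minimising intra-class variance over a 256-bin histogram."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if np.unique(values).size < 2:
        raise DegenerateInputError("Otsu threshold requires >= 2 distinct values")
    return float(threshold_otsu(values, nbins=256))


def binarize_scale(t_prime_j: np.ndarray) -> tuple[np.ndarray, float | None]:
    """Otsu binarisation of one compound scale image (strict >).

    A constant image is degenerate; it yields an empty mask and a logged
    warning instead of an error.
    """
    try:
        mu = otsu_threshold(t_prime_j)
    except DegenerateInputError:
        logger.warning("constant compound scale image; empty ROI mask")
        return np.zeros(t_prime_j.shape, dtype=bool), None
    return t_prime_j > mu, mu


def morph_close(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary closing (dilation then erosion) with a disk element.

    The mask is zero-padded by the radius first, so the closing is computed
    on the infinite-domain extension and never removes foreground pixels.
    Radius 0 is the identity.
    """
    if radius < 0:
        raise ParameterError("radius must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    selem = disk(radius).astype(bool)
    padded = np.pad(mask, radius, mode="constant")
    closed = ndi.binary_erosion(ndi.binary_dilation(padded, structure=selem),
                                structure=selem)
    return closed[radius:-radius, radius:-radius]


def largest_components(closed_mask: np.ndarray, keep: int = 1) -> np.ndarray:
    """Keep the ``keep`` largest 8-connected components (ties broken toward
    the component whose first pixel comes earliest in raster order)."""
    if keep < 1:
        raise ParameterError("keep must be >= 1")
    mask = np.asarray(closed_mask, dtype=bool)
    labels, n = ndi.label(mask, structure=_EIGHT_CONNECTED)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())[1:]
    # ndi.label assigns ids in raster order of first pixel, so a stable sort
    # on size alone implements the tie-break.
    order = np.argsort(-sizes, kind="stable")[:keep] + 1
    return np.isin(labels, order)


def median_scale_windows(cc_masks_resized: list[np.ndarray],
                         window_width: int) -> list[np.ndarray]:
    """Sliding median (majority vote for odd widths) over the ordered scale
    masks; stride 1, output count K = n_scales - L + 1."""
    n = len(cc_masks_resized)
    length = window_width
    if length < 1 or length > n:
        raise ParameterError("median window width must be in 1..n_scales")
    stack = np.stack([np.asarray(m, dtype=bool) for m in cc_masks_resized])
    # order statistic: middle element for odd L, lower median for even L
    pick = length // 2 if length % 2 == 1 else length // 2 - 1
    out = []
    for i in range(n - length + 1):
        window = np.sort(stack[i:i + length], axis=0)
        out.append(window[pick])
    return out


def combine_scale_masks(median_masks: list[np.ndarray],
                        tau: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel vote count of the median masks; ROI where the count
    strictly exceeds ``tau`` (tau = 0 is the union)."""
    if tau < 0:
        raise ParameterError("tau must be >= 0")
    vote = np.sum([m.astype(np.int64) for m in median_masks], axis=0)
    return vote, vote > tau


def extract_roi(t_per_scale: list[np.ndarray], config: PipelineConfig,
                target_shape: tuple[int, int]) -> ScaleMaskSet:
    """Run the full multiscale ROI stage on the per-scale compound images."""
    otsu_masks, thresholds, closed, cc, resized = [], [], [], [], []
    radii = []
    for j, t_prime in enumerate(t_per_scale, start=1):
        source = np.abs(t_prime) if config.roi.use_magnitude else t_prime
        mask, mu = binarize_scale(source)
        radius = int(config.per_scale("roi.disk_radius", j))
        closed_j = morph_close(mask, radius)
        cc_j = largest_components(closed_j, config.roi.keep_components)
        if cc_j.shape == tuple(target_shape):
            resized_j = cc_j.copy()
        else:
            resized_j = lanczos_resize(cc_j.astype(np.float64), target_shape) > 0.5
        otsu_masks.append(mask)
        thresholds.append(mu)
        closed.append(closed_j)
        cc.append(cc_j)
        resized.append(resized_j)
        radii.append(radius)
    median_masks = median_scale_windows(resized, config.roi.median_width)
    vote, roi = combine_scale_masks(median_masks, config.roi.vote_threshold)
    return ScaleMaskSet(
        otsu_masks=otsu_masks, otsu_thresholds=thresholds, closed_masks=closed,
        cc_masks=cc, resized_masks=resized, disk_radius=radii,
        median_masks=median_masks, window_width=config.roi.median_width,
        vote_image=vote, roi=roi, vote_threshold=config.roi.vote_threshold)
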
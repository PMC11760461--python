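"""Final integration and per-frame pipeline orchestration.

The compound texture TE is restricted to the blood-vessel ROI, split into
polarities, and blended with the original frame under the dynamic-range
balancing rule: positive texture is divisively suppressed in bright regions
(divisor 1 + beta*I) and negative texture in dark regions
(divisor 1 + beta - beta*I), so the enhancement never pushes pixels past
the ends of the display range where it matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .config import PipelineConfig, load_config
from .errors import InputError, PipelineError
from .facilitation import compute_lf_stack
from .gabor import Frame, compute_edge_stack
from .roi import extract_roi

logger = logging.getLogger(__name__)

__all__ = ["EnhancedFrame", "apply_roi", "split_texture", "integrate",
           "enhance_frame"]


@dataclass
class EnhancedFrame:
    texture_masked: np.ndarray    # Twb, zero outside the ROI
    tex_pos: np.ndarray           # T_P
    tex_neg: np.ndarray           # T_N
    alpha: float
    beta: float
    output: np.ndarray            # IE, clipped to [0, 1]
    clipped_fraction: float = 0.0


@dataclass
class Diagnostics:
    """Every intermediate of one pipeline run, for QC and debugging."""

    pyramid: Any = None
    bank: Any = None
    edges: Any = None
    lf: Any = None
    masks: Any = None
    stage_seconds: dict[str, float] = field(default_factory=dict)


def apply_roi(texture: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Restrict the texture image to the ROI (elementwise product)."""
    if texture.shape != roi.shape:
        raise InputError("texture and ROI shapes differ")
    return texture * roi.astype(np.float64)


def split_texture(twb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Half-wave rectification; T_P - T_N reconstructs Twb exactly."""
    return np.maximum(0.0, twb), np.maximum(0.0, -twb)


def integrate(frame: np.ndarray, tex_pos: np.ndarray, tex_neg: np.ndarray,
              alpha: float = 0.4, beta: float = 4.0,
              clip: bool = True) -> tuple[np.ndarray, float]:
    """Blend the polarity textures into the frame with dynamic-range
    balancing; returns the enhanced image and the clipped-pixel fraction."""
    if frame.shape != tex_pos.shape or frame.shape != tex_neg.shape:
        raise InputError("frame and texture shapes differ")
    if alpha < 0 or beta < 0:
        raise InputError("alpha and beta must be >= 0")
    out = frame + alpha * (tex_pos / (1.0 + beta * frame)
                           - tex_neg / (1.0 + beta - beta * frame))
    clipped = 0.0
    if clip:
        outside = (out < 0) | (out > 1)
        clipped = float(outside.mean())
        if clipped:
            logger.info("clipped %.2f%% of pixels to [0, 1]", 100 * clipped)
        out = np.clip(out, 0.0, 1.0)
    return out, clipped


def enhance_frame(frame: Frame, config: PipelineConfig | None = None
                  ) -> tuple[EnhancedFrame, Diagnostics]:
    """Run the full enhancement pipeline on one frame.

    Deterministic for a fixed input and configuration; all intermediates are
    exposed on the returned :class:`Diagnostics`.
    """
    import time

    if config is None:
        config = load_config()
    diag = Diagnostics()
    timings = diag.stage_seconds

    def _run(stage, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage label
            raise PipelineError(stage, str(exc)) from exc
        timings[stage] = time.perf_counter() - t0
        return result

    diag.pyramid, diag.bank, diag.edges = _run(
        "oriented-edges", compute_edge_stack, frame, config)
    diag.lf = _run("lateral-facilitation", compute_lf_stack,
                   diag.pyramid, diag.edges, config)
    diag.masks = _run("bv-roi", extract_roi, diag.lf.t_per_scale, config,
                      frame.shape)

    t0 = time.perf_counter()
    twb = apply_roi(diag.lf.texture, diag.masks.roi)
    tex_pos, tex_neg = split_texture(twb)
    output, clipped = integrate(frame.pixels, tex_pos, tex_neg,
                                config.integrate.alpha, config.integrate.beta,
                                config.integrate.clip)
    timings["integration"] = time.perf_counter() - t0

    enhanced = EnhancedFrame(
        texture_masked=twb, tex_pos=tex_pos, tex_neg=tex_neg,
        alpha=config.integrate.alpha, beta=config.integrate.beta,
        output=output, clipped_fraction=clipped)
    logger.debug("stage timings: %s",
                 {k: f"{v:.3f}s" for k, v in timings.items()})
    return enhanced, diag
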
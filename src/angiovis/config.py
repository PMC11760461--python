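"""Pipeline configuration: defaults, YAML round-trip, validation.

The configuration is grouped by pipeline stage.  Per-scale arrays
(``lf.sigma_x`` etc.) default to the packaged 8-scale parameter table and are
truncated / edge-extended when ``pyramid.n_scales`` differs from 8.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .errors import ParameterError

__all__ = ["PipelineConfig", "load_config", "default_scale_params"]


def default_scale_params() -> dict[str, list[float]]:
    """The packaged per-scale parameter table (8 scales)."""
    text = resources.files("angiovis").joinpath("_scale_params.yaml").read_text()
    return yaml.safe_load(text)


_TABLE = default_scale_params()


@dataclass
class GaborConfig:
    sigma: float = 8.0            # Gaussian envelope std-dev (pixels)
    wavelength: float = 12.0      # carrier period lambda (pixels)
    n_orientations: int = 8
    support: int | None = None    # odd kernel size; None -> 4*sigma+1 rounded odd

    def validate(self) -> None:
        if self.sigma <= 0 or self.wavelength <= 0:
            raise ParameterError("gabor.sigma and gabor.wavelength must be positive")
        if self.n_orientations < 2:
            raise ParameterError("gabor.n_orientations must be >= 2")
        if self.support is not None and self.support % 2 == 0:
            raise ParameterError("gabor.support must be odd")


@dataclass
class PyramidConfig:
    n_scales: int = 8

    def validate(self) -> None:
        if self.n_scales < 1:
            raise ParameterError("pyramid.n_scales must be >= 1")


@dataclass
class NoiseConfig:
    percentile: float = 0.05      # fraction of nonzero responses gated as noise
    use_max_fraction: bool = False  # variant gate: thr = 0.95 * max response

    def validate(self) -> None:
        if not 0.0 < self.percentile < 1.0:
            raise ParameterError("noise.percentile must be in (0, 1)")


@dataclass
class NRConfig:
    n: float = 2.0                # Naka-Rushton exponent
    sigma: float = 0.1            # semi-saturation constant
    sigma_is_power: bool = False  # read sigma as sigma^n = value instead

    def validate(self) -> None:
        if self.n < 1:
            raise ParameterError("nr.n must be >= 1")
        if self.sigma <= 0:
            raise ParameterError("nr.sigma must be positive")


@dataclass
class LFConfig:
    sigma_x: list[float] = field(default_factory=lambda: list(_TABLE["sigma_x"]))
    sigma_y: list[float] = field(default_factory=lambda: list(_TABLE["sigma_y"]))
    gamma_percentile: list[float] = field(
        default_factory=lambda: list(_TABLE["gamma_percentile"]))
    a: float = 1.0                # additive-signal strength
    rf_radius: float = 8.0        # classical RF radius (pixels, all scales)
    m1: int = 1                   # orientation recombination exponent
    m2: int = 2                   # scale recombination exponent
    gamma_norm: float = 1.0 / 8.0  # scale recombination normalisation
    tau: list[float] = field(default_factory=lambda: [1.0] * 8)
    soft_step_steepness: float | None = None  # None -> 10/thr_j; inf -> hard gate
    pixel_scale_mode: str = "width"  # relative sigmas scale with level width
    literal_te_power: bool = False   # TE uses |T|^m2 instead of the 1/m2 root

    def validate(self) -> None:
        for name in ("sigma_x", "sigma_y"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ParameterError(f"lf.{name} entries must be positive")
        if any(not 0 < g < 100 for g in self.gamma_percentile):
            raise ParameterError("lf.gamma_percentile entries must be in (0, 100)")
        if self.rf_radius < 0:
            raise ParameterError("lf.rf_radius must be >= 0")
        if self.m1 < 1 or self.m2 < 1:
            raise ParameterError("lf.m1 and lf.m2 must be >= 1")
        if any(t <= 0 for t in self.tau):
            raise ParameterError("lf.tau entries must be positive")
        if self.pixel_scale_mode not in ("width", "height", "min"):
            raise ParameterError("lf.pixel_scale_mode must be width, height or min")


@dataclass
class ROIConfig:
    disk_radius: list[int] = field(default_factory=lambda: list(_TABLE["disk_radius"]))
    median_width: int = 3         # L, width of the sliding median window
    vote_threshold: int = 0       # tau, minimum multiscale vote count (strict >)
    keep_components: int = 1      # largest connected components kept per scale
    use_magnitude: bool = True    # Otsu on |T'_j|; False: signed values

    def validate(self) -> None:
        if any(r < 0 for r in self.disk_radius):
            raise ParameterError("roi.disk_radius entries must be >= 0")
        if self.median_width < 1:
            raise ParameterError("roi.median_width must be >= 1")
        if self.vote_threshold < 0:
            raise ParameterError("roi.vote_threshold must be >= 0")
        if self.keep_components < 1:
            raise ParameterError("roi.keep_components must be >= 1")


@dataclass
class IntegrateConfig:
    alpha: float = 0.4            # texture blend weight
    beta: float = 4.0             # polarity dynamic-range balance
    clip: bool = True

    def validate(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ParameterError("integrate.alpha and integrate.beta must be >= 0")


@dataclass
class PipelineConfig:
    gabor: GaborConfig = field(default_factory=GaborConfig)
    pyramid: PyramidConfig = field(default_factory=PyramidConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    nr: NRConfig = field(default_factory=NRConfig)
    lf: LFConfig = field(default_factory=LFConfig)
    roi: ROIConfig = field(default_factory=ROIConfig)
    integrate: IntegrateConfig = field(default_factory=IntegrateConfig)
    provenance: str = "defaults"

    def validate(self) -> "PipelineConfig":
        for group in (self.gabor, self.pyramid, self.noise, self.nr,
                      self.lf, self.roi, self.integrate):
            group.validate()
        return self

    # -- per-scale parameter access ------------------------------------

    def per_scale(self, name: str, j: int) -> float:
        """Value of per-scale list ``name`` (``"lf.sigma_x"`` style) at
        1-based scale index ``j``; lists shorter than n_scales are
        edge-extended with their last entry."""
        group, key = name.split(".")
        values = getattr(getattr(self, group), key)
        return values[min(j - 1, len(values) - 1)]

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        out.pop("provenance")
        return out

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


_GROUPS = {
    "gabor": GaborConfig, "pyramid": PyramidConfig, "noise": NoiseConfig,
    "nr": NRConfig, "lf": LFConfig, "roi": ROIConfig, "integrate": IntegrateConfig,
}


def _build_group(cls, data: dict[str, Any], group: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ParameterError(
            f"unknown config key '{group}.{sorted(unknown)[0]}'")
    return cls(**data)


def load_config(source: str | Path | dict[str, Any] | None = None) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig` from defaults, a mapping, or
    a YAML file.  Unknown keys are rejected by name."""
    if source is None:
        return PipelineConfig().validate()
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text()) or {}
        provenance = str(source)
    else:
        data = dict(source)
        provenance = "dict"
    if not isinstance(data, dict):
        raise ParameterError("config file must contain a mapping")
    unknown = set(data) - set(_GROUPS)
    if unknown:
        raise ParameterError(f"unknown config group '{sorted(unknown)[0]}'")
    groups = {}
    for name, cls in _GROUPS.items():
        sub = data.get(name, {})
        if not isinstance(sub, dict):
            raise ParameterError(f"config group '{name}' must be a mapping")
        groups[name] = _build_group(cls, sub, name)
    return PipelineConfig(provenance=provenance, **groups).validate()
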
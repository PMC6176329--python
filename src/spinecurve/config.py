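"""Shared configuration for the detection / segmentation / curvature pipeline.

All tunable parameters of the pipeline live in small frozen dataclasses that
are grouped into a single :class:`PipelineConfig`.  Configurations round-trip
through YAML; unknown keys are rejected on load so that typos in config files
fail loudly instead of silently falling back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

CONFIG_VERSION = 1


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


@dataclass(frozen=True)
class FeatureConfig:
    """Geometry of the fused Haar / LBP / HOG descriptor.

    Parameters
    ----------
    window:
        Canonical detector sub-window ``(rows, cols)`` in pixels.  Candidate
        patches are resized to this shape before feature extraction.
    haar_scales:
        Placement-box sizes for the Haar pool, as fractions of the window.
    haar_stride_frac:
        Stride of Haar placement positions, as a fraction of the window.
    lbp_grid:
        ``(rows, cols)`` subdivision of the window for per-region LBP
        histograms (256 bins each).
    hog_cell:
        Side of a square HOG cell in pixels.
    hog_bins:
        Number of unsigned orientation bins over ``[0, pi)``.
    hog_block:
        Side of a block, in cells, used for local L2 normalization.
    """

    window: tuple[int, int] = (90, 80)
    haar_scales: tuple[float, ...] = (0.5, 0.25)
    haar_stride_frac: float = 0.25
    lbp_grid: tuple[int, int] = (4, 4)
    hog_cell: int = 8
    hog_bins: int = 9
    hog_block: int = 2

    def __post_init__(self) -> None:
        rows, cols = self.window
        if rows < 3 or cols < 3:
            raise ConfigError(f"window {self.window} too small")
        if not all(0 < s <= 1 for s in self.haar_scales):
            raise ConfigError("haar_scales must lie in (0, 1]")
        if not 0 < self.haar_stride_frac <= 1:
            raise ConfigError("haar_stride_frac must lie in (0, 1]")
        gr, gc = self.lbp_grid
        if rows // gr < 3 or cols // gc < 3:
            raise ConfigError("lbp_grid produces subregions smaller than 3x3")
        if self.hog_cell < 1 or self.hog_bins < 1 or self.hog_block < 1:
            raise ConfigError("hog parameters must be positive")
        if rows < self.hog_cell or cols < self.hog_cell:
            raise ConfigError("window smaller than one HOG cell")


@dataclass(frozen=True)
class DetectorConfig:
    """Cascade training and sliding-window scanning parameters.

    The per-stage true-positive-rate target (0.9), the per-stage false-alarm
    target (0.03), and the maximum number of stages (10) are the detector's
    operating defaults; stride, pyramid factor and NMS threshold govern the
    scan and are freely configurable.
    """

    tpr_target: float = 0.9
    fpr_target: float = 0.03
    n_stages: int = 10
    min_weak_learners: int = 5
    max_weak_learners: int = 40
    stride: int = 8
    pyramid_scale: float = 1.1
    scales: tuple[float, ...] | None = None  # explicit scan scales; None = pyramid
    nms_iou: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.tpr_target <= 1:
            raise ConfigError("tpr_target must lie in (0, 1]")
        if not 0 < self.fpr_target < 1:
            raise ConfigError("fpr_target must lie in (0, 1)")
        if self.n_stages < 1 or self.max_weak_learners < 1:
            raise ConfigError("n_stages and max_weak_learners must be >= 1")
        if not 1 <= self.min_weak_learners <= self.max_weak_learners:
            raise ConfigError("min_weak_learners must lie in [1, max_weak_learners]")
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")
        if self.pyramid_scale <= 1:
            raise ConfigError("pyramid_scale must exceed 1")
        if not 0 < self.nms_iou < 1:
            raise ConfigError("nms_iou must lie in (0, 1)")


@dataclass(frozen=True)
class LevelSetConfig:
    """Distance-regularized level-set evolution parameters.

    ``mu`` weights the distance-regularization term, ``lam`` the edge-length
    term and ``alpha`` the area (balloon) term of the gradient flow;
    ``epsilon`` is the width of the smoothed Dirac delta and ``sigma`` the
    Gaussian scale of the edge indicator.  The explicit scheme requires
    ``mu * dt < 1/4``; the defaults pair ``mu = 0.04`` with ``dt = 5`` (the
    customary ``mu = 0.2 / dt`` coupling), giving ``mu * dt = 0.2``.
    """

    mu: float = 0.04
    lam: float = 5.0
    alpha: float = 1.5
    epsilon: float = 1.5
    sigma: float = 1.5
    dt: float = 5.0
    n_iter: int = 200
    c0: float = 2.0
    pad_frac: float = 0.2
    clahe_clip: float = 0.01
    clahe_tiles: tuple[int, int] = (8, 8)
    intensity_scale: float = 64.0

    def __post_init__(self) -> None:
        if self.mu * self.dt >= 0.25:
            raise ConfigError(
                f"stability contract violated: mu*dt = {self.mu * self.dt:.3f} >= 0.25"
            )
        if self.epsilon <= 0 or self.sigma <= 0 or self.dt <= 0:
            raise ConfigError("epsilon, sigma and dt must be positive")
        if self.n_iter < 0:
            raise ConfigError("n_iter must be non-negative")
        if self.pad_frac < 0:
            raise ConfigError("pad_frac must be non-negative")
        if not 0 < self.clahe_clip <= 1:
            raise ConfigError("clahe_clip must lie in (0, 1]")
        if min(self.clahe_tiles) < 1:
            raise ConfigError("clahe_tiles must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level configuration bundling every pipeline stage."""

    features: FeatureConfig = field(default_factory=FeatureConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    levelset: LevelSetConfig = field(default_factory=LevelSetConfig)
    curve_degree: int | None = None  # None = automatic from centroid count
    version: int = CONFIG_VERSION

    def __post_init__(self) -> None:
        if self.version != CONFIG_VERSION:
            raise ConfigError(f"unsupported config version {self.version}")
        if self.curve_degree is not None and self.curve_degree < 1:
            raise ConfigError("curve_degree must be >= 1")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs: dict = {}
        sections = {
            "features": FeatureConfig,
            "detector": DetectorConfig,
            "levelset": LevelSetConfig,
        }
        for name, section_cls in sections.items():
            if name in data:
                section = data.pop(name)
                if not isinstance(section, dict):
                    raise ConfigError(f"section {name!r} must be a mapping")
                kwargs[name] = _build_section(section_cls, section)
        for key in ("curve_degree", "version"):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise ConfigError(f"unknown config keys: {sorted(data)}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_listify(self.to_dict()), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)


def _build_section(section_cls, data: dict):
    names = {f.name for f in dataclasses.fields(section_cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in {section_cls.__name__}: {sorted(unknown)}")
    converted = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        converted[key] = value
    return section_cls(**converted)


def _listify(obj):
    """YAML-friendly copy: tuples become lists, recursively."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj
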
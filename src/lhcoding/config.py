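"""Validated pipeline configuration with study-default parameters.

Defaults encode the analysis parameters of the study the pipeline models: a
500 ms / 50 ms sliding PSTH over 0–3 s trials, an exact Poisson response test
in the 0.7–2.2 s window against a blank control at FDR-adjusted p < 0.01
(p < 0.04 per single trial), 1000 odor-label shuffles, a 10-point C grid with
4-fold cross-validation for decoding, an overlap-score threshold of 6000 and
25 supervoxel clusters, and 90% census confidence intervals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Bad configuration file: unknown key or out-of-range value."""


@dataclass
class AnalysisWindows:
    """Time windows (seconds from trial onset) for PSTH and response testing."""

    psth_window: float = 0.5
    psth_step: float = 0.05
    psth_span: tuple[float, float] = (0.0, 3.0)
    test_window: tuple[float, float] = (0.7, 2.2)
    baseline_window: tuple[float, float] = (0.0, 0.55)
    evoked_max_window: tuple[float, float] = (0.55, 2.4)
    valve: tuple[float, float] = (0.5, 0.75)

    def __post_init__(self) -> None:
        lo, hi = self.psth_span
        for name in ("test_window", "baseline_window", "evoked_max_window", "valve"):
            a, b = getattr(self, name)
            if not (lo <= a < b <= hi):
                raise ConfigError(f"{name}={a, b} outside psth_span {self.psth_span}")
        if not 0 < self.psth_step <= self.psth_window:
            raise ConfigError("psth_step must be in (0, psth_window]")


@dataclass
class DetectionParams:
    fdr_alpha_multi: float = 0.01
    fdr_alpha_single: float = 0.04
    reliability_rate_threshold: float = 5.0
    min_odors: int = 28  # inclusion rule for population analyses

    def __post_init__(self) -> None:
        for name in ("fdr_alpha_multi", "fdr_alpha_single"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name}={v} must be in (0, 1)")
        if self.reliability_rate_threshold < 0:
            raise ConfigError("reliability_rate_threshold must be >= 0")


@dataclass
class CorrelationParams:
    n_shuffle_reps: int = 1000
    sparse_prob_threshold: float = 0.36

    def __post_init__(self) -> None:
        if self.n_shuffle_reps < 1:
            raise ConfigError("n_shuffle_reps must be >= 1")
        if not 0 < self.sparse_prob_threshold <= 1:
            raise ConfigError("sparse_prob_threshold must be in (0, 1]")


@dataclass
class ClassificationParams:
    sigma: float = 3.0  # µm, similarity kernel decay
    resample_spacing: float = 1.0  # µm
    tangent_neighbors: int = 5

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.resample_spacing <= 0:
            raise ConfigError("sigma and resample_spacing must be positive")
        if self.tangent_neighbors < 2:
            raise ConfigError("tangent_neighbors must be >= 2")


@dataclass
class CodingParams:
    n_auc_shuffles: int = 5
    response_bins: int = 6
    bin_width: float = 0.25  # s, non-overlapping bins from odor onset
    onset: float = 0.5  # s, valve opening
    c_grid: tuple[float, ...] = tuple(10.0 ** e for e in range(-8, 2))
    folds: int = 4
    runs_per_size: int = 20
    max_population: int = 10

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if any(c <= 0 for c in self.c_grid):
            raise ConfigError("C grid must be strictly positive")


@dataclass
class AnatomyParams:
    delta: float = 1.0  # µm, overlap kernel length scale
    overlap_threshold: float = 6000.0
    dendrite_fraction: float = 0.5
    n_supervoxels: int = 25
    kde_bandwidth: float = 5.0  # µm

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.kde_bandwidth <= 0:
            raise ConfigError("delta and kde_bandwidth must be positive")
        if not 0 <= self.dendrite_fraction <= 1:
            raise ConfigError("dendrite_fraction must be in [0, 1]")


@dataclass
class CensusParams:
    level: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ConfigError(f"confidence level {self.level} must be in (0, 1)")


@dataclass
class PipelineConfig:
    """Resolved configuration for a full pipeline run."""

    windows: AnalysisWindows = field(default_factory=AnalysisWindows)
    detection: DetectionParams = field(default_factory=DetectionParams)
    correlation: CorrelationParams = field(default_factory=CorrelationParams)
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    coding: CodingParams = field(default_factory=CodingParams)
    anatomy: AnatomyParams = field(default_factory=AnatomyParams)
    census: CensusParams = field(default_factory=CensusParams)
    trial_duration: float = 3.0
    n_trials: int = 4
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "windows": AnalysisWindows,
    "detection": DetectionParams,
    "correlation": CorrelationParams,
    "classification": ClassificationParams,
    "coding": CodingParams,
    "anatomy": AnatomyParams,
    "census": CensusParams,
}
_SCALARS = {"trial_duration": float, "n_trials": int, "seed": int}


def _build_section(cls, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"unknown keys under {path}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; absent keys fall back to the study defaults.

    Unknown keys and out-of-range values raise :class:`ConfigError` — there is
    no silent ignoring of typos.  An empty (or missing) file yields the full
    default configuration.
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        data = loaded

    unknown = set(data) - set(_SECTIONS) - set(_SCALARS)
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    kwargs: dict = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    for name, cast in _SCALARS.items():
        if name in data:
            kwargs[name] = cast(data[name])
    try:
        return PipelineConfig(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
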
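"""Pipeline configuration: one structured YAML document, one seed.

The single ``seed`` is propagated to every stochastic stage (cohort
sampling, waveform noise, train/test split, GPR restart draws), so a
fixed config reproduces the whole simulate -> evaluate chain bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidConfigError
from .gpr import FitOptions
from .model_bank import DEFAULT_DBP_WIDTH, DEFAULT_MIN_CELL_SIZE, DEFAULT_SBP_WIDTH
from .synthetic_cohort import MorphologyLink, SyntheticConfig


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end study configuration with validation-cohort defaults."""

    seed: int = 1
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    filter_low: float = 0.5
    filter_high: float = 10.0
    window_s: float = 15.0
    activity_threshold: float = 10.0
    sbp_bin_width: int = DEFAULT_SBP_WIDTH
    dbp_bin_width: int = DEFAULT_DBP_WIDTH
    min_cell_size: int = DEFAULT_MIN_CELL_SIZE
    n_train: int = 306
    n_test: int = 129
    fit: FitOptions = field(default_factory=FitOptions)
    calibration_window: int = 0

    def __post_init__(self) -> None:
        if self.n_train < 2 or self.n_test < 1:
            raise InvalidConfigError("split requires n_train >= 2 and n_test >= 1")
        if self.n_train + self.n_test > self.synthetic.n_subjects:
            raise InvalidConfigError(
                "n_train + n_test exceeds the synthetic cohort size"
            )
        if not 0 < self.filter_low < self.filter_high:
            raise InvalidConfigError("filter band must satisfy 0 < low < high")

    @classmethod
    def with_seed(cls, seed: int, **overrides) -> "PipelineConfig":
        """Config whose every stochastic stage derives from ``seed``."""
        synthetic = overrides.pop(
            "synthetic", SyntheticConfig(seed=seed)
        )
        fit = overrides.pop("fit", FitOptions(seed=seed % (2**31)))
        return cls(seed=seed, synthetic=synthetic, fit=fit, **overrides)


def _dataclass_from_mapping(cls, mapping: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise InvalidConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a PipelineConfig from a YAML file; missing keys take defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise InvalidConfigError("config file must hold a mapping")
    kwargs = dict(raw)
    if "synthetic" in kwargs:
        syn = dict(kwargs["synthetic"])
        if "morphology_link" in syn:
            syn["morphology_link"] = _dataclass_from_mapping(
                MorphologyLink, dict(syn["morphology_link"])
            )
        kwargs["synthetic"] = _dataclass_from_mapping(SyntheticConfig, syn)
    if "fit" in kwargs:
        fit = dict(kwargs["fit"])
        for key in ("scale_bounds", "noise_bounds"):
            if key in fit:
                fit[key] = tuple(fit[key])
        kwargs["fit"] = _dataclass_from_mapping(FitOptions, fit)
    return _dataclass_from_mapping(PipelineConfig, kwargs)


def dump_config(config: PipelineConfig) -> str:
    """YAML rendering of a config with every default made explicit."""

    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return yaml.safe_dump(clean(config), sort_keys=False)
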
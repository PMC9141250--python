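"""Run configuration.

A single flat object carries every tunable of the pipeline; defaults are
the study conventions (truncation 652.25--1026.25 nm, smoothing window
9, 10-fold CV, at most 20 latent variables).  Serialisable to/from a
flat YAML mapping so runs are fully reproducible from one file plus one
seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import FormatError, InvalidParameterError
from .grid import TRUNCATED_HI_NM, TRUNCATED_LO_NM
from .synth import SynthConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    # preprocessing
    window: int = 9
    lo_nm: float = TRUNCATED_LO_NM
    hi_nm: float = TRUNCATED_HI_NM
    snv_ddof: int = 1
    # modeling
    max_lv: int = 20
    n_folds: int = 10
    # wavelength selection
    spa_m_min: int = 1
    spa_m_max: int = 25
    cars_n_runs: int = 50
    cars_subsample: float = 0.8
    # global
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise InvalidParameterError("window must be a positive odd integer")
        if self.max_lv < 1 or self.n_folds < 2:
            raise InvalidParameterError("need max_lv >= 1 and n_folds >= 2")
        if not 1 <= self.spa_m_min <= self.spa_m_max:
            raise InvalidParameterError("need 1 <= spa_m_min <= spa_m_max")
        if self.cars_n_runs < 2 or not 0 < self.cars_subsample <= 1:
            raise InvalidParameterError("invalid CARS settings")

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self, seed=seed, synth=dataclasses.replace(self.synth, seed=seed)
        )


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config: RunConfig, path: str | Path) -> None:
    data = _to_plain(config)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration; unknown keys are rejected."""
    try:
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    except yaml.YAMLError as e:
        raise FormatError(f"cannot parse config {path}: {e}") from e
    if not isinstance(data, dict):
        raise FormatError(f"config {path} is not a mapping")
    from .synth import Band, BandTable

    synth_data = dict(data.pop("synth", {}))
    bands_data = synth_data.pop("bands", None)
    synth_kwargs = dict(synth_data)
    if bands_data is not None:
        synth_kwargs["bands"] = BandTable(
            sugar_bands=tuple(Band(**b) for b in bands_data["sugar_bands"]),
            water_bands=tuple(Band(**b) for b in bands_data["water_bands"]),
            baseline_intercept=bands_data["baseline_intercept"],
            baseline_slope_per_nm=bands_data["baseline_slope_per_nm"],
            o2_760_boost=bands_data["o2_760_boost"],
        )
    known = {f.name for f in dataclasses.fields(RunConfig)} - {"synth"}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    unknown_synth = set(synth_kwargs) - {f.name for f in dataclasses.fields(SynthConfig)}
    if unknown_synth:
        raise FormatError(f"unknown synth config keys: {sorted(unknown_synth)}")
    return RunConfig(synth=SynthConfig(**synth_kwargs), **data)
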
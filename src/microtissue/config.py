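"""Run configuration: one YAML document governs a pipeline run.

Validation is strict (unknown keys rejected, ranges checked, a seed is
mandatory for every stochastic stage) and happens before any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import (
    CohortParams,
    EffectParams,
    TissueSceneParams,
    params_from_dict,
)
from .segmentation import SegConfig

_TOP_KEYS = {
    "seed",
    "out_dir",
    "n_lanes_per_gel",
    "cohort",
    "effects",
    "scene",
    "segmentation",
    "stats",
}
_STATS_KEYS = {"alpha", "exclude_outliers"}


class ConfigError(ValueError):
    """A run configuration failed validation."""


@dataclass
class RunConfig:
    seed: int
    out_dir: Path
    cohort: CohortParams
    effects: EffectParams
    scene_overrides: dict = field(default_factory=dict)
    segmentation: SegConfig = field(default_factory=SegConfig)
    alpha: float = 0.05
    exclude_outliers: str = "sensitivity"   # 'never' | 'sensitivity'
    n_lanes_per_gel: int = 10

    def scene_params(self, **kwargs) -> TissueSceneParams:
        merged = {**self.scene_overrides, **kwargs}
        return params_from_dict(TissueSceneParams, merged)


def validate_config(source) -> RunConfig:
    """Load and schema-check a YAML config (path or mapping).

    All defaults are resolved here; errors name the offending key.
    """
    if isinstance(source, (str, Path)):
        try:
            raw = yaml.safe_load(Path(source).read_text())
        except FileNotFoundError as e:
            raise ConfigError(str(e)) from e
    else:
        raw = source
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ConfigError("seed is mandatory for any stochastic stage")
    try:
        seed = int(raw["seed"])
    except (TypeError, ValueError) as e:
        raise ConfigError(f"seed must be an integer: {e}") from e

    try:
        cohort_kwargs = dict(raw.get("cohort", {}))
        cohort_kwargs.setdefault("seed", seed)
        cohort = params_from_dict(CohortParams, cohort_kwargs)
        effects = params_from_dict(EffectParams, dict(raw.get("effects", {})))
        scene_overrides = dict(raw.get("scene", {}))
        if "pixel_size" in scene_overrides and scene_overrides["pixel_size"] <= 0:
            raise ValueError("pixel_size must be positive")
        # validate scene overrides eagerly against the dataclass
        params_from_dict(TissueSceneParams, {**scene_overrides, "seed": seed})
        seg_kwargs = dict(raw.get("segmentation", {}))
        known_seg = set(SegConfig.__dataclass_fields__)
        bad = set(seg_kwargs) - known_seg
        if bad:
            raise ValueError(f"unknown segmentation keys: {sorted(bad)}")
        segmentation = SegConfig(**seg_kwargs)
    except ValueError as e:
        raise ConfigError(str(e)) from e

    stats_kwargs = dict(raw.get("stats", {}))
    bad = set(stats_kwargs) - _STATS_KEYS
    if bad:
        raise ConfigError(f"unknown stats keys: {sorted(bad)}")
    alpha = float(stats_kwargs.get("alpha", 0.05))
    if not 0 < alpha < 1:
        raise ConfigError("alpha must be in (0, 1)")
    exclude = stats_kwargs.get("exclude_outliers", "sensitivity")
    if exclude not in ("never", "sensitivity"):
        raise ConfigError("exclude_outliers must be 'never' or 'sensitivity'")

    return RunConfig(
        seed=seed,
        out_dir=Path(raw.get("out_dir", "runs/demo")),
        cohort=cohort,
        effects=effects,
        scene_overrides=scene_overrides,
        segmentation=segmentation,
        alpha=alpha,
        exclude_outliers=exclude,
        n_lanes_per_gel=int(raw.get("n_lanes_per_gel", 10)),
    )
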
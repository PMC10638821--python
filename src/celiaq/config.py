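"""Pipeline configuration: one human-readable YAML file, strict keys, stable hash."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .mls import MARSH_CATEGORIES
from . import synthetic
from .segmentation import SegmentationConfig

_GENERATOR_SHARED_KEYS = set(synthetic.SHARED_DEFAULTS)
_GENERATOR_TYPE_KEYS = set(next(iter(synthetic.MARSH_GEOMETRY.values())))
_SEGMENTATION_KEYS = {f.name for f in dataclasses.fields(SegmentationConfig)}


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on.

    ``generator`` may override the shared generator defaults (top-level keys such
    as ``n_villi``) and/or per-Marsh-type geometry (keys "0".."3c" mapping to
    parameter dicts).  ``segmentation`` overrides :class:`SegmentationConfig`
    fields.  Unknown keys anywhere are rejected.
    """

    seed: int = 0
    n_per_type: int = 2
    marsh_types: list = field(default_factory=lambda: list(MARSH_CATEGORIES))
    mode: str = "truth"  # "truth" | "segmentation"
    denominator_mode: str = "enterocytes"
    alignment_tol: float = 0.333
    model_source: str = "published"  # "published" or a model-JSON path
    noise_sd: float = 0.0
    out_dir: str = "celiaq_out"
    generator: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("truth", "segmentation"):
            raise ConfigError(f"mode must be 'truth' or 'segmentation', got {self.mode!r}")
        if self.denominator_mode not in ("enterocytes", "all_cells"):
            raise ConfigError(f"unknown denominator_mode {self.denominator_mode!r}")
        for mt in self.marsh_types:
            if str(mt).lower() not in MARSH_CATEGORIES:
                raise ConfigError(f"unknown Marsh type in marsh_types: {mt!r}")
        self.marsh_types = [str(mt).lower() for mt in self.marsh_types]
        for key, val in self.generator.items():
            if key in MARSH_CATEGORIES:
                bad = set(val) - (_GENERATOR_TYPE_KEYS | _GENERATOR_SHARED_KEYS)
                if bad:
                    raise ConfigError(f"unknown generator keys for type {key}: {sorted(bad)}")
            elif key not in _GENERATOR_SHARED_KEYS:
                raise ConfigError(f"unknown generator key: {key!r}")
        bad = set(self.segmentation) - _SEGMENTATION_KEYS
        if bad:
            raise ConfigError(f"unknown segmentation keys: {sorted(bad)}")

    # ---- dict / YAML round trip -----------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown configuration keys: {sorted(bad)}")
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            d = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as e:
            raise ConfigError(f"cannot parse configuration file {path}: {e}") from e
        if not isinstance(d, dict):
            raise ConfigError(f"configuration file {path} must contain a mapping")
        return cls.from_dict(d)

    def hash(self) -> str:
        """Stable sha256 of the canonical JSON form (for output provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(**self.segmentation)

    def generator_overrides(self, marsh_type: str) -> dict:
        """Merged shared + per-type generator overrides for one Marsh type."""
        shared = {k: v for k, v in self.generator.items() if k in _GENERATOR_SHARED_KEYS}
        per_type = dict(self.generator.get(marsh_type, {}))
        shared.update(per_type)
        return shared
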
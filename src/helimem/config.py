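"""Pipeline configuration: defaults, YAML loading, stable hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .classify import ClassifierThresholds
from .geometry import DEFAULT_SMOOTHING_ALPHA
from .sequences import DEFAULT_DELTA, DEFAULT_WINDOW

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline in one place.

    Every threshold has a default so a bare config is valid; the canonical
    JSON serialisation hashes to a short digest recorded in every output
    file, making result provenance checkable.
    """

    scale: str = "fauchere_pliska"
    window: int = DEFAULT_WINDOW
    delta: float = DEFAULT_DELTA
    smoothing_alpha: float = DEFAULT_SMOOTHING_ALPHA
    include_hydrogens: bool = True
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable 12-hex-digit digest of the canonical JSON form."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    thr = data.pop("thresholds", None)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    if thr is not None:
        if isinstance(thr, dict):
            cfg.thresholds = ClassifierThresholds(**thr)
        elif isinstance(thr, ClassifierThresholds):
            cfg.thresholds = thr
        else:
            raise ValueError("thresholds must be a mapping")
    return cfg
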
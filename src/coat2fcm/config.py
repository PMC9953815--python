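"""YAML run configuration with strict validation.

Every field has a default; unknown keys are rejected loudly so a typo
in a config file cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Effective configuration of one segmentation run."""

    method: str = "coa-t2fcm"  # coa-t2fcm | fcm | kmeans
    clusters: int = 3
    fuzzifier: float = 2.0  # single-m baseline (fcm)
    fuzzifier_low: float = 1.1  # search bounds for the type-2 pair
    fuzzifier_high: float = 5.0
    hesitation_alpha: float | None = 2.0
    use_spatial: bool = False
    pop_size: int = 12
    iterations: int = 30
    f_start: float = 2.5
    f_end: float = 0.0
    mu_threshold: float = 0.5
    chaotic_map: str = "logistic"
    opposition_init: bool = False
    final_refine_iters: int = 10
    lesion_rule: str = "brightest_centroid"
    view: str = "mlo"  # cc | mlo
    pectoral_removal: bool = True
    crop_margin: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("coa-t2fcm", "fcm", "kmeans"):
            raise ConfigError(f"unknown method {self.method!r}")
        if self.clusters < 1:
            raise ConfigError("clusters must be >= 1")
        if self.fuzzifier <= 1 or self.fuzzifier_low <= 1:
            raise ConfigError("fuzzifiers must be > 1")
        if self.fuzzifier_low > self.fuzzifier_high:
            raise ConfigError("fuzzifier_low must be <= fuzzifier_high")
        if self.pop_size < 4 or self.iterations < 1:
            raise ConfigError("pop_size >= 4 and iterations >= 1 required")
        if self.chaotic_map not in ("logistic", "tent", "sine"):
            raise ConfigError(f"unknown chaotic_map {self.chaotic_map!r}")
        if self.lesion_rule not in ("brightest_centroid", "largest_mean_membership"):
            raise ConfigError(f"unknown lesion_rule {self.lesion_rule!r}")
        if self.view not in ("cc", "mlo"):
            raise ConfigError(f"unknown view {self.view!r}")
        if self.crop_margin < 0:
            raise ConfigError("crop_margin must be >= 0")

    def as_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the effective configuration."""
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML config, merge defaults, validate strictly.

    ``None`` (or an empty file) yields all defaults.  Keyword overrides
    (e.g. from CLI flags) take precedence over the file.
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must be a YAML mapping")
        data = loaded
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.as_dict(), sort_keys=True))
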
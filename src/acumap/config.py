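"""Package configuration: thresholds and defaults, loadable from YAML.

Unknown keys are rejected (typo safety); every field has a documented
default so a config file is optional.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional, Union

import yaml

from .errors import InvalidInputError
from .evaluation import DEFAULT_OKS_K, DEFAULT_OKS_THRESHOLDS


@dataclass(frozen=True)
class PackageConfig:
    registry_path: Optional[str] = None  # None -> shipped default table
    front_max_deg: float = 45.0
    back_min_deg: float = 135.0
    face_center_threshold: float = 0.2
    oks_k: float = DEFAULT_OKS_K
    oks_thresholds: tuple[float, ...] = DEFAULT_OKS_THRESHOLDS
    ref_cm: Optional[float] = None
    ref_px: Optional[float] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.front_max_deg <= self.back_min_deg <= 180.0):
            raise InvalidInputError(
                "need 0 < front_max_deg <= back_min_deg <= 180"
            )
        if not (0.0 < self.face_center_threshold < 1.0):
            raise InvalidInputError("face_center_threshold must be in (0, 1)")
        if self.oks_k <= 0:
            raise InvalidInputError("oks_k must be positive")
        if any(not (0.0 < t <= 1.0) for t in self.oks_thresholds):
            raise InvalidInputError("OKS thresholds must be in (0, 1]")
        if self.log_level.upper() not in (
                "DEBUG", "INFO", "WARNING", "ERROR", "CRITICAL"):
            raise InvalidInputError(f"unknown log level {self.log_level!r}")


def load_config(path: Union[str, Path, None] = None) -> PackageConfig:
    """Load a YAML config; ``None`` returns the defaults."""
    if path is None:
        return PackageConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return PackageConfig()
    if not isinstance(raw, dict):
        raise InvalidInputError("config file must be a YAML mapping")
    known = {f.name for f in fields(PackageConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    if "oks_thresholds" in raw:
        raw["oks_thresholds"] = tuple(raw["oks_thresholds"])
    return PackageConfig(**raw)
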
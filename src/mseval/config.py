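"""Evaluation run configuration with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .detection import DetectionParams

__all__ = ["EvalConfig"]

SCHEMA_VERSION = 1


@dataclass
class EvalConfig:
    """Everything a challenge evaluation run needs, serializable to YAML.

    CLI flags override file values; the file carries a schema version so
    old configs fail loudly rather than silently misparse.
    """

    schema_version: int = SCHEMA_VERSION
    # detection matcher
    detection: DetectionParams = field(default_factory=DetectionParams)
    # consensus fusion
    fusion_mode: str = "lop_staple"
    fusion_threshold: float = 0.5
    fusion_max_iter: int = 100
    fusion_tol: float = 1e-6
    # clustering
    cluster_k: int = 3
    cluster_seed: int = 12345
    cluster_metrics: tuple[str, str] = ("dice", "f1")
    # metrics evaluated per pair
    metrics: tuple[str, ...] = ("dice", "ppv", "sensitivity", "specificity", "assd_mm")
    #: metrics where smaller is better (for ranking)
    lower_is_better: tuple[str, ...] = ("assd_mm",)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["detection"] = asdict(self.detection)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "EvalConfig":
        d = dict(d)
        version = d.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"config schema version {version} not supported (expected {SCHEMA_VERSION})"
            )
        if "detection" in d and not isinstance(d["detection"], DetectionParams):
            d["detection"] = DetectionParams(**d["detection"])
        for key in ("cluster_metrics", "metrics", "lower_is_better"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EvalConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
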
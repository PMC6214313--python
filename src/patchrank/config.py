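"""Run configuration: validated settings for the ranking pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import yaml

__all__ = ["RunConfig", "ConfigError"]

_VALID_METRICS = ("C_A", "C_S", "D", "C_B")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Settings controlling a ranking run.

    ``metric_set`` may be None, meaning: use (C_A, C_S, D) when site
    distances are available and (C_A, C_S) otherwise.  Explicitly asking
    for D without a distance source fails before any computation.
    """

    edges: str | None = None
    graphml: str | None = None
    patches: str | None = None          # GeoJSON polygon layer
    sites: str | None = None            # GeoJSON protected sites
    distances: str | None = None        # CSV node_id,D (precomputed)
    adjacency: str = "rook"
    metric_set: Sequence[str] | None = None
    normalization: str = "component"    # betweenness scope: component|global
    rounding: int = 2
    noise_filter: bool = False
    seed: int = 0
    outdir: str = "patchrank_out"

    def __post_init__(self) -> None:
        if self.adjacency not in ("rook", "queen"):
            raise ConfigError(f"adjacency must be rook or queen, got {self.adjacency!r}")
        if self.normalization not in ("component", "global"):
            raise ConfigError(
                f"normalization must be component or global, got {self.normalization!r}"
            )
        if self.rounding < 0:
            raise ConfigError("rounding must be >= 0")
        if self.metric_set is not None:
            self.metric_set = tuple(self.metric_set)
            bad = [m for m in self.metric_set if m not in _VALID_METRICS]
            if bad:
                raise ConfigError(
                    f"unknown metric(s) {bad}; valid: {_VALID_METRICS}"
                )
            if not self.metric_set:
                raise ConfigError("metric_set must not be empty")
        sources = [s for s in (self.edges, self.graphml, self.patches) if s]
        if len(sources) == 0:
            raise ConfigError("one of edges, graphml or patches is required")
        if len(sources) > 1:
            raise ConfigError("give exactly one of edges, graphml or patches")

    @property
    def has_distance_source(self) -> bool:
        return bool(self.sites and self.patches) or bool(self.distances)

    def resolved_metrics(self) -> tuple[str, ...]:
        if self.metric_set is not None:
            if "D" in self.metric_set and not self.has_distance_source:
                raise ConfigError(
                    "metric D requested but no site layer or distance table given"
                )
            return tuple(self.metric_set)
        if self.has_distance_source:
            return ("C_A", "C_S", "D")
        return ("C_A", "C_S")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from YAML, rejecting unknown keys; overrides win."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s): {unknown}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if d["metric_set"] is not None:
            d["metric_set"] = list(d["metric_set"])
        return d
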
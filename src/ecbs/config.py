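"""Run configuration: thresholds, permutation budget, seeds.

Loadable from a YAML key-value file; command-line flags override file
values.  Defaults match the package documentation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    alpha: float = 0.01
    gev_min_probes: int = 100
    min_width: int = 2
    small_segment: int = 15
    edge_window: int = 25
    edge_alpha: float = 0.01
    n_perm: int = 1000
    early_stop: bool = True
    presegment_alpha: float = 0.001
    presegment_min_probes: int = 100
    seed: int = 0
    jobs: int = 1
    model_path: str | None = None
    force_permutation: bool = False
    edge_correction: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("gev_min_probes", "min_width", "small_segment",
                     "edge_window", "n_perm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
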
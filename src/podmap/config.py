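"""Pipeline configuration.

Every analysis constant lives here with its default: the DEG gates
(|log2FC| > 0.58 = log2 1.5, BH p < 0.05), the goodness-of-fit gate (0.05),
the 50-bin activation grid, the activity threshold (linear fold change 1.5),
the 0.7/0.2/0.1 region weights with the 0.6 pass cut, the half-count
pseudocount for cell ratios, and the label-profile cluster count (7).
Configs load from YAML/JSON mappings and can be overridden per field.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class PipelineConfig:
    deg_fc_threshold: float = 0.58
    deg_alpha: float = 0.05
    gof_alpha: float = 0.05
    grid_bins: int = 50
    activity_threshold_linear_fc: float = 1.5
    correlation_weights: tuple[float, float, float] = (0.7, 0.2, 0.1)
    correlation_pass_threshold: float = 0.6
    pseudocount: float = 0.5
    cluster_k: int = 7
    undefined_region_policy: str = "renormalize"
    seed: int = 0

    @property
    def activity_threshold_log2(self) -> float:
        """Activity threshold on the log2 scale (log2 of the linear cut)."""
        return float(np.log2(self.activity_threshold_linear_fc))

    def __post_init__(self):
        for name in (
            "deg_fc_threshold",
            "deg_alpha",
            "gof_alpha",
            "activity_threshold_linear_fc",
            "correlation_pass_threshold",
            "pseudocount",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.grid_bins < 3:
            raise ValueError(f"grid_bins must be >= 3, got {self.grid_bins}")
        w = tuple(float(x) for x in self.correlation_weights)
        if len(w) != 3 or any(x <= 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"correlation_weights must be 3 positives summing to 1, got {w}")
        self.correlation_weights = w
        if self.cluster_k < 1:
            raise ValueError(f"cluster_k must be >= 1, got {self.cluster_k}")
        if self.undefined_region_policy not in ("renormalize", "zero"):
            raise ValueError(
                f"undefined_region_policy must be 'renormalize' or 'zero', "
                f"got {self.undefined_region_policy!r}"
            )

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Load from a YAML (or JSON) mapping; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update(overrides)
        if "correlation_weights" in data:
            data["correlation_weights"] = tuple(data["correlation_weights"])
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["correlation_weights"] = list(self.correlation_weights)
        return out

    def dump(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
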
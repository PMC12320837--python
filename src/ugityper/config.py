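"""Analysis configuration.

Every threshold of the upper-GI microbiota workflow lives here so a
run can be reproduced from a single flat YAML file.  Defaults:
rarefaction to 2907 (human) / 3404 (mouse) reads,
prevalence filter >0.1% relative abundance in at least 3 samples,
pseudocount of 1 count for zeros, correlation dendrograms cut at height 1,
the 2.5-fold cluster-dominance typing rule with the <10% low-both category,
volcano cutoffs of |log2 RNA/DNA| >= 0.6 at q < 0.1, a |rho| > 0.7 "strong
correlation" threshold, and 999 ANOSIM permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

__all__ = ["AnalysisConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised for invalid or missing configuration values."""


@dataclass
class AnalysisConfig:
    rarefaction_depth_human: int = 2907
    rarefaction_depth_mouse: int = 3404
    prevalence_min_rel: float = 0.001
    prevalence_min_samples: int = 3
    corr_min_samples: int = 5
    pseudocount: float = 1.0
    cut_height: float = 1.0
    linkage_method: str = "complete"
    fold_threshold: float = 2.5
    low_both_threshold: float = 0.10
    log2_ratio_cut: float = 0.6
    q_cut: float = 0.1
    strong_corr_cut: float = 0.7
    anosim_permutations: int = 999
    shannon_log_base: float = 2.0
    exclusion_fraction: float = 0.25
    yield_floor_ng_ul: float = 1.0
    shared_taxa_min_rel: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "rarefaction_depth_human",
            "rarefaction_depth_mouse",
            "prevalence_min_rel",
            "prevalence_min_samples",
            "corr_min_samples",
            "cut_height",
            "log2_ratio_cut",
            "q_cut",
            "strong_corr_cut",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.fold_threshold < 1:
            raise ConfigError(f"fold_threshold must be >= 1, got {self.fold_threshold}")
        if not 0 < self.low_both_threshold < 1:
            raise ConfigError(
                f"low_both_threshold must be in (0, 1), got {self.low_both_threshold}"
            )
        if self.pseudocount < 0:
            raise ConfigError(f"pseudocount must be >= 0, got {self.pseudocount}")
        if self.linkage_method not in {"complete", "average", "ward"}:
            raise ConfigError(f"unknown linkage_method {self.linkage_method!r}")

    def rarefaction_depth(self, host: str) -> int:
        if host == "human":
            return self.rarefaction_depth_human
        if host == "mouse":
            return self.rarefaction_depth_mouse
        raise ConfigError(f"unknown host {host!r}; expected 'human' or 'mouse'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}
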
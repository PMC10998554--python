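"""Pipeline configuration: every analysis threshold in one structured object.

A YAML config file maps flat keys onto :class:`PipelineConfig` fields, with
tier bounds nested under ``tier_thresholds``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .secretion_profile import TierThresholds


@dataclass
class PipelineConfig:
    # chain filtering
    require_productive: bool = True
    require_full_length: bool = True
    require_high_confidence: bool = True
    require_is_cell: bool = True
    # clonotype assembly
    max_chains_per_locus: int = 2
    clonotype_key_level: str = "nt"      # nt | aa
    min_frequency: int = 1
    # epitope deconvolution
    epitope_threshold: float = 0.90
    min_total_umis: int = 1
    epitope_mode: str = "pooled_counts"  # pooled_counts | cell_majority
    # secretion profiling
    tier_thresholds: TierThresholds = field(default_factory=TierThresholds)
    secretion_aggregate: str = "max"     # max | mean
    statistical_test: str = "mannwhitney"  # mannwhitney | welch


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "tier_thresholds" in raw:
        raw["tier_thresholds"] = TierThresholds(**raw["tier_thresholds"])
    return PipelineConfig(**raw)
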
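"""Run configuration: one structured file naming inputs, thresholds, seeds."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from .annotation import CADD_DELETERIOUS_THRESHOLD
from .druggability import ATC_ANTIHYPERTENSIVE_PREFIXES

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Thresholds and switches for a full pipeline run."""

    # candidate expansion
    mode: str = "ld_then_window"
    r2_min: float = 0.8
    window_bp: int = 50_000
    # annotation
    cadd_threshold: float = CADD_DELETERIOUS_THRESHOLD
    # specificity
    B: int = 1_000
    shift_bp: int = 500_000
    seed: int = 1
    # variant-to-gene
    promoter_up: int = 2_000
    promoter_down: int = 500
    include_trans: bool = False
    min_interaction_score: Optional[float] = None
    # eQTL integration
    q_max: float = 0.05
    tissues: Optional[list[str]] = None  # whitelist; None = all
    # druggability
    atc_prefixes: list[str] = field(
        default_factory=lambda: list(ATC_ANTIHYPERTENSIVE_PREFIXES)
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
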
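"""Pipeline configuration with the published decision constants as defaults.

All thresholds the pipeline applies — the anterior-Bolton stratification
bounds, both normative standards, the significance level — live here so a
run is fully described by (cohort, config, seed).  The config serialises
to and from YAML for reproducible analyses.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

from .derivation import BoltonGroupBounds
from .norms import BOLTON_STANDARD, SATR_STANDARD, NormStandard

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    bolton_bounds: BoltonGroupBounds = field(default_factory=BoltonGroupBounds)
    bolton_standard: NormStandard = BOLTON_STANDARD
    satr_standard: NormStandard = SATR_STANDARD
    alpha: float = 0.05
    t_variant: str = "auto"  # 'pooled' | 'welch' | 'auto' (Levene-gated)
    positive_condition: str = "normal"
    #: 'full' classifies against full-precision thresholds; 'strict' clamps
    #: standards to their printed 2-decimal values first.
    rounding: str = "full"
    #: Establish the in-cohort SATR standard from subjects with a normal
    #: Bolton diagnosis ('normal_abr') or from every subject ('all').
    norm_source: str = "normal_abr"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_variant not in ("pooled", "welch", "auto"):
            raise ValueError(f"t_variant {self.t_variant!r} invalid")
        if self.positive_condition not in ("normal", "abnormal"):
            raise ValueError(f"positive_condition {self.positive_condition!r} invalid")
        if self.rounding not in ("full", "strict"):
            raise ValueError(f"rounding {self.rounding!r} invalid")
        if self.norm_source not in ("normal_abr", "all"):
            raise ValueError(f"norm_source {self.norm_source!r} invalid")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")

    def effective_standard(self, which: str = "satr") -> NormStandard:
        std = self.satr_standard if which == "satr" else self.bolton_standard
        return std.rounded(2) if self.rounding == "strict" else std

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "bolton_bounds": {
                "low_upper": self.bolton_bounds.low_upper,
                "high_lower": self.bolton_bounds.high_lower,
            },
            "bolton_standard": asdict(self.bolton_standard),
            "satr_standard": asdict(self.satr_standard),
            "alpha": self.alpha,
            "t_variant": self.t_variant,
            "positive_condition": self.positive_condition,
            "rounding": self.rounding,
            "norm_source": self.norm_source,
            "seed": self.seed,
        }

    def to_yaml(self, path=None) -> "str | None":
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "bolton_bounds" in d:
            d["bolton_bounds"] = BoltonGroupBounds(**d["bolton_bounds"])
        for key in ("bolton_standard", "satr_standard"):
            if key in d and isinstance(d[key], dict):
                d[key] = NormStandard(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source, "r", encoding="utf-8") as fh:
                    data = yaml.safe_load(fh.read())
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        return cls.from_dict(data or {})
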
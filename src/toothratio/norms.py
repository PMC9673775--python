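"""Normative standards (mean +/- k*SD) and three-way ratio classification.

A ratio value is classified against a normative range as deficient (below
the lower bound), normal (within, bounds inclusive) or excess (above).
Two standards ship as defaults: the simplified anterior tooth ratio
standard 85.69% +/- 3.57% and the anterior Bolton norm for the Chinese
population 78.8% +/- 1.72%, whose k = 1 bounds (82.12/89.26 and
77.08/80.52) define the published decision thresholds.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DiagnosisLabel",
    "NormStandard",
    "SATR_STANDARD",
    "BOLTON_STANDARD",
    "establish_standard",
    "classify",
]


class DiagnosisLabel(enum.IntEnum):
    """Ordered three-way diagnosis: deficient < normal < excess."""

    DEFICIENT = 0
    NORMAL = 1
    EXCESS = 2

    def __str__(self) -> str:
        return self.name.lower()

    @classmethod
    def parse(cls, value: "str | DiagnosisLabel") -> "DiagnosisLabel":
        if isinstance(value, cls):
            return value
        return cls[str(value).upper()]


@dataclass(frozen=True)
class NormStandard:
    """A mean +/- k*SD normative range, in percent."""

    mean: float
    sd: float
    k: float = 1.0
    n: "int | None" = None
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")
        if self.k < 0:
            raise ValueError(f"k must be non-negative, got {self.k}")

    @property
    def lower(self) -> float:
        return self.mean - self.k * self.sd

    @property
    def upper(self) -> float:
        return self.mean + self.k * self.sd

    def rounded(self, decimals: int = 2) -> "NormStandard":
        """Standard with mean and SD clamped to the printed precision.

        Classification against the rounded standard reproduces published
        tables exactly ("strict" mode); the unrounded standard is the
        full-precision default.
        """
        return NormStandard(
            mean=round(self.mean, decimals),
            sd=round(self.sd, decimals),
            k=self.k,
            n=self.n,
            name=self.name,
        )

    def __str__(self) -> str:
        return (
            f"{self.name}: {self.mean:.2f}% +/- {self.sd:.2f}% "
            f"(k={self.k:g}, normal {self.lower:.2f}-{self.upper:.2f}%)"
        )


#: Published simplified-anterior-tooth-ratio standard (n = 132 ideal occlusions).
SATR_STANDARD = NormStandard(mean=85.69, sd=3.57, k=1.0, n=132, name="SATR")
#: Anterior Bolton ratio norm for the Chinese population.
BOLTON_STANDARD = NormStandard(mean=78.8, sd=1.72, k=1.0, name="ABR")


def establish_standard(
    values: Sequence[float], k: float = 1.0, name: str = "custom"
) -> NormStandard:
    """Normative standard from observed ratio percents: mean +/- k * sample SD.

    The SD uses the n-1 denominator.  At least two values are required.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValueError("need at least 2 values to establish a standard")
    return NormStandard(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        k=k,
        n=len(arr),
        name=name,
    )


def classify(value: float, standard: NormStandard) -> DiagnosisLabel:
    """Deficient / normal / excess for a ratio percent against a standard.

    Bounds are inclusive to normal: value < lower -> deficient,
    value > upper -> excess, otherwise normal.  Boundary comparisons carry
    a 1e-9 relative guard so a threshold stated in decimal (e.g. 89.26 =
    85.69 + 3.57) stays inclusive despite binary-float representation.
    """
    if not value > 0:
        raise ValueError(f"ratio must be positive, got {value}")
    eps = 1e-9 * max(1.0, abs(standard.mean))
    if value < standard.lower - eps:
        return DiagnosisLabel.DEFICIENT
    if value > standard.upper + eps:
        return DiagnosisLabel.EXCESS
    return DiagnosisLabel.NORMAL
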
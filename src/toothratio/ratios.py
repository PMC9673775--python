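"""Inter-arch tooth-width ratios.

The anterior Bolton ratio (ABR) is the classic index of anterior tooth-size
proportion: the summed mesiodistal widths of the six mandibular anterior
teeth over the six maxillary anterior teeth, expressed as a percentage.  The
simplified anterior tooth ratio (SATR) restricts both sums to the lateral
incisors, the "key teeth" whose size variation drives ABR abnormality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .teeth import (
    ANTERIOR_FDI_CODES,
    SATR_FDI_CODES,
    AnteriorWidths,
    ToothRef,
    WidthError,
    _tooth,
)

__all__ = ["RatioResult", "generic_ratio", "anterior_bolton_ratio", "satr"]


@dataclass(frozen=True)
class RatioResult:
    """A lower/upper width ratio with its numerator and denominator."""

    kind: str  # "ABR", "SATR" or "custom"
    value: float  # percent, 100 * lower_sum / upper_sum
    lower_sum: float  # mm
    upper_sum: float  # mm
    teeth_used: tuple[ToothRef, ...]

    def __str__(self) -> str:
        return f"{self.kind} = {self.value:.2f}% ({self.lower_sum:.3f}/{self.upper_sum:.3f} mm)"


def generic_ratio(
    record: AnteriorWidths,
    lower_teeth: Sequence,
    upper_teeth: Sequence,
    kind: str = "custom",
) -> RatioResult:
    """100 x sum(lower widths) / sum(upper widths) for arbitrary tooth sets.

    Both named ratios are this operation with fixed tooth sets.  Tooth lists
    must be non-empty and arch-consistent; cross-arch sets are rejected.
    """
    lower = [_tooth(c) for c in lower_teeth]
    upper = [_tooth(c) for c in upper_teeth]
    if not lower or not upper:
        raise WidthError("tooth sets must be non-empty")
    bad_low = [t.fdi_code for t in lower if t.arch != "lower"]
    bad_up = [t.fdi_code for t in upper if t.arch != "upper"]
    if bad_low or bad_up:
        raise WidthError(
            f"arch mismatch: non-mandibular in lower set {bad_low}, "
            f"non-maxillary in upper set {bad_up}"
        )
    missing = [t.fdi_code for t in lower + upper if not record.has(t)]
    if missing:
        raise WidthError(
            f"subject {record.subject_id!r}: missing teeth {sorted(missing)}"
        )
    lower_sum = sum(record.width(t) for t in lower)
    upper_sum = sum(record.width(t) for t in upper)
    return RatioResult(
        kind=kind,
        value=100.0 * lower_sum / upper_sum,
        lower_sum=lower_sum,
        upper_sum=upper_sum,
        teeth_used=tuple(sorted(lower + upper)),
    )


def anterior_bolton_ratio(record: AnteriorWidths) -> RatioResult:
    """Anterior Bolton ratio over all 12 anterior teeth (record must be complete)."""
    lower = [c for c in ANTERIOR_FDI_CODES if c >= 30]
    upper = [c for c in ANTERIOR_FDI_CODES if c < 30]
    return generic_ratio(record, lower, upper, kind="ABR")


def satr(record: AnteriorWidths) -> RatioResult:
    """Simplified anterior tooth ratio: lower laterals over upper laterals.

    SATR% = 100 x (w32 + w42) / (w12 + w22).
    """
    return generic_ratio(record, (32, 42), (12, 22), kind="SATR")
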
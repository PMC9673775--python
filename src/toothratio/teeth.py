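"""Data model and I/O for per-subject anterior tooth-width records.

Tooth identity uses FDI two-digit notation. Only the 12 permanent anterior
teeth (incisors and canines of both arches) are modelled: quadrants 1-2 are
maxillary, 3-4 mandibular; position 1 is the central incisor, 2 the lateral
incisor, 3 the canine. Mesiodistal crown widths are stored in millimetres at
full floating precision.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ANTERIOR_FDI_CODES",
    "SATR_FDI_CODES",
    "ToothRef",
    "AnteriorWidths",
    "Cohort",
    "ValidationReport",
    "WidthError",
    "validate",
    "bilateral_mean",
    "cohort_summary",
    "load_widths",
    "write_widths",
]

#: Canonical column order for the wide CSV layout (upper right -> lower right).
ANTERIOR_FDI_CODES: tuple[int, ...] = (13, 12, 11, 21, 22, 23, 33, 32, 31, 41, 42, 43)

#: The four lateral incisors needed for the simplified anterior tooth ratio.
SATR_FDI_CODES: tuple[int, ...] = (12, 22, 32, 42)

_POSITION_TYPE = {1: "central", 2: "lateral", 3: "canine"}

#: Default plausibility window for a mesiodistal width, mm.  Wide enough for
#: real anatomical variation, narrow enough to catch cm-vs-mm unit errors.
DEFAULT_WIDTH_WINDOW: tuple[float, float] = (3.0, 15.0)


class WidthError(ValueError):
    """Raised for structurally invalid tooth-width data."""


@dataclass(frozen=True, order=True)
class ToothRef:
    """A single permanent anterior tooth identified by its FDI code."""

    fdi_code: int

    def __post_init__(self) -> None:
        if self.fdi_code not in ANTERIOR_FDI_CODES:
            raise WidthError(
                f"FDI code {self.fdi_code} is not one of the 12 permanent "
                f"anterior teeth {sorted(ANTERIOR_FDI_CODES)}"
            )

    @property
    def quadrant(self) -> int:
        return self.fdi_code // 10

    @property
    def arch(self) -> str:
        """'upper' (quadrants 1-2) or 'lower' (quadrants 3-4)."""
        return "upper" if self.quadrant in (1, 2) else "lower"

    @property
    def tooth_type(self) -> str:
        """'central', 'lateral' or 'canine' from the position digit."""
        return _POSITION_TYPE[self.fdi_code % 10]

    @property
    def side(self) -> str:
        """Patient's right (quadrants 1 and 4) or left (quadrants 2 and 3)."""
        return "right" if self.quadrant in (1, 4) else "left"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return str(self.fdi_code)


def _tooth(code: "int | str | ToothRef") -> ToothRef:
    if isinstance(code, ToothRef):
        return code
    try:
        return ToothRef(int(code))
    except (TypeError, ValueError) as exc:
        raise WidthError(f"invalid FDI tooth code {code!r}") from exc


def tooth_pair(arch: str, tooth_type: str) -> tuple[ToothRef, ToothRef]:
    """Both (right, left) teeth of one arch and tooth type."""
    refs = [
        ToothRef(c)
        for c in ANTERIOR_FDI_CODES
        if ToothRef(c).arch == arch and ToothRef(c).tooth_type == tooth_type
    ]
    right = next(r for r in refs if r.side == "right")
    left = next(r for r in refs if r.side == "left")
    return right, left


@dataclass
class AnteriorWidths:
    """Mesiodistal crown widths (mm) of one subject's anterior teeth."""

    subject_id: str
    widths: dict[ToothRef, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[ToothRef, float] = {}
        for code, w in self.widths.items():
            ref = _tooth(code)
            w = float(w)
            if not w > 0:
                raise WidthError(
                    f"subject {self.subject_id!r}: width {w} for tooth "
                    f"{ref} must be strictly positive"
                )
            clean[ref] = w
        self.widths = clean

    def width(self, code: "int | ToothRef") -> float:
        ref = _tooth(code)
        try:
            return self.widths[ref]
        except KeyError:
            raise WidthError(
                f"subject {self.subject_id!r}: tooth {ref} not measured"
            ) from None

    def has(self, code: "int | ToothRef") -> bool:
        return _tooth(code) in self.widths

    @property
    def is_bolton_complete(self) -> bool:
        """All 12 anterior teeth present (anterior Bolton ratio computable)."""
        return all(self.has(c) for c in ANTERIOR_FDI_CODES)

    @property
    def is_satr_complete(self) -> bool:
        """All four lateral incisors present (SATR computable)."""
        return all(self.has(c) for c in SATR_FDI_CODES)

    def missing(self, requirement: str = "bolton") -> list[int]:
        codes = ANTERIOR_FDI_CODES if requirement == "bolton" else SATR_FDI_CODES
        return [c for c in codes if not self.has(c)]


@dataclass
class Cohort:
    """An ordered collection of subjects with optional group labels."""

    records: list[AnteriorWidths] = field(default_factory=list)
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise WidthError(f"duplicate subject ids in cohort: {dupes}")
        extraneous = set(self.groups) - set(ids)
        if extraneous:
            raise WidthError(f"group labels for unknown subjects: {sorted(extraneous)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subject(self, subject_id: str) -> AnteriorWidths:
        for r in self.records:
            if r.subject_id == subject_id:
                return r
        raise KeyError(subject_id)

    def with_groups(self, groups: Mapping[str, str]) -> "Cohort":
        return Cohort(records=list(self.records), groups=dict(groups))


@dataclass
class ValidationReport:
    """Outcome of checking a record against a completeness requirement."""

    subject_id: str
    requirement: str
    missing_codes: list[int]
    implausible: list[tuple[int, float]]  # (code, width) outside the window

    @property
    def ok(self) -> bool:
        return not self.missing_codes and not self.implausible

    def __str__(self) -> str:
        if self.ok:
            return f"{self.subject_id}: OK for {self.requirement}"
        parts = []
        if self.missing_codes:
            parts.append(f"missing teeth {self.missing_codes}")
        if self.implausible:
            parts.append(
                "implausible widths "
                + ", ".join(f"{c}={w:g} mm" for c, w in self.implausible)
            )
        return f"{self.subject_id}: " + "; ".join(parts)


def validate(
    record: AnteriorWidths,
    requirement: str = "bolton",
    window: tuple[float, float] = DEFAULT_WIDTH_WINDOW,
) -> ValidationReport:
    """Report missing teeth and widths outside the plausibility window.

    The report is empty (``.ok``) iff the record satisfies ``requirement``
    ('bolton': all 12 teeth; 'satr': the four lateral incisors) and every
    stored width lies within ``window``.
    """
    if requirement not in ("bolton", "satr"):
        raise ValueError(f"requirement must be 'bolton' or 'satr', got {requirement!r}")
    lo, hi = window
    implausible = sorted(
        (ref.fdi_code, w)
        for ref, w in record.widths.items()
        if not (lo <= w <= hi)
    )
    return ValidationReport(
        subject_id=record.subject_id,
        requirement=requirement,
        missing_codes=record.missing(requirement),
        implausible=implausible,
    )


def bilateral_mean(record: AnteriorWidths, arch: str, tooth_type: str) -> float:
    """Mean of the left and right widths of one tooth type in one arch."""
    right, left = tooth_pair(arch, tooth_type)
    return (record.width(right) + record.width(left)) / 2.0


TOOTH_TYPE_ORDER: tuple[tuple[str, str], ...] = (
    ("upper", "central"),
    ("upper", "lateral"),
    ("upper", "canine"),
    ("lower", "central"),
    ("lower", "lateral"),
    ("lower", "canine"),
)


def cohort_summary(cohort: Cohort, groups: "Mapping[str, str] | None" = None) -> pd.DataFrame:
    """Per-group, per-tooth-type mean and sample SD of bilateral mean widths.

    Returns a DataFrame indexed by (group, arch, tooth_type) with columns
    ``n``, ``mean_mm``, ``sd_mm``.  SD uses the n-1 denominator; for a group
    of one subject the SD is reported as NaN (undefined), not 0.
    """
    if groups is None:
        groups = cohort.groups or {r.subject_id: "all" for r in cohort.records}
    unlabeled = [r.subject_id for r in cohort.records if r.subject_id not in groups]
    if unlabeled:
        raise WidthError(f"subjects without a group label: {unlabeled}")

    rows = []
    for rec in cohort.records:
        for arch, ttype in TOOTH_TYPE_ORDER:
            rows.append(
                {
                    "group": groups[rec.subject_id],
                    "arch": arch,
                    "tooth_type": ttype,
                    "width": bilateral_mean(rec, arch, ttype),
                }
            )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["group", "arch", "tooth_type"], sort=False)["width"]
        .agg(n="count", mean_mm="mean", sd_mm=lambda s: s.std(ddof=1))
        .reset_index()
        .set_index(["group", "arch", "tooth_type"])
    )
    return out


# ---------------------------------------------------------------------------
# CSV I/O
#
# Wide layout:  subject_id,13,12,11,21,22,23,33,32,31,41,42,43[,group]
# Long layout:  subject_id,tooth_fdi,width_mm
# ---------------------------------------------------------------------------


def load_widths(source, layout: str = "wide") -> Cohort:
    """Read a cohort from a CSV file path or text stream.

    Unknown tooth codes or non-numeric widths raise :class:`WidthError`
    naming the offending value; nothing is silently dropped.  Duplicate
    (subject, tooth) entries and empty files are hard errors.
    """
    if layout not in ("wide", "long"):
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    try:
        df = pd.read_csv(source, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise WidthError("empty input: no CSV content") from None
    if df.empty:
        raise WidthError("empty input: CSV has a header but no rows")
    df.columns = [str(c).strip() for c in df.columns]
    if layout == "wide":
        return _load_wide(df)
    return _load_long(df)


def _parse_width(raw, subject: str, code: int) -> float:
    try:
        w = float(raw)
    except (TypeError, ValueError):
        raise WidthError(
            f"subject {subject!r}, tooth {code}: non-numeric width {raw!r}"
        ) from None
    if not w > 0:
        raise WidthError(f"subject {subject!r}, tooth {code}: width {w} not positive")
    return w


def _load_wide(df: pd.DataFrame) -> Cohort:
    if "subject_id" not in df.columns:
        raise WidthError("wide CSV must have a 'subject_id' column")
    tooth_cols = [c for c in df.columns if c not in ("subject_id", "group")]
    for c in tooth_cols:
        if not (c.isdigit() and int(c) in ANTERIOR_FDI_CODES):
            raise WidthError(f"column {c!r} is not an anterior FDI tooth code")
    records, groups = [], {}
    for _, row in df.iterrows():
        sid = str(row["subject_id"]).strip()
        widths = {}
        for c in tooth_cols:
            raw = row[c]
            if pd.isna(raw) or str(raw).strip() == "":
                continue
            widths[ToothRef(int(c))] = _parse_width(raw, sid, int(c))
        records.append(AnteriorWidths(subject_id=sid, widths=widths))
        if "group" in df.columns and not pd.isna(row["group"]):
            groups[sid] = str(row["group"]).strip()
    return Cohort(records=records, groups=groups)


def _load_long(df: pd.DataFrame) -> Cohort:
    required = {"subject_id", "tooth_fdi", "width_mm"}
    if not required.issubset(df.columns):
        raise WidthError(f"long CSV must have columns {sorted(required)}")
    per_subject: dict[str, dict[ToothRef, float]] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"]).strip()
        raw_code = str(row["tooth_fdi"]).strip()
        if not (raw_code.isdigit() and int(raw_code) in ANTERIOR_FDI_CODES):
            raise WidthError(
                f"subject {sid!r}: tooth code {raw_code!r} is not an "
                "anterior FDI code"
            )
        ref = ToothRef(int(raw_code))
        if sid not in per_subject:
            per_subject[sid] = {}
            order.append(sid)
        if ref in per_subject[sid]:
            raise WidthError(f"duplicate entry for subject {sid!r}, tooth {ref}")
        per_subject[sid][ref] = _parse_width(row["width_mm"], sid, ref.fdi_code)
    records = [AnteriorWidths(sid, per_subject[sid]) for sid in order]
    return Cohort(records=records)


def write_widths(cohort: Cohort, target=None, layout: str = "wide") -> "str | None":
    """Write a cohort as CSV; returns the text if ``target`` is None.

    Round-trips with :func:`load_widths` at full stored precision.
    """
    if layout == "wide":
        rows = []
        for rec in cohort.records:
            row = {"subject_id": rec.subject_id}
            for code in ANTERIOR_FDI_CODES:
                row[str(code)] = rec.widths.get(ToothRef(code))
            if cohort.groups:
                row["group"] = cohort.groups.get(rec.subject_id)
            rows.append(row)
        df = pd.DataFrame(rows)
    elif layout == "long":
        rows = [
            {"subject_id": rec.subject_id, "tooth_fdi": ref.fdi_code, "width_mm": w}
            for rec in cohort.records
            for ref, w in sorted(rec.widths.items(), key=lambda kv: ANTERIOR_FDI_CODES.index(kv[0].fdi_code))
        ]
        df = pd.DataFrame(rows)
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    text = df.to_csv(index=False, float_format="%.17g")
    if target is None:
        return text
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(text)
    return None
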
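"""Key-tooth derivation: ratio stratification and pairwise width tests.

Subjects are stratified by their anterior Bolton ratio into low (< 77.08%),
normal (77.08-80.52%) and high (> 80.52%) groups.  For every arch x tooth
type, bilateral-mean widths are compared between each pair of groups with an
independent two-sample t-test.  The tooth type per arch that differs
significantly in all three comparisons is the "key tooth" — the basis of the
simplified ratio.

The t statistic is computed from closed forms (pooled and Welch); the
default variant is chosen per comparison by Levene's test on variance
homogeneity, mirroring the SPSS workflow of the source analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .teeth import TOOTH_TYPE_ORDER, Cohort, WidthError, bilateral_mean
from .ratios import anterior_bolton_ratio

__all__ = [
    "BoltonGroupBounds",
    "assign_bolton_group",
    "levene_mean_center",
    "t_test",
    "TTestResult",
    "PairwiseTest",
    "pairwise_tooth_tests",
    "KeyTeethSelection",
    "select_key_teeth",
    "label_cohort_by_abr",
]

GROUP_ORDER = ("low", "normal", "high")
#: The three group pairs tested per tooth type, in reporting order.
COMPARISONS = ("normal-vs-small", "normal-vs-large", "small-vs-large")
_COMPARISON_GROUPS = {
    "normal-vs-small": ("normal", "low"),
    "normal-vs-large": ("normal", "high"),
    "small-vs-large": ("low", "high"),
}


@dataclass(frozen=True)
class BoltonGroupBounds:
    """Boundaries of the normal anterior-Bolton range (percent)."""

    low_upper: float = 77.08
    high_lower: float = 80.52

    def __post_init__(self) -> None:
        if not self.low_upper < self.high_lower:
            raise ValueError(
                f"low_upper ({self.low_upper}) must be below high_lower "
                f"({self.high_lower})"
            )


def assign_bolton_group(abr: float, bounds: BoltonGroupBounds = BoltonGroupBounds()) -> str:
    """'low', 'normal' or 'high' for an anterior Bolton ratio in percent.

    Boundary values belong to the normal group; the outer groups are strict.
    """
    if not abr > 0:
        raise ValueError(f"ratio must be positive, got {abr}")
    if abr < bounds.low_upper:
        return "low"
    if abr > bounds.high_lower:
        return "high"
    return "normal"


def label_cohort_by_abr(
    cohort: Cohort, bounds: BoltonGroupBounds = BoltonGroupBounds()
) -> Cohort:
    """Attach low/normal/high labels computed from each subject's ABR."""
    groups = {
        rec.subject_id: assign_bolton_group(anterior_bolton_ratio(rec).value, bounds)
        for rec in cohort.records
    }
    return cohort.with_groups(groups)


# ---------------------------------------------------------------------------
# Two-sample t-test, closed forms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str  # 'pooled' or 'welch'


def levene_mean_center(a: Sequence[float], b: Sequence[float]) -> float:
    """p-value of Levene's variance-homogeneity test centred at the mean.

    Equivalent to a one-way ANOVA on absolute deviations from each group
    mean (the classic Levene statistic, as distinct from the Brown-Forsythe
    median-centred variant).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    za = np.abs(a - a.mean())
    zb = np.abs(b - b.mean())
    n1, n2 = len(za), len(zb)
    n = n1 + n2
    grand = (za.sum() + zb.sum()) / n
    ss_between = n1 * (za.mean() - grand) ** 2 + n2 * (zb.mean() - grand) ** 2
    ss_within = ((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()
    if ss_within == 0.0:
        return 1.0 if ss_between == 0.0 else 0.0
    f = ss_between / 1.0 / (ss_within / (n - 2))
    return float(stats.f.sf(f, 1, n - 2))


def t_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    variant: str = "auto",
    levene_alpha: float = 0.05,
) -> TTestResult:
    """Independent two-sample t-test from closed forms.

    variant 'pooled' assumes equal variances; 'welch' does not; 'auto'
    gates on Levene's test (mean-centred): pooled when its p > levene_alpha.
    Two degenerate cases: both samples constant with equal means gives
    t = 0, p = 1; constant with unequal means is undefined and raises.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if variant not in ("pooled", "welch", "auto"):
        raise ValueError(f"unknown variant {variant!r}")

    n1, n2 = len(a), len(b)
    m1, m2 = a.mean(), b.mean()
    v1 = a.var(ddof=1)
    v2 = b.var(ddof=1)

    if v1 == 0.0 and v2 == 0.0:
        if m1 == m2:
            return TTestResult(t=0.0, df=float(n1 + n2 - 2), p=1.0,
                               variant="pooled" if variant != "welch" else "welch")
        raise ZeroDivisionError(
            "t statistic undefined: zero variance in both samples with "
            "unequal means"
        )

    if variant == "auto":
        variant = "pooled" if levene_mean_center(a, b) > levene_alpha else "welch"

    if variant == "pooled":
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        se2_1, se2_2 = v1 / n1, v2 / n2
        se = math.sqrt(se2_1 + se2_2)
        df = (se2_1 + se2_2) ** 2 / (
            se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1)
        )
    t = (m1 - m2) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p=p, variant=variant)


# ---------------------------------------------------------------------------
# Pairwise tooth tests and key-tooth selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseTest:
    """One group-pair comparison of bilateral-mean widths for a tooth type."""

    arch: str
    tooth_type: str
    comparison: str  # one of COMPARISONS
    t: float
    df: float
    p: float
    variant: str


def pairwise_tooth_tests(
    cohort: Cohort,
    variant: str = "auto",
    groups: "Mapping[str, str] | None" = None,
) -> list[PairwiseTest]:
    """All 18 comparisons (6 tooth types x 3 group pairs) on bilateral means.

    No multiple-testing correction is applied.  Groups must be labelled
    'low', 'normal', 'high' with at least two subjects each.
    """
    labels = dict(groups) if groups is not None else dict(cohort.groups)
    if not labels:
        raise WidthError("cohort has no low/normal/high group labels")
    unknown = sorted(set(labels.values()) - set(GROUP_ORDER))
    if unknown:
        raise WidthError(f"unknown group labels {unknown}; expected {GROUP_ORDER}")

    by_group: dict[str, list] = {g: [] for g in GROUP_ORDER}
    for rec in cohort.records:
        if rec.subject_id not in labels:
            raise WidthError(f"subject {rec.subject_id!r} has no group label")
        by_group[labels[rec.subject_id]].append(rec)
    for g in GROUP_ORDER:
        if len(by_group[g]) < 2:
            raise WidthError(
                f"group {g!r} has {len(by_group[g])} subject(s); need >= 2"
            )

    widths = {
        g: {
            key: np.array([bilateral_mean(rec, *key) for rec in recs])
            for key in TOOTH_TYPE_ORDER
        }
        for g, recs in by_group.items()
    }

    out: list[PairwiseTest] = []
    for arch, ttype in TOOTH_TYPE_ORDER:
        for comparison in COMPARISONS:
            ga, gb = _COMPARISON_GROUPS[comparison]
            res = t_test(widths[ga][(arch, ttype)], widths[gb][(arch, ttype)], variant)
            out.append(
                PairwiseTest(
                    arch=arch,
                    tooth_type=ttype,
                    comparison=comparison,
                    t=res.t,
                    df=res.df,
                    p=res.p,
                    variant=res.variant,
                )
            )
    return out


@dataclass(frozen=True)
class KeyTeethSelection:
    """The tooth type per arch significant in all three group comparisons."""

    upper_type: "str | None"
    lower_type: "str | None"
    alpha: float = 0.05


def select_key_teeth(tests: Iterable[PairwiseTest], alpha: float = 0.05) -> KeyTeethSelection:
    """Select, per arch, the tooth type with p < alpha in all 3 comparisons.

    Returns None for an arch where no type qualifies; raises if more than
    one type qualifies in the same arch (ambiguous selection is surfaced,
    not resolved silently).
    """
    tests = list(tests)
    seen = {(t.arch, t.tooth_type, t.comparison) for t in tests}
    expected = {
        (arch, ttype, comp)
        for arch, ttype in TOOTH_TYPE_ORDER
        for comp in COMPARISONS
    }
    if seen != expected:
        missing = sorted(expected - seen)
        raise ValueError(f"incomplete test set; missing comparisons {missing}")

    chosen: dict[str, "str | None"] = {}
    for arch in ("upper", "lower"):
        qualifying = []
        for _, ttype in (k for k in TOOTH_TYPE_ORDER if k[0] == arch):
            ps = [t.p for t in tests if t.arch == arch and t.tooth_type == ttype]
            if all(p < alpha for p in ps):
                qualifying.append(ttype)
        if len(qualifying) > 1:
            raise ValueError(
                f"ambiguous key-tooth selection in {arch} arch: "
                f"{qualifying} all significant in every comparison"
            )
        chosen[arch] = qualifying[0] if qualifying else None
    return KeyTeethSelection(upper_type=chosen["upper"], lower_type=chosen["lower"], alpha=alpha)
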
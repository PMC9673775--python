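"""Diagnostic evaluation of a screening ratio against a gold standard.

The screening diagnosis (rows) and the gold-standard diagnosis (columns)
are cross-tabulated over the three categories deficient/normal/excess,
collapsed to a 2x2 normal-vs-abnormal table, and summarised by sensitivity,
specificity, PPV and NPV.  Following the source convention these are
computed with *normal* as the positive condition (the screening question
is "does this patient have a normal anterior ratio?"); the convention is
explicit and swappable.

Consistency of the two methods' marginal diagnosis distributions is tested
with a 2x3 Pearson chi-square (no continuity correction) on the stacked
row/column margins.  Paired-agreement statistics (Cohen's kappa, Bowker
symmetry, Stuart-Maxwell marginal homogeneity) are available as extras.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .norms import DiagnosisLabel

__all__ = [
    "CrossTable3",
    "CrossTable2",
    "DiagnosticMetrics",
    "MarginalChiSquareResult",
    "cross_tabulate",
    "collapse_to_binary",
    "diagnostic_metrics",
    "marginal_chi_square",
    "cohen_kappa",
    "bowker_symmetry",
    "stuart_maxwell",
]

_LABELS3 = (DiagnosisLabel.DEFICIENT, DiagnosisLabel.NORMAL, DiagnosisLabel.EXCESS)
LABEL_NAMES3 = ("deficient", "normal", "excess")
LABEL_NAMES2 = ("normal", "abnormal")


@dataclass(frozen=True)
class CrossTable3:
    """3x3 paired-diagnosis counts; rows = screening test, cols = gold standard.

    Row/column order is deficient, normal, excess.
    """

    counts: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (3, 3):
            raise ValueError(f"counts must be 3x3, got shape {arr.shape}")
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if arr.sum() == 0:
            raise ValueError("grand total must be positive")
        object.__setattr__(
            self, "counts", tuple(tuple(int(c) for c in row) for row in arr)
        )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    @property
    def row_totals(self) -> tuple[int, int, int]:
        return tuple(int(x) for x in self.array.sum(axis=1))

    @property
    def col_totals(self) -> tuple[int, int, int]:
        return tuple(int(x) for x in self.array.sum(axis=0))

    @property
    def grand_total(self) -> int:
        return int(self.array.sum())


@dataclass(frozen=True)
class CrossTable2:
    """2x2 counts; rows = screening test, cols = gold; order normal, abnormal."""

    counts: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (2, 2):
            raise ValueError(f"counts must be 2x2, got shape {arr.shape}")
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(
            self, "counts", tuple(tuple(int(c) for c in row) for row in arr)
        )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    @property
    def grand_total(self) -> int:
        return int(self.array.sum())


def cross_tabulate(pred: Sequence, gold: Sequence) -> CrossTable3:
    """Count paired (screening, gold) diagnoses into a 3x3 table."""
    if len(pred) != len(gold):
        raise ValueError(
            f"label lists must align by subject: {len(pred)} vs {len(gold)}"
        )
    if len(pred) == 0:
        raise ValueError("need at least one subject")
    counts = np.zeros((3, 3), dtype=int)
    for p, g in zip(pred, gold):
        counts[DiagnosisLabel.parse(p), DiagnosisLabel.parse(g)] += 1
    return CrossTable3(counts=tuple(map(tuple, counts)))


def collapse_to_binary(t3: CrossTable3) -> CrossTable2:
    """Pool deficient and excess into 'abnormal'; normal is preserved."""
    a = t3.array
    normal = DiagnosisLabel.NORMAL
    abn = [DiagnosisLabel.DEFICIENT, DiagnosisLabel.EXCESS]
    nn = a[normal, normal]
    na = a[normal, abn].sum()
    an = a[abn, normal].sum()
    aa = a[np.ix_(abn, abn)].sum()
    return CrossTable2(counts=((int(nn), int(na)), (int(an), int(aa))))


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV in percent; NaN marks an undefined metric."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    positive_condition: str = "normal"

    def rounded(self, decimals: int = 2) -> "DiagnosticMetrics":
        return DiagnosticMetrics(
            *(round(v, decimals) for v in
              (self.sensitivity, self.specificity, self.ppv, self.npv)),
            positive_condition=self.positive_condition,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def _safe_pct(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def diagnostic_metrics(t2: CrossTable2, positive: str = "normal") -> DiagnosticMetrics:
    """Sen/Spe/PPV/NPV of the screening test from a 2x2 table.

    With positive='normal' (the default convention here), a true positive
    is a subject called normal by both methods.  positive='abnormal' swaps
    the roles, exchanging sensitivity with specificity and PPV with NPV.
    A zero denominator leaves that metric NaN; the others are still
    computed.
    """
    if positive not in LABEL_NAMES2:
        raise ValueError(f"positive must be one of {LABEL_NAMES2}")
    a = t2.array
    if positive == "abnormal":
        a = a[::-1, ::-1]
    tp, fp = int(a[0, 0]), int(a[0, 1])
    fn, tn = int(a[1, 0]), int(a[1, 1])
    return DiagnosticMetrics(
        sensitivity=_safe_pct(tp, tp + fn),
        specificity=_safe_pct(tn, tn + fp),
        ppv=_safe_pct(tp, tp + fp),
        npv=_safe_pct(tn, tn + fn),
        positive_condition=positive,
    )


@dataclass(frozen=True)
class MarginalChiSquareResult:
    statistic: float
    df: int
    p: float


def marginal_chi_square(t3: CrossTable3) -> MarginalChiSquareResult:
    """Pearson chi-square comparing the two methods' marginal distributions.

    Builds the 2x3 table whose first row is the screening test's diagnosis
    totals and second row the gold standard's, and computes the ordinary
    chi-square of independence (sum of (obs-exp)^2/exp, no continuity
    correction) on 2 degrees of freedom.
    """
    obs = np.array([t3.row_totals, t3.col_totals], dtype=float)
    col_sums = obs.sum(axis=0)
    if (col_sums == 0).any():
        dead = [LABEL_NAMES3[i] for i in np.flatnonzero(col_sums == 0)]
        raise ZeroDivisionError(
            f"expected count zero: category {dead} empty in both margins"
        )
    row_sums = obs.sum(axis=1, keepdims=True)
    expected = row_sums * col_sums / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return MarginalChiSquareResult(statistic=statistic, df=df, p=p)


# ---------------------------------------------------------------------------
# Paired-agreement extras (not part of the standard evaluation report)
# ---------------------------------------------------------------------------


def cohen_kappa(t3: CrossTable3) -> float:
    """Cohen's kappa for paired 3-way diagnoses (chance-corrected agreement)."""
    a = t3.array.astype(float)
    n = a.sum()
    po = np.trace(a) / n
    pe = float(np.array(t3.row_totals) @ np.array(t3.col_totals)) / n**2
    if pe == 1.0:
        return 1.0
    return float((po - pe) / (1.0 - pe))


def bowker_symmetry(t3: CrossTable3) -> MarginalChiSquareResult:
    """Bowker's test of symmetry for a paired 3x3 table (df = 3).

    Off-diagonal pairs with zero combined count contribute nothing and
    reduce the degrees of freedom.
    """
    a = t3.array.astype(float)
    statistic, df = 0.0, 0
    for i in range(3):
        for j in range(i + 1, 3):
            s = a[i, j] + a[j, i]
            if s > 0:
                statistic += (a[i, j] - a[j, i]) ** 2 / s
                df += 1
    p = float(stats.chi2.sf(statistic, df)) if df else 1.0
    return MarginalChiSquareResult(statistic=float(statistic), df=df, p=p)


def stuart_maxwell(t3: CrossTable3) -> MarginalChiSquareResult:
    """Stuart-Maxwell test of marginal homogeneity for a paired 3x3 table."""
    a = t3.array.astype(float)
    d = np.array(t3.row_totals, dtype=float) - np.array(t3.col_totals, dtype=float)
    d = d[:2]
    s = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            if i == j:
                s[i, j] = t3.row_totals[i] + t3.col_totals[i] - 2 * a[i, i]
            else:
                s[i, j] = -(a[i, j] + a[j, i])
    try:
        statistic = float(d @ np.linalg.solve(s, d))
    except np.linalg.LinAlgError:
        raise ZeroDivisionError("Stuart-Maxwell covariance matrix is singular") from None
    p = float(stats.chi2.sf(statistic, 2))
    return MarginalChiSquareResult(statistic=statistic, df=2, p=p)
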
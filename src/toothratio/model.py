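"""Study-level model and results objects tying the stages together.

:class:`AnteriorRatioStudy` wraps a cohort plus a :class:`PipelineConfig`;
``fit()`` runs the requested stages of the analysis —

    derive    stratify by anterior Bolton ratio, run the 18 pairwise
              tooth-width tests, select the key teeth
    associate correlate SATR with the Bolton ratio and fit the
              simple linear regression
    norm      establish an in-cohort SATR normative standard
    classify  diagnose every subject with both indices
    evaluate  cross-tabulate SATR against the Bolton gold standard and
              compute the diagnostic metrics and marginal chi-square

— and returns a :class:`StudyResults` carrying every intermediate table
plus a plain-text ``summary()``.  The run is deterministic given cohort,
config and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .association import LinearFit, as_fraction, ols_fit
from .config import PipelineConfig
from .derivation import (
    KeyTeethSelection,
    PairwiseTest,
    label_cohort_by_abr,
    pairwise_tooth_tests,
    select_key_teeth,
)
from .diagnostics import (
    CrossTable2,
    CrossTable3,
    DiagnosticMetrics,
    MarginalChiSquareResult,
    collapse_to_binary,
    cross_tabulate,
    diagnostic_metrics,
    marginal_chi_square,
    LABEL_NAMES3,
)
from .norms import DiagnosisLabel, NormStandard, classify, establish_standard
from .ratios import anterior_bolton_ratio, satr
from .teeth import Cohort, WidthError, cohort_summary, load_widths

__all__ = ["AnteriorRatioStudy", "StudyResults", "ALL_STAGES"]

logger = logging.getLogger("toothratio")

ALL_STAGES = ("derive", "associate", "norm", "classify", "evaluate")

_REQUIREMENT = {
    "derive": "bolton",
    "associate": "bolton",
    "norm": "bolton",
    "classify": "satr",
    "evaluate": "bolton",
}


@dataclass
class StudyResults:
    """Fitted study artefacts; every field is None until its stage has run."""

    config: PipelineConfig
    n_subjects: int
    stages: tuple[str, ...]
    per_subject: pd.DataFrame  # subject_id [, abr, satr, satr_diag, gold_diag]
    width_summary: "pd.DataFrame | None" = None
    pairwise_tests: "list[PairwiseTest] | None" = None
    key_teeth: "KeyTeethSelection | None" = None
    linear_fit: "LinearFit | None" = None
    established_standard: "NormStandard | None" = None
    crosstab3: "CrossTable3 | None" = None
    crosstab2: "CrossTable2 | None" = None
    metrics: "DiagnosticMetrics | None" = None
    chi_square: "MarginalChiSquareResult | None" = None

    def tests_frame(self) -> "pd.DataFrame | None":
        if self.pairwise_tests is None:
            return None
        return pd.DataFrame([t.__dict__ for t in self.pairwise_tests])

    def crosstab3_frame(self) -> "pd.DataFrame | None":
        if self.crosstab3 is None:
            return None
        df = pd.DataFrame(
            self.crosstab3.array,
            index=[f"satr_{l}" for l in LABEL_NAMES3],
            columns=[f"gold_{l}" for l in LABEL_NAMES3],
        )
        df["total"] = df.sum(axis=1)
        df.loc["total"] = df.sum(axis=0)
        return df

    def summary(self) -> str:
        """Plain-text report of every fitted stage."""
        lines = [
            "Anterior tooth-ratio study",
            "=" * 26,
            f"subjects: {self.n_subjects}   stages: {', '.join(self.stages)}",
            "",
        ]
        if self.width_summary is not None:
            lines += ["Bilateral-mean width summary (mm)",
                      self.width_summary.round(3).to_string(), ""]
        if self.pairwise_tests is not None:
            lines += ["Pairwise tooth-width t-tests",
                      self.tests_frame().round(4).to_string(index=False), ""]
        if self.key_teeth is not None:
            lines += [
                f"Key teeth (alpha={self.key_teeth.alpha:g}): "
                f"upper={self.key_teeth.upper_type or 'none'}, "
                f"lower={self.key_teeth.lower_type or 'none'}", "",
            ]
        if self.linear_fit is not None:
            f = self.linear_fit
            lines += [
                "SATR vs anterior Bolton ratio (fractions):",
                f"  r = {f.r:.3f} (p = {f.p:.3g}, n = {f.n})",
                f"  y = {f.intercept:.3f} + {f.slope:.3f} x", "",
            ]
        if self.established_standard is not None:
            lines += [f"Established standard -> {self.established_standard}", ""]
        if self.crosstab3 is not None:
            lines += ["SATR vs gold standard (3-class)",
                      self.crosstab3_frame().to_string(), ""]
        if self.metrics is not None:
            m = self.metrics.rounded(2)
            lines += [
                f"Diagnostics (positive = {m.positive_condition}): "
                f"Sen {m.sensitivity:.2f}%  Spe {m.specificity:.2f}%  "
                f"PPV {m.ppv:.2f}%  NPV {m.npv:.2f}%",
            ]
        if self.chi_square is not None:
            c = self.chi_square
            lines += [
                f"Marginal consistency: chi2 = {c.statistic:.2f}, "
                f"df = {c.df}, p = {c.p:.2f}",
            ]
        return "\n".join(lines).rstrip() + "\n"


class AnteriorRatioStudy:
    """The anterior-ratio analysis bound to one cohort and one config."""

    def __init__(self, cohort: Cohort, config: "PipelineConfig | None" = None):
        self.cohort = cohort
        self.config = config or PipelineConfig()

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, layout: str = "wide",
        config: "PipelineConfig | None" = None,
    ) -> "AnteriorRatioStudy":
        import io

        buf = io.StringIO(df.to_csv(index=False))
        return cls(load_widths(buf, layout=layout), config=config)

    @classmethod
    def from_csv(
        cls, path, layout: str = "wide", config: "PipelineConfig | None" = None
    ) -> "AnteriorRatioStudy":
        return cls(load_widths(path, layout=layout), config=config)

    # -- fitting ------------------------------------------------------------

    def _check_stage(self, stage: str, gold_labels) -> None:
        requirement = _REQUIREMENT[stage]
        if stage == "evaluate" and gold_labels is not None:
            requirement = "satr"
        incomplete = [
            rec.subject_id
            for rec in self.cohort.records
            if rec.missing(requirement)
        ]
        if incomplete:
            raise WidthError(
                f"stage {stage!r} requires {requirement}-complete records; "
                f"incomplete subjects: {incomplete[:5]}"
                + ("..." if len(incomplete) > 5 else "")
            )

    def fit(
        self,
        stages: "Iterable[str] | None" = None,
        gold_labels: "Mapping[str, DiagnosisLabel] | None" = None,
    ) -> StudyResults:
        """Run the requested stages (default: all) and collect the results.

        ``gold_labels`` optionally supplies external gold-standard
        diagnoses keyed by subject id, letting ``evaluate`` run on
        SATR-complete-only cohorts.
        """
        stages = tuple(stages) if stages is not None else ALL_STAGES
        if not stages:
            raise ValueError("no stages requested")
        unknown = sorted(set(stages) - set(ALL_STAGES))
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {ALL_STAGES}")
        stages = tuple(s for s in ALL_STAGES if s in stages)
        for stage in stages:
            self._check_stage(stage, gold_labels)

        cfg = self.config
        satr_std = cfg.effective_standard("satr")
        bolton_std = cfg.effective_standard("bolton")
        logger.info(
            "fit stages=%s alpha=%g variant=%s positive=%s rounding=%s "
            "satr_std=[%g,%g] bolton_bounds=[%g,%g]",
            stages, cfg.alpha, cfg.t_variant, cfg.positive_condition,
            cfg.rounding, satr_std.lower, satr_std.upper,
            cfg.bolton_bounds.low_upper, cfg.bolton_bounds.high_lower,
        )

        per = pd.DataFrame({"subject_id": [r.subject_id for r in self.cohort.records]})
        need_abr = any(s in stages for s in ("derive", "associate", "norm")) or (
            "evaluate" in stages and gold_labels is None
        )
        if need_abr:
            per["abr"] = [anterior_bolton_ratio(r).value for r in self.cohort.records]
        if any(s in stages for s in ("associate", "norm", "classify", "evaluate")):
            per["satr"] = [satr(r).value for r in self.cohort.records]

        results = StudyResults(
            config=cfg, n_subjects=len(self.cohort), stages=stages, per_subject=per
        )

        if "derive" in stages:
            labeled = (
                self.cohort
                if self.cohort.groups
                else label_cohort_by_abr(self.cohort, cfg.bolton_bounds)
            )
            results.width_summary = cohort_summary(labeled)
            results.pairwise_tests = pairwise_tooth_tests(labeled, cfg.t_variant)
            results.key_teeth = select_key_teeth(results.pairwise_tests, cfg.alpha)

        if "associate" in stages:
            results.linear_fit = ols_fit(
                as_fraction(per["satr"]), as_fraction(per["abr"])
            )

        if "norm" in stages:
            if cfg.norm_source == "normal_abr":
                mask = per["abr"].map(
                    lambda v: classify(v, bolton_std) == DiagnosisLabel.NORMAL
                )
                values = per.loc[mask, "satr"]
            else:
                values = per["satr"]
            results.established_standard = establish_standard(
                values.to_numpy(), k=satr_std.k, name="SATR (established)"
            )

        if "classify" in stages:
            per["satr_diag"] = [
                str(classify(v, satr_std)) for v in per["satr"]
            ]

        if "evaluate" in stages:
            if "satr_diag" not in per.columns:
                per["satr_diag"] = [str(classify(v, satr_std)) for v in per["satr"]]
            if gold_labels is not None:
                missing = [s for s in per["subject_id"] if s not in gold_labels]
                if missing:
                    raise WidthError(
                        f"stage 'evaluate': gold labels missing for {missing[:5]}"
                    )
                per["gold_diag"] = [
                    str(DiagnosisLabel.parse(gold_labels[s])) for s in per["subject_id"]
                ]
            else:
                per["gold_diag"] = [
                    str(classify(v, bolton_std)) for v in per["abr"]
                ]
            results.crosstab3 = cross_tabulate(
                per["satr_diag"].tolist(), per["gold_diag"].tolist()
            )
            results.crosstab2 = collapse_to_binary(results.crosstab3)
            results.metrics = diagnostic_metrics(
                results.crosstab2, cfg.positive_condition
            )
            results.chi_square = marginal_chi_square(results.crosstab3)

        results.per_subject = per
        return results
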
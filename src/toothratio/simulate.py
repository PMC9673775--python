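"""Synthetic tooth-width cohorts with the structure the analysis assumes.

Each subject's 12 anterior widths are drawn around per-tooth-type means with
three variance components: a shared per-subject size factor (real tooth
sizes covary within a mouth), an independent per-subject per-tooth-type
component, and left-right asymmetry noise.  The components are scaled so
the marginal SD of every tooth equals the configured per-type SD exactly.

Ratio abnormality is planted through deterministic lateral-incisor shifts,
the mechanism by which anterior-ratio deviation arises in practice:
scenario ``lateral_deficient`` enlarges the upper laterals and shrinks the
lower ones (driving both ratios down), ``lateral_excess`` mirrors it, and
``mixed`` draws a scenario per subject.  Because shifts are deterministic,
the planted ground truth is exact and power analyses are interpretable.

Default width means/SDs are the normal-ratio reference values (mm):
upper central 8.650/0.490, upper lateral 7.216/0.511, upper canine
8.007/0.522, lower central 5.654/0.418, lower lateral 6.172/0.350,
lower canine 6.961/0.531.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .teeth import (
    ANTERIOR_FDI_CODES,
    DEFAULT_WIDTH_WINDOW,
    AnteriorWidths,
    Cohort,
    ToothRef,
)
from .ratios import anterior_bolton_ratio, satr

__all__ = [
    "TABLE_NORMAL_WIDTHS",
    "SyntheticCohortParams",
    "SyntheticCohort",
    "generate_cohort",
    "generate_three_group_study",
]

#: (mean mm, SD mm) per (arch, tooth_type) for the normal-ratio reference group.
TABLE_NORMAL_WIDTHS: dict[tuple[str, str], tuple[float, float]] = {
    ("upper", "central"): (8.650, 0.490),
    ("upper", "lateral"): (7.216, 0.511),
    ("upper", "canine"): (8.007, 0.522),
    ("lower", "central"): (5.654, 0.418),
    ("lower", "lateral"): (6.172, 0.350),
    ("lower", "canine"): (6.961, 0.531),
}

SCENARIOS = ("balanced", "lateral_deficient", "lateral_excess", "mixed")

#: Scenario mix for ``mixed`` cohorts: share of ratio-deficient, balanced and
#: ratio-excess subjects, patterned on a screening-clinic case mix in which
#: roughly half of referred patients have a normal anterior ratio.
DEFAULT_MIXED_PROPORTIONS = (0.30, 0.53, 0.17)  # deficient, balanced, excess


@dataclass(frozen=True)
class SyntheticCohortParams:
    """Generator settings; defaults emulate the normal-ratio reference group."""

    tooth_params: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE_NORMAL_WIDTHS)
    )
    #: Fraction of each tooth-type variance carried by the shared size factor.
    size_factor_sd_share: float = 0.5
    #: Deterministic per-arch lateral-incisor shift (mm) for abnormal scenarios;
    #: ~0.7 within-type SD, a clinically evident size discrepancy.
    lateral_shift_mm: float = 0.35
    #: SD of independent left-right asymmetry noise (mm).
    asymmetry_sd_mm: float = 0.15
    scenario: str = "balanced"
    mixed_proportions: tuple[float, float, float] = DEFAULT_MIXED_PROPORTIONS
    n: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not 0.0 <= self.size_factor_sd_share <= 1.0:
            raise ValueError("size_factor_sd_share must lie in [0, 1]")
        if self.asymmetry_sd_mm < 0 or self.lateral_shift_mm < 0:
            raise ValueError("noise and shift parameters must be non-negative")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for key, (mu, sd) in self.tooth_params.items():
            if sd < 0:
                raise ValueError(f"negative SD for {key}")
            shifted_min = mu - (self.lateral_shift_mm if key[1] == "lateral" else 0.0)
            if shifted_min <= 0:
                raise ValueError(f"non-positive mean width for {key} after shift")
        if not math.isclose(sum(self.mixed_proportions), 1.0, abs_tol=1e-9):
            raise ValueError("mixed_proportions must sum to 1")

    def residual_sd(self, key: tuple[str, str]) -> float:
        """SD of the per-subject per-tooth-type component for one tooth type.

        Chosen so size-factor, per-type and asymmetry variances add up to
        the configured per-tooth SD squared.
        """
        sd = self.tooth_params[key][1]
        var = (1.0 - self.size_factor_sd_share) * sd**2 - self.asymmetry_sd_mm**2
        if var < -1e-12:
            raise ValueError(
                f"asymmetry_sd_mm={self.asymmetry_sd_mm} exceeds the "
                f"non-shared variance of {key} (sd {sd}); reduce asymmetry "
                "or size_factor_sd_share"
            )
        return math.sqrt(max(var, 0.0))


def _scenario_shifts(scenario: str, s: float) -> dict[tuple[str, str], float]:
    """Per-(arch, tooth_type) width shift planting the named ratio deviation."""
    if scenario == "balanced":
        return {}
    if scenario == "lateral_deficient":  # ratio pushed down
        return {("upper", "lateral"): +s, ("lower", "lateral"): -s}
    if scenario == "lateral_excess":  # ratio pushed up
        return {("upper", "lateral"): -s, ("lower", "lateral"): +s}
    raise ValueError(f"no deterministic shifts for scenario {scenario!r}")


@dataclass
class SyntheticCohort:
    """A generated cohort with its exact planted ground truth."""

    cohort: Cohort
    truth: pd.DataFrame  # subject_id, scenario, shifts, true_abr, true_satr
    n_clipped: int  # widths clipped into the plausibility window


def generate_cohort(params: SyntheticCohortParams, id_prefix: str = "S") -> SyntheticCohort:
    """Draw a cohort of ``params.n`` subjects; bit-reproducible from the seed."""
    rng = np.random.default_rng(params.seed)
    n = params.n

    if params.scenario == "mixed":
        scenario_names = ("lateral_deficient", "balanced", "lateral_excess")
        probs = (
            params.mixed_proportions[0],
            params.mixed_proportions[1],
            params.mixed_proportions[2],
        )
        subject_scen = rng.choice(scenario_names, size=n, p=probs)
    else:
        subject_scen = np.full(n, params.scenario, dtype=object)

    refs = [ToothRef(c) for c in ANTERIOR_FDI_CODES]
    keys = [(r.arch, r.tooth_type) for r in refs]
    mu = np.array([params.tooth_params[k][0] for k in keys])
    lam = np.array(
        [params.tooth_params[k][1] * math.sqrt(params.size_factor_sd_share) for k in keys]
    )
    res_sd = np.array([params.residual_sd(k) for k in keys])
    type_keys = list(TABLE_NORMAL_WIDTHS)  # 6 unique (arch, type) keys
    type_index = np.array([type_keys.index(k) for k in keys])  # tooth -> type col

    z = rng.standard_normal(n)  # shared size factor
    delta = rng.standard_normal((n, len(type_keys)))  # per-subject per-type
    eps = rng.standard_normal((n, len(refs))) * params.asymmetry_sd_mm

    shift = np.zeros((n, len(refs)))
    for scen in np.unique(subject_scen):
        mask = subject_scen == scen
        for j, k in enumerate(keys):
            shift[mask, j] += _scenario_shifts(str(scen), params.lateral_shift_mm).get(k, 0.0)

    res_sd_per_tooth = res_sd  # aligned with keys/refs
    widths = (
        mu[None, :]
        + lam[None, :] * z[:, None]
        + delta[:, type_index] * res_sd_per_tooth[None, :]
        + shift
        + eps
    )

    lo, hi = DEFAULT_WIDTH_WINDOW
    n_clipped = int(((widths < lo) | (widths > hi)).sum())
    if n_clipped:
        warnings.warn(
            f"{n_clipped} generated width(s) clipped into the plausibility "
            f"window [{lo}, {hi}] mm",
            stacklevel=2,
        )
        widths = np.clip(widths, lo, hi)

    digits = max(4, len(str(n)))
    records, truth_rows = [], []
    for i in range(n):
        sid = f"{id_prefix}{i + 1:0{digits}d}"
        rec = AnteriorWidths(
            subject_id=sid,
            widths={refs[j]: float(widths[i, j]) for j in range(len(refs))},
        )
        records.append(rec)
        scen = str(subject_scen[i])
        shifts = _scenario_shifts(scen, params.lateral_shift_mm)
        truth_rows.append(
            {
                "subject_id": sid,
                "scenario": scen,
                "upper_lateral_shift_mm": shifts.get(("upper", "lateral"), 0.0),
                "lower_lateral_shift_mm": shifts.get(("lower", "lateral"), 0.0),
                "true_abr": anterior_bolton_ratio(rec).value,
                "true_satr": satr(rec).value,
            }
        )
    return SyntheticCohort(
        cohort=Cohort(records=records),
        truth=pd.DataFrame(truth_rows),
        n_clipped=n_clipped,
    )


def expected_mean_abr(params: SyntheticCohortParams, scenario: str) -> float:
    """Ratio of planted mean width sums (percent) for a pure scenario."""
    shifts = _scenario_shifts(scenario, params.lateral_shift_mm)
    upper = sum(
        2 * (params.tooth_params[k][0] + shifts.get(k, 0.0))
        for k in params.tooth_params
        if k[0] == "upper"
    )
    lower = sum(
        2 * (params.tooth_params[k][0] + shifts.get(k, 0.0))
        for k in params.tooth_params
        if k[0] == "lower"
    )
    return 100.0 * lower / upper


def generate_three_group_study(
    params: SyntheticCohortParams = SyntheticCohortParams(),
    group_sizes: tuple[int, int, int] = (80, 80, 80),
    seed: "int | None" = None,
    bounds: tuple[float, float] = (77.08, 80.52),
) -> SyntheticCohort:
    """Low/normal/high ratio groups for the key-tooth derivation design.

    The normal group is balanced; the low group plants ``lateral_deficient``
    shifts (larger upper, smaller lower laterals) and the high group the
    mirror image — the pattern observed between extreme ratio groups.
    Group labels are attached to the cohort.  If the planted shifts do not
    move the group mean ratios past the stratification bounds, a warning is
    emitted (the construction still proceeds).
    """
    n_low, n_normal, n_high = group_sizes
    if min(group_sizes) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if seed is not None:
        params = replace(params, seed=seed)

    if expected_mean_abr(params, "lateral_deficient") >= bounds[0]:
        warnings.warn(
            "lateral_shift_mm too small: planted low-group mean ratio is not "
            f"below {bounds[0]}%",
            stacklevel=2,
        )
    if expected_mean_abr(params, "lateral_excess") <= bounds[1]:
        warnings.warn(
            "lateral_shift_mm too small: planted high-group mean ratio is not "
            f"above {bounds[1]}%",
            stacklevel=2,
        )

    rng = np.random.default_rng(params.seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=3)
    pieces = []
    for (group, scen, size), sub_seed in zip(
        (
            ("low", "lateral_deficient", n_low),
            ("normal", "balanced", n_normal),
            ("high", "lateral_excess", n_high),
        ),
        sub_seeds,
    ):
        piece = generate_cohort(
            replace(params, scenario=scen, n=size, seed=int(sub_seed)),
            id_prefix=f"{group[0].upper()}",
        )
        piece.truth["group"] = group
        pieces.append(piece)

    records = [rec for p in pieces for rec in p.cohort.records]
    groups = {
        row["subject_id"]: row["group"]
        for p in pieces
        for row in p.truth.to_dict("records")
    }
    truth = pd.concat([p.truth for p in pieces], ignore_index=True)
    return SyntheticCohort(
        cohort=Cohort(records=records, groups=groups),
        truth=truth,
        n_clipped=sum(p.n_clipped for p in pieces),
    )
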
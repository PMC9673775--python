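import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from toothratio import (
    BoltonGroupBounds,
    PairwiseTest,
    SyntheticCohortParams,
    assign_bolton_group,
    generate_three_group_study,
    pairwise_tooth_tests,
    select_key_teeth,
    t_test,
)
from toothratio.derivation import COMPARISONS, levene_mean_center
from toothratio.teeth import TOOTH_TYPE_ORDER


class TestAssignBoltonGroup:
    @pytest.mark.parametrize(
        "abr, expected",
        [
            (76.00, "low"),
            (78.80, "normal"),
            (81.00, "high"),
            (77.08, "normal"),  # boundaries belong to normal
            (80.52, "normal"),
            (77.079, "low"),
            (80.521, "high"),
        ],
    )
    def test_stratification(self, abr, expected):
        assert assign_bolton_group(abr) == expected

    def test_partition_and_monotone(self):
        order = {"low": 0, "normal": 1, "high": 2}
        values = np.linspace(60, 100, 801)
        labels = [order[assign_bolton_group(v)] for v in values]
        assert labels == sorted(labels)  # monotone in the ratio
        assert set(labels) == {0, 1, 2}

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            BoltonGroupBounds(low_upper=81.0, high_lower=77.0)


class TestTTest:
    def test_identical_samples(self):
        res = t_test([5.0, 6.0, 7.0], [5.0, 6.0, 7.0], "pooled")
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_pooled(self):
        # means 2 and 3, pooled var 1, se = sqrt(2/3): t = -1/sqrt(2/3)
        res = t_test([1, 2, 3], [2, 3, 4], "pooled")
        assert res.t == pytest.approx(-math.sqrt(1.5), abs=1e-4)
        assert res.t == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == 4

    def test_constant_equal_samples_define_t_zero(self):
        res = t_test([4.0, 4.0], [4.0, 4.0])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_constant_unequal_samples_undefined(self):
        with pytest.raises(ZeroDivisionError):
            t_test([4.0, 4.0], [5.0, 5.0])

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 9), rng.normal(0.4, 1.3, 7)
        for variant in ("pooled", "welch"):
            ab, ba = t_test(a, b, variant), t_test(b, a, variant)
            assert ab.t == pytest.approx(-ba.t, rel=1e-12)
            assert ab.p == pytest.approx(ba.p, rel=1e-12)

    @pytest.mark.parametrize("variant, equal_var", [("pooled", True), ("welch", False)])
    def test_matches_scipy_oracle(self, variant, equal_var):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n1, n2 = rng.integers(2, 12, size=2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), n1)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), n2)
            mine = t_test(a, b, variant)
            ref = stats.ttest_ind(a, b, equal_var=equal_var)
            assert mine.t == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_levene_gate_matches_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = rng.normal(0, rng.uniform(0.5, 3), rng.integers(4, 15))
            b = rng.normal(0, rng.uniform(0.5, 3), rng.integers(4, 15))
            mine = levene_mean_center(a, b)
            ref = stats.levene(a, b, center="mean").pvalue
            assert mine == pytest.approx(ref, abs=1e-10)


def _make_tests(p_by_type):
    """Build an 18-row test list with fixed p-values per (arch, type)."""
    rows = []
    for arch, ttype in TOOTH_TYPE_ORDER:
        for i, comp in enumerate(COMPARISONS):
            ps = p_by_type[(arch, ttype)]
            p = ps[i] if isinstance(ps, (list, tuple)) else ps
            rows.append(PairwiseTest(arch, ttype, comp, t=1.0, df=10.0, p=p, variant="pooled"))
    return rows


class TestSelectKeyTeeth:
    def test_published_significance_pattern_selects_laterals(self):
        # p-values copied from the printed 18-comparison table
        pattern = {
            ("upper", "central"): (0.082, 0.076, 0.002),
            ("upper", "lateral"): (0.016, 0.009, 0.000),
            ("upper", "canine"): (0.167, 0.268, 0.024),
            ("lower", "central"): (0.000, 0.559, 0.000),
            ("lower", "lateral"): (0.003, 0.025, 0.000),
            ("lower", "canine"): (0.508, 0.376, 0.098),
        }
        sel = select_key_teeth(_make_tests(pattern))
        assert sel.upper_type == "lateral"
        assert sel.lower_type == "lateral"

    def test_no_type_qualifies(self):
        sel = select_key_teeth(_make_tests({k: 0.5 for k in TOOTH_TYPE_ORDER}))
        assert sel.upper_type is None and sel.lower_type is None

    def test_ambiguity_is_surfaced(self):
        pattern = {k: 0.5 for k in TOOTH_TYPE_ORDER}
        pattern[("upper", "central")] = 0.01
        pattern[("upper", "lateral")] = 0.01
        with pytest.raises(ValueError, match="ambiguous"):
            select_key_teeth(_make_tests(pattern))

    def test_incomplete_test_set_rejected(self):
        rows = _make_tests({k: 0.5 for k in TOOTH_TYPE_ORDER})[:-1]
        with pytest.raises(ValueError, match="missing"):
            select_key_teeth(rows)


class TestPairwiseToothTests:
    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_identical_groups_give_zero_t(self):
        sim = generate_three_group_study(
            replace(SyntheticCohortParams(),
                    tooth_params={k: (m, 0.0) for k, (m, _) in
                                  SyntheticCohortParams().tooth_params.items()},
                    lateral_shift_mm=0.0, asymmetry_sd_mm=0.0,
                    size_factor_sd_share=0.0),
            group_sizes=(3, 3, 3), seed=0,
        )
        tests = pairwise_tooth_tests(sim.cohort)
        assert all(t.t == 0.0 and t.p == 1.0 for t in tests)

    def test_lateral_shifts_make_lateral_rows_significant(self):
        sim = generate_three_group_study(group_sizes=(80, 80, 80), seed=3)
        tests = pairwise_tooth_tests(sim.cohort)
        assert len(tests) == 18
        lateral_ps = [t.p for t in tests if t.tooth_type == "lateral"]
        assert all(p < 0.05 for p in lateral_ps)
        sel = select_key_teeth(tests)
        assert (sel.upper_type, sel.lower_type) == ("lateral", "lateral")

    def test_small_group_rejected(self):
        sim = generate_three_group_study(group_sizes=(2, 5, 5), seed=0)
        groups = dict(sim.cohort.groups)
        # drop one low-group subject below the minimum
        low_id = next(s for s, g in groups.items() if g == "low")
        cohort = type(sim.cohort)(
            records=[r for r in sim.cohort.records if r.subject_id != low_id],
            groups={s: g for s, g in groups.items() if s != low_id},
        )
        with pytest.raises(Exception, match="low"):
            pairwise_tooth_tests(cohort)

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_null_rejection_rate_close_to_alpha(self):
        rej = tot = 0
        params = replace(SyntheticCohortParams(), lateral_shift_mm=0.0)
        for seed in range(120):
            sim = generate_three_group_study(params, group_sizes=(30, 30, 30), seed=seed)
            tests = pairwise_tooth_tests(sim.cohort)
            rej += sum(t.p < 0.05 for t in tests)
            tot += len(tests)
        assert 0.02 < rej / tot < 0.09
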
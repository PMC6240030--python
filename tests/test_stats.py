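"""Statistical battery: exact oracles, invariances, and study structure."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

import csdscope as cs
from csdscope.exceptions import DegenerateDataError
from csdscope.recording import GROUPS, SubjectMeta
from csdscope.stats import SubjectSummary


def brute_force_u(a, b):
    """Larger-U convention by direct pair counting (midranks for ties)."""
    u_ab = sum(0.5 if x == y else float(x > y) for x in a for y in b)
    return max(u_ab, len(a) * len(b) - u_ab)


def enumeration_p(a, b):
    """Exact two-sided p by enumerating all rank assignments."""
    pooled = np.r_[a, b]
    n1, n = len(a), len(pooled)
    ranks = rankdata(pooled)
    u_obs = min(ranks[:n1].sum() - n1 * (n1 + 1) / 2,
                n1 * (n - n1) - (ranks[:n1].sum() - n1 * (n1 + 1) / 2))
    cnt = tot = 0
    for comb in itertools.combinations(range(n), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        u = min(u, n1 * (n - n1) - u)
        tot += 1
        cnt += u <= u_obs + 1e-9
    return cnt / tot


class TestMannWhitney:
    @pytest.mark.parametrize("n1,n2,expect", [(8, 9, 72.0), (7, 9, 63.0),
                                              (6, 9, 54.0)])
    def test_complete_separation_u(self, n1, n2, expect):
        low = list(range(n1))
        high = [100 + i for i in range(n2)]
        res = cs.mann_whitney_u(low, high)
        assert res.statistic == expect == n1 * n2

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(1, 7, size=2)
            a, b = rng.normal(size=n1), rng.normal(size=n2)
            assert cs.mann_whitney_u(a, b).statistic == \
                pytest.approx(brute_force_u(a, b))

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            n1, n2 = rng.integers(2, 7, size=2)
            a, b = rng.normal(size=n1), rng.normal(size=n2)
            assert cs.mann_whitney_u(a, b).p_value == \
                pytest.approx(enumeration_p(a, b), abs=1e-9)

    def test_identical_samples_p_one(self):
        res = cs.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_small_example(self):
        assert cs.mann_whitney_u([1, 2], [3]).statistic == 2.0

    def test_empty_sample_rejected(self):
        with pytest.raises(DegenerateDataError):
            cs.mann_whitney_u([], [1.0])

    @given(st.lists(st.integers(-50, 50), min_size=1, max_size=8),
           st.lists(st.integers(-50, 50), min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_u_complement_property(self, a, b):
        # U(a,b) + U(b,a) = n1*n2 with midranks, so the larger-U convention
        # is symmetric in its arguments
        ua = cs.mann_whitney_u(a, b)
        ub = cs.mann_whitney_u(b, a)
        assert ua.statistic == ub.statistic
        assert ua.statistic >= len(a) * len(b) / 2
        assert ua.p_value == pytest.approx(ub.p_value, abs=1e-12)

    @given(st.lists(st.integers(-1000, 1000), min_size=2, max_size=8,
                    unique=True),
           st.lists(st.integers(-1000, 1000), min_size=2, max_size=8,
                    unique=True))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rank_invariance_under_monotone_transform(self, a, b):
        f = lambda v: [math.exp(x / 500.0) for x in v]
        r0 = cs.mann_whitney_u(a, b)
        r1 = cs.mann_whitney_u(f(a), f(b))
        assert r0.statistic == r1.statistic
        assert r0.p_value == pytest.approx(r1.p_value, abs=1e-12)


class TestKruskalWallis:
    def test_df_is_groups_minus_one(self):
        g4 = [np.random.default_rng(i).normal(size=8) for i in range(4)]
        assert cs.kruskal_wallis(g4).df == 3
        g5 = g4 + [np.random.default_rng(9).normal(size=8)]
        assert cs.kruskal_wallis(g5).df == 4

    def test_all_identical_gives_h_zero(self):
        res = cs.kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_two_group_case_monotone_with_mann_whitney(self):
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(100):
            a, b = rng.normal(size=8), rng.normal(size=9)
            h = cs.kruskal_wallis([a, b]).statistic
            u = cs.mann_whitney_u(a, b).statistic
            rows.append((u, h))
        rows.sort()
        hs = [h for _, h in rows]
        # larger separation (larger U) never decreases H
        assert all(h2 >= h1 - 1e-9 for h1, h2 in zip(hs, hs[1:]))


class TestDunn:
    def test_pair_count(self):
        groups = [np.arange(5) + i for i in range(4)]
        assert len(cs.dunn_bonferroni(groups)) == 6

    def test_identical_groups_p_one(self):
        g = [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]]
        res = cs.dunn_bonferroni(g)
        first = [r for r in res if r.comparison == "group0 vs group1"][0]
        assert first.p_value == 1.0

    def test_z_matches_direct_rank_arithmetic(self):
        g = [[1.0, 2.0, 3.0], [2.5, 3.5, 4.0], [5.0, 6.0, 7.0]]
        res = cs.dunn_bonferroni(g)
        pooled = np.concatenate(g)
        ranks = rankdata(pooled)
        mr = [ranks[i * 3:(i + 1) * 3].mean() for i in range(3)]
        var_unit = 9 * 10 / 12.0
        z01 = (mr[0] - mr[1]) / math.sqrt(var_unit * (2 / 3))
        assert res[0].statistic == pytest.approx(z01)

    def test_bonferroni_bounds(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=6) for _ in range(4)]
        for r in cs.dunn_bonferroni(groups):
            raw = 2 * (1 - 0.5 * (1 + math.erf(abs(r.statistic) / math.sqrt(2))))
            assert r.p_value >= raw - 1e-12
            assert r.p_value <= 1.0

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            cs.dunn_bonferroni([[1.0, 2.0]])


class TestRegression:
    def test_perfect_fit(self):
        x = np.arange(5.0)
        res = cs.linear_regression_t(x, 2 * x + 1)
        assert math.isinf(res.statistic)
        assert res.p_value == 0.0

    def test_t_equals_pearson_identity(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        r = np.corrcoef(x, y)[0, 1]
        expect = r * math.sqrt(28) / math.sqrt(1 - r ** 2)
        res = cs.linear_regression_t(x, y)
        assert res.statistic == pytest.approx(expect)
        assert res.df == 28

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateDataError):
            cs.linear_regression_t([1.0] * 5, np.arange(5.0))


class TestPairedT:
    def test_df_convention(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=33)
        res = cs.paired_t(a, a + rng.normal(size=33))
        assert res.df == 32

    def test_constant_shift_flags_infinite_t(self):
        res = cs.paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert math.isinf(res.statistic) and res.statistic > 0
        assert res.p_value == 0.0

    def test_identical_pairs_degenerate(self):
        with pytest.raises(DegenerateDataError):
            cs.paired_t([1.0, 2.0], [1.0, 2.0])


def synthetic_cohort(rng, n_per_cell=5, pm_reduction=True):
    cohort = []
    k = 0
    for genotype in ("WT", "G301R"):
        for group in GROUPS:
            for j in range(n_per_cell):
                base = 6.0 if genotype == "WT" else 12.0
                if genotype == "G301R" and group == "PM_female" and pm_reduction:
                    base = 8.0
                freq = base + rng.normal(0, 0.5)
                onset = None if (genotype == "WT" and j % 2 == 0) \
                    else 900.0 + 200.0 * rng.normal()
                cohort.append(SubjectSummary(
                    meta=SubjectMeta(f"s{k}", genotype, group),
                    csd_frequency_per_hr=freq,
                    propagation_speed_mm_per_min=(3.5 if genotype == "WT"
                                                  else 5.0) + 0.2 * rng.normal(),
                    epi_onset_s=onset,
                    epi_class="none" if onset is None else "bouts",
                    severity=1.0 + rng.random(),
                    xcorr_coeffs={"A|B": 0.9 + 0.02 * rng.normal(),
                                  "A|C": 0.85 + 0.02 * rng.normal(),
                                  "B|C": 0.8 + 0.02 * rng.normal()},
                    xcorr_lags={"A|B": 0.01, "A|C": 0.03 + 0.003 * rng.normal(),
                                "B|C": 0.02 + 0.003 * rng.normal()}))
                k += 1
    return cohort


class TestRunStudy:
    def test_full_battery_structure(self):
        rng = np.random.default_rng(7)
        report = cs.run_study(synthetic_cohort(rng))
        tests = report["tests"]
        assert len(tests["csd_frequency_wt_vs_mut"]) == 4
        assert len(tests["propagation_speed_wt_vs_mut"]) == 4
        # onset family: pooled WT + 4 mutant cells -> 5 groups, 10 Dunn pairs
        onset = tests["epi_onset_groups"]
        assert onset["kruskal_wallis"].df == 4
        if onset["kruskal_wallis"].significant:
            assert len(onset["dunn"]) == 10
        assert set(tests["regressions_g301r"]) <= {
            "severity_vs_frequency", "onset_vs_frequency", "severity_vs_onset"}
        assert len(tests["xcorr_paired"]["max_coeff"]) == 3
        assert len(tests["xcorr_paired"]["abs_lag"]) == 3

    def test_empty_cells_skipped_with_reason(self):
        rng = np.random.default_rng(8)
        cohort = [s for s in synthetic_cohort(rng)
                  if not (s.meta.genotype == "G301R"
                          and s.meta.group == "female")]
        report = cs.run_study(cohort)
        assert any("female" in s for s in report["skipped"])

    def test_onset_exclusions_counted(self):
        rng = np.random.default_rng(9)
        report = cs.run_study(synthetic_cohort(rng))
        assert report["n_without_epileptiform_onset"] > 0

    def test_report_frame_tidy(self):
        rng = np.random.default_rng(10)
        frame = cs.stats.report_to_frame(cs.run_study(synthetic_cohort(rng)))
        assert {"section", "test", "statistic", "p_value"} <= set(frame.columns)
        assert (frame["p_value"].dropna() <= 1.0).all()
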
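import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from qfib.parameters import parameter_schema
from qfib.published import VALIDATION_PVALUES
from qfib.stats import (
    CohortTable,
    ComparisonResult,
    PanelSpec,
    build_panel,
    compare_groups,
    screen_and_validate,
    wilcoxon_rank_sum,
)


def brute_force_p(x, y):
    """Independent oracle: enumerate every label assignment of the pool."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, nx = len(pooled), len(x)
    w_obs = ranks[:nx].sum()
    lo = hi = 0
    total = 0
    for comb in itertools.combinations(range(n), nx):
        w = ranks[list(comb)].sum()
        total += 1
        if w <= w_obs + 1e-9:
            lo += 1
        if w >= w_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


class TestWilcoxon:
    def test_separated_triples_exact(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
        assert w == 6.0
        assert p == pytest.approx(0.100)  # 2 of the 20 assignments as extreme

    def test_identical_multisets_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 2, 5], [1, 2, 2, 5])
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_symmetry_in_sample_order(self, rng):
        x, y = rng.normal(size=7), rng.normal(size=5)
        for mode in ("exact", "approx"):
            _, pxy = wilcoxon_rank_sum(x, y, mode=mode)
            _, pyx = wilcoxon_rank_sum(y, x, mode=mode)
            assert pxy == pytest.approx(pyx)

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(size=9), rng.normal(size=9)
        _, p1 = wilcoxon_rank_sum(x, y)
        _, p2 = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_exact_matches_brute_force_small_samples(self, data):
        """Exact-mode p equals full enumeration for pooled n <= 10."""
        nx = data.draw(st.integers(1, 8))
        ny = data.draw(st.integers(1, min(8, 10 - nx)))
        pool = data.draw(
            st.lists(st.integers(0, 10**6), min_size=nx + ny, max_size=nx + ny,
                     unique=True)
        )
        x, y = np.array(pool[:nx], float), np.array(pool[nx:], float)
        _, p = wilcoxon_rank_sum(x, y, mode="exact")
        assert p == pytest.approx(brute_force_p(x, y), abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.data())
    def test_exact_with_ties_matches_brute_force(self, data):
        nx = data.draw(st.integers(2, 5))
        ny = data.draw(st.integers(2, 5))
        pool = data.draw(
            st.lists(st.integers(0, 3), min_size=nx + ny, max_size=nx + ny)
        )
        x, y = np.array(pool[:nx], float), np.array(pool[nx:], float)
        _, p = wilcoxon_rank_sum(x, y, mode="exact")
        assert p == pytest.approx(brute_force_p(x, y), abs=1e-12)

    def test_exact_and_approx_agree_at_moderate_n(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=8), rng.normal(size=8)
            _, pe = wilcoxon_rank_sum(x, y, mode="exact")
            _, pa = wilcoxon_rank_sum(x, y, mode="approx")
            assert abs(pe - pa) <= 0.02

    def test_approx_matches_reference_implementation(self, rng):
        """Normal-approximation path against scipy's Mann-Whitney U."""
        for _ in range(20):
            x = rng.poisson(8, size=20).astype(float)
            y = rng.poisson(10, size=25).astype(float)
            _, p = wilcoxon_rank_sum(x, y, mode="approx")
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic").pvalue
            assert p == pytest.approx(ref, rel=1e-9)

    def test_auto_switches_to_exact_when_small_and_tiefree(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        _, p_auto = wilcoxon_rank_sum(x, y, mode="auto")
        _, p_exact = wilcoxon_rank_sum(x, y, mode="exact")
        assert p_auto == p_exact == pytest.approx(0.100)


def _cohort(rng, n_a=10, n_b=10, shift=0.0):
    schema = parameter_schema()
    rows = {}
    groups = {}
    for i in range(n_a):
        rows[f"a{i}"] = dict(zip(schema, rng.normal(size=56)))
        groups[f"a{i}"] = "A"
    for i in range(n_b):
        rows[f"b{i}"] = dict(zip(schema, rng.normal(size=56) + shift))
        groups[f"b{i}"] = "B"
    return CohortTable(values=pd.DataFrame.from_dict(rows, orient="index"),
                       group=pd.Series(groups))


class TestCompareGroups:
    def test_results_cover_schema_in_order(self, rng):
        res = compare_groups(_cohort(rng), "A", "B")
        assert [r.parameter for r in res] == parameter_schema()
        for r in res:
            assert 0.0 <= r.p_value <= 1.0
            assert r.significant == (r.p_value < r.alpha)

    def test_missing_group_rejected(self, rng):
        with pytest.raises(ValueError, match="not present"):
            compare_groups(_cohort(rng), "A", "C")

    def test_large_shift_all_significant(self, rng):
        res = compare_groups(_cohort(rng, shift=10.0), "A", "B")
        assert all(r.significant for r in res)

    def test_bh_flag_is_more_conservative(self, rng):
        cohort = _cohort(rng, shift=0.6)
        raw = compare_groups(cohort, "A", "B")
        bh = compare_groups(cohort, "A", "B", bh=True)
        assert sum(r.significant for r in bh) <= sum(r.significant for r in raw)
        for r in bh:
            assert r.p_adjusted is not None and r.p_adjusted >= r.p_value - 1e-12

    def test_parameter_subset(self, rng):
        res = compare_groups(_cohort(rng), "A", "B",
                             parameters=["#StrPS", "%Periportal"])
        assert [r.parameter for r in res] == ["%Periportal", "#StrRPS"]


class TestPanel:
    def _results(self, pvalues):
        return [
            ComparisonResult(name, 0.0, p, p < 0.05)
            for name, p in pvalues.items()
        ]

    def test_published_validation_panel_has_26(self):
        """Applying p < 0.05 to the published validation column keeps 26 of 28."""
        results = self._results(VALIDATION_PVALUES)
        panel = build_panel(results, list(VALIDATION_PVALUES))
        assert len(panel.candidate_names) == 28
        assert len(panel.retained_names) == 26
        excluded = set(panel.candidate_names) - set(panel.retained_names)
        assert excluded == {"#ThinStrPeriportal", "#ThinStrPeriportalDis"}

    def test_boundary_p_is_not_significant(self):
        results = [ComparisonResult("%Periportal", 0.0, 0.05, False)]
        panel = build_panel(results, ["%Periportal"])
        assert panel.retained_names == []

    def test_all_p_one_empty_panel(self):
        results = self._results({n: 1.0 for n in parameter_schema()})
        assert build_panel(results, parameter_schema()).retained_names == []

    def test_all_p_small_keeps_everything(self):
        results = self._results({n: 0.001 for n in parameter_schema()})
        panel = build_panel(results, parameter_schema())
        assert panel.retained_names == parameter_schema()

    def test_candidate_without_result_rejected(self):
        with pytest.raises(ValueError, match="no comparison result"):
            build_panel([], ["%Periportal"])

    def test_retained_not_subset_rejected(self):
        with pytest.raises(ValueError):
            PanelSpec(candidate_names=["%Periportal"], retained_names=["%RPS"])


class TestScreenAndValidate:
    def test_stage2_candidates_are_stage1_significant(self, rng):
        disc = _cohort(rng, shift=1.5)
        true = _cohort(rng, shift=1.5)
        screen, validation, panel = screen_and_validate(disc, true)
        stage1_sig = [r.parameter for r in screen if r.significant]
        assert [r.parameter for r in validation] == stage1_sig
        assert panel.candidate_names == stage1_sig
        assert set(panel.retained_names) == {
            r.parameter for r in validation if r.significant
        }

    def test_no_stage1_hits_empty_panel(self, rng):
        # identical groups: with 56 null tests a few false positives can
        # appear, so force emptiness with alpha = 0
        disc = _cohort(rng)
        true = _cohort(rng)
        screen, validation, panel = screen_and_validate(disc, true, alpha=0.0)
        assert validation == [] and panel.retained_names == []
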
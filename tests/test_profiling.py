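"""Test battery: exact paths vs enumeration oracles, effect sizes, FDR, GLM."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snfcc import (
    CohortSpec,
    compare_categorical,
    compare_numeric,
    fdr_adjust,
    generate_cohort,
    permutation_glm,
    profile_clusters,
    trend_test,
)


def mann_whitney_exact_oracle(x, y):
    """Two-sided exact p by enumerating every rank split (no ties assumed)."""
    ranks = stats.rankdata(np.concatenate([x, y]))
    n1, n2 = len(x), len(y)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array(
        [ranks[list(c)].sum() - n1 * (n1 + 1) / 2
         for c in combinations(range(n1 + n2), n1)]
    )
    u_lo = min(u_obs, n1 * n2 - u_obs)
    p = ((us <= u_lo).sum() + (us >= n1 * n2 - u_lo).sum()) / len(us)
    return min(p, 1.0)


class TestCompareNumeric:
    def test_fully_separated_small_groups(self):
        res = compare_numeric(
            [1, 2, 3, 4, 5, 6], [1, 1, 1, 2, 2, 2], gate="nonparametric"
        )
        assert res.test == "mann_whitney_exact"
        assert res.statistic == 0  # U1: group 1 never exceeds group 2
        assert res.p_raw == pytest.approx(0.1)
        assert res.effect_size == pytest.approx(1.0)

    def test_exact_p_matches_enumeration_for_small_groups(self):
        rng = np.random.default_rng(0)
        for n1, n2 in [(3, 4), (5, 5), (7, 6)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2) + rng.normal()
            res = compare_numeric(
                np.concatenate([x, y]), [1] * n1 + [2] * n2, gate="nonparametric"
            )
            assert res.p_raw == pytest.approx(mann_whitney_exact_oracle(x, y))

    def test_three_identical_groups_are_null(self):
        res = compare_numeric([5.0] * 9, [1, 1, 1, 2, 2, 2, 3, 3, 3])
        assert res.p_raw == 1.0 and res.effect_size == 0.0

    def test_kruskal_effect_size_is_h_over_n_minus_one(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(c, 1, 15) for c in (0, 1, 2)])
        labels = np.repeat([1, 2, 3], 15)
        res = compare_numeric(vals, labels, gate="nonparametric")
        H = stats.kruskal(*[vals[labels == g] for g in (1, 2, 3)]).statistic
        assert res.test == "kruskal_wallis"
        assert res.effect_size == pytest.approx(H / (len(vals) - 1))

    def test_normal_groups_take_parametric_path_with_cohens_f(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(0, 1, 40), rng.normal(1, 1, 40)])
        labels = np.repeat([1, 2], 40)
        res = compare_numeric(vals, labels)
        if res.test == "one_way_linear_model":  # gate decides on the draw
            assert res.effect_family == "cohens_f" and res.effect_size > 0

    def test_tiny_group_raises(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_numeric([1, 2, 3], [1, 1, 2])

    def test_group_summaries_report_median_and_iqr(self):
        res = compare_numeric([1, 2, 3, 10, 20, 30], [1, 1, 1, 2, 2, 2],
                              gate="nonparametric")
        assert res.group_summaries[1]["median"] == 2
        assert res.group_summaries[2]["iqr"] == 10


class TestCompareCategorical:
    def test_fisher_2x2_diagonal_table(self):
        res = compare_categorical([[2, 0], [0, 2]])
        assert res.test == "fisher_exact"
        assert res.p_raw == pytest.approx(1 / 3)

    def test_proportional_table_has_zero_association(self):
        res = compare_categorical([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0)
        assert res.effect_size == pytest.approx(0.0)

    def test_balanced_table_takes_chi_squared_branch(self):
        res = compare_categorical([[10, 10], [10, 10]])
        assert res.test == "chi_squared"
        assert res.p_raw == pytest.approx(1.0)

    def test_empty_row_raises(self):
        with pytest.raises(ValueError, match="empty"):
            compare_categorical([[0, 0], [1, 2]])

    def test_rxc_enumeration_matches_permutation_oracle(self):
        table = np.array([[3, 1, 1], [1, 2, 2]])
        res = compare_categorical(table)
        assert res.test == "fisher_exact_rxc"

        # oracle: exhaustive permutation of column labels over all subjects
        rows = np.repeat([0, 1], table.sum(axis=1))
        cols = np.repeat([0, 1, 2], table.sum(axis=0))
        log_fact = np.concatenate(
            [[0.0], np.cumsum(np.log(np.arange(1, table.sum() + 1)))]
        )

        def lp(t):
            return (
                log_fact[t.sum(axis=1)].sum() + log_fact[t.sum(axis=0)].sum()
                - log_fact[t.sum()] - log_fact[t].sum()
            )

        obs = lp(table)
        seen = {}
        from itertools import permutations

        for perm in set(permutations(cols.tolist())):
            t = np.zeros((2, 3), dtype=np.int64)
            np.add.at(t, (rows, np.array(perm)), 1)
            key = tuple(t.ravel())
            seen.setdefault(key, [lp(t), 0])
            seen[key][1] += 1
        total = sum(c for _, c in seen.values())
        p_oracle = sum(c for l, c in seen.values() if l <= obs + 1e-7) / total
        assert res.p_raw == pytest.approx(p_oracle, rel=1e-9)

    def test_monte_carlo_fallback_reports_its_error(self):
        table = np.array([[4, 3, 2, 1], [1, 2, 3, 4], [2, 2, 2, 2]])
        res = compare_categorical(table, max_enumerate=10, seed=0)
        assert res.test == "fisher_exact_mc"
        assert "monte_carlo_se" in res.note
        assert 0 < res.p_raw <= 1


class TestTrendTest:
    def test_identical_level_distributions_are_null(self):
        vals = [0, 1, 2, 0, 1, 2, 0, 1, 2, 0, 1, 2]
        labels = [1] * 6 + [2] * 6
        res = trend_test(vals, labels, n_perm=999, seed=0)
        assert res.p_raw >= 0.95

    def test_perfectly_ordered_groups_reach_minimum_attainable_p(self):
        res = trend_test([0] * 10 + [2] * 10, [1] * 10 + [2] * 10,
                         n_perm=999, seed=1)
        assert res.p_raw >= 1 / 1000  # attainable minimum
        assert res.p_raw <= 0.01

    def test_single_level_variable_is_flagged_null(self):
        res = trend_test([1] * 10, [1] * 5 + [2] * 5, n_perm=199, seed=2)
        assert res.p_raw == 1.0 and res.statistic == 0.0
        assert "degenerate" in res.note

    def test_permutation_p_matches_exhaustive_enumeration(self):
        vals = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 2, 2, 0])
        labels = np.array([1] * 6 + [2] * 6)
        res = trend_test(vals, labels, n_perm=20_000, seed=3)

        from snfcc.profiling import _trend_statistic

        uniq = np.unique(labels)
        obs = _trend_statistic(vals.astype(float), labels, uniq)
        hits = total = 0
        for idx in combinations(range(12), 6):
            perm = np.full(12, 2)
            perm[list(idx)] = 1
            total += 1
            hits += _trend_statistic(vals.astype(float), perm, uniq) >= obs - 1e-12
        exact = hits / total
        se = np.sqrt(exact * (1 - exact) / 20_000)
        assert res.p_raw == pytest.approx(exact, abs=4 * se + 1e-3)

    def test_three_group_statistic_is_max_contrast(self):
        vals = [0] * 5 + [1] * 5 + [2] * 5
        labels = [1] * 5 + [2] * 5 + [3] * 5
        res = trend_test(vals, labels, n_perm=499, seed=4)
        assert res.statistic > 0
        assert res.p_raw < 0.05


class TestFDR:
    def test_step_up_hand_example(self):
        assert np.allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_is_unchanged(self):
        assert fdr_adjust([0.3])[0] == pytest.approx(0.3)

    def test_q_dominates_p_and_is_monotone_in_sorted_order(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.random(rng.integers(2, 30))
            q = fdr_adjust(p)
            assert (q >= p - 1e-15).all()
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-15).all()
            assert (q <= 1).all()

    def test_out_of_range_p_raises(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestPermutationGLM:
    def _cohort(self, seed, effect=0.0, n=60):
        rng = np.random.default_rng(seed)
        labels = np.repeat([1, 2], n // 2)
        age = rng.uniform(4, 7, n)
        sex = rng.integers(0, 2, n)
        y = rng.normal(size=n) + effect * (labels == 2)
        return y, labels, np.column_stack([age, sex])

    def test_same_seed_gives_identical_p(self):
        y, labels, cov = self._cohort(0, effect=0.5)
        p1 = permutation_glm(y, labels, cov, n_perm=300, seed=9).p_raw
        p2 = permutation_glm(y, labels, cov, n_perm=300, seed=9).p_raw
        assert p1 == p2

    def test_detects_a_strong_group_effect(self):
        y, labels, cov = self._cohort(1, effect=2.0)
        res = permutation_glm(y, labels, cov, n_perm=499, seed=0)
        assert res.p_raw < 0.01
        assert res.effect_family == "cohens_f" and res.effect_size > 0

    def test_rejection_concordance_with_unadjusted_rank_test(self):
        agree = 0
        for seed in range(200):
            y, labels, cov = self._cohort(seed, effect=1.2)
            p_glm = permutation_glm(y, labels, cov, n_perm=299, seed=seed).p_raw
            p_mw = compare_numeric(y, labels, gate="nonparametric").p_raw
            agree += (p_glm < 0.05) == (p_mw < 0.05)
        assert agree >= 190

    def test_rank_deficient_design_names_columns(self):
        y, labels, cov = self._cohort(2)
        cov = np.column_stack([cov, cov[:, 0]])  # duplicated covariate
        with pytest.raises(ValueError, match="collinear"):
            permutation_glm(y, labels, cov, n_perm=200, seed=0)

    def test_too_few_permutations_rejected(self):
        y, labels, cov = self._cohort(3)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_glm(y, labels, cov, n_perm=50, seed=0)


@pytest.fixture(scope="module")
def profiled():
    cohort = generate_cohort(
        CohortSpec(n_subjects=90, cluster_proportions=(0.5, 0.5),
                   effect_size=1.5, out_of_model_effect=1.5, seed=8)
    )
    results = profile_clusters(
        cohort.true_labels.to_numpy(),
        cohort.blocks,
        cohort.out_of_model,
        cohort.covariates,
        n_perm=299,
        seed=0,
    )
    return cohort, results


class TestProfileClusters:

    def test_every_variable_is_dispatched_by_kind(self, profiled):
        cohort, results = profiled
        tests_by_var = {}
        for r in results:
            tests_by_var.setdefault(r.variable, set()).add(r.test)
        for var in ("ventilation_days", "tpn_days", "cpap_days"):
            assert tests_by_var[var] == {"extended_cochran_armitage"}
        assert any("mann_whitney" in t or t in ("one_way_linear_model",)
                   for t in tests_by_var["imd"])
        assert "permutation_glm" in tests_by_var["imd"]
        assert "permutation_glm" in tests_by_var["wppsi_fsiq"]

    def test_fdr_applied_within_families_and_sorted(self, profiled):
        _, results = profiled
        assert all(r.q_fdr >= r.p_raw - 1e-12 for r in results)
        qs = [r.q_fdr for r in results]
        assert qs == sorted(qs)
        statuses = {r.model_status for r in results}
        assert statuses == {"in_model", "out_of_model"}

    def test_strong_effects_are_detected(self, profiled):
        _, results = profiled
        numeric_unadj = [
            r for r in results
            if r.model_status == "out_of_model" and r.test != "permutation_glm"
        ]
        assert all(r.q_fdr < 0.05 for r in numeric_unadj)

    def test_empty_out_of_model_table_is_fine(self, profiled):
        cohort, _ = profiled
        results = profile_clusters(
            cohort.true_labels.to_numpy(), cohort.blocks,
            pd.DataFrame(index=cohort.out_of_model.index), None,
            n_perm=199, seed=1,
        )
        assert all(r.model_status == "in_model" for r in results)


def test_effect_sizes_respect_their_bounds_on_random_fixtures():
    rng = np.random.default_rng(10)
    for i in range(1000):
        kind = i % 3
        if kind == 0:  # two-group rank biserial
            n1, n2 = rng.integers(3, 12, 2)
            res = compare_numeric(
                rng.normal(size=n1 + n2), [1] * n1 + [2] * n2,
                gate="nonparametric",
            )
            assert -1 - 1e-12 <= res.effect_size <= 1 + 1e-12
        elif kind == 1:  # epsilon squared
            ns = rng.integers(3, 8, 3)
            vals = rng.normal(size=ns.sum())
            labels = np.repeat([1, 2, 3], ns)
            res = compare_numeric(vals, labels, gate="nonparametric")
            assert 0 <= res.effect_size <= 1
        else:  # Cramer's V
            t = rng.integers(1, 30, size=(2, 2))
            res = compare_categorical(t)
            assert 0 <= res.effect_size <= 1 + 1e-12
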
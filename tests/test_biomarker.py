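"""ddCT quantification, the two-tRF ratio, Mann-Whitney, and log-rank."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from trfkit.biomarker import (
    delta_delta_ct,
    dichotomize,
    logrank,
    mann_whitney,
    ratio_score,
    relative_expression,
)


class TestDeltaDeltaCt:
    def test_calibrator_yields_unity(self):
        _, rel = delta_delta_ct(25.0, 20.0, 5.0)
        assert rel == pytest.approx(1.0)

    def test_doubling_per_cycle(self):
        _, rel = delta_delta_ct(23.0, 20.0, 5.0)  # ddCT = -2
        assert rel == pytest.approx(4.0)

    def test_monotonicity(self):
        base = delta_delta_ct(25.0, 20.0, 0.0)[1]
        assert delta_delta_ct(26.0, 20.0, 0.0)[1] < base   # more cycles = less RNA
        assert delta_delta_ct(25.0, 21.0, 0.0)[1] > base   # relative to reference

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            delta_delta_ct(float("nan"), 20.0, 0.0)

    def test_planted_fold_recovered(self, rng):
        # 4-fold planted effect, CT noise sigma = 0.2, n = 40 per group
        rows = []
        for i in range(40):
            ct_ref = rng.normal(20, 0.2)
            rows.append({"sample_id": f"n{i}", "group": "NAP",
                         "ct_REF": ct_ref, "ct_T": ct_ref + 5 + rng.normal(0, 0.2)})
        for i in range(40):
            ct_ref = rng.normal(20, 0.2)
            rows.append({"sample_id": f"p{i}", "group": "PCa",
                         "ct_REF": ct_ref, "ct_T": ct_ref + 5 - 2 + rng.normal(0, 0.2)})
        expr = relative_expression(pd.DataFrame(rows), ["T"], "REF", "NAP")
        gm = expr.groupby("group")["rel_T"].apply(lambda v: np.exp(np.mean(np.log(v))))
        assert 3.5 <= gm["PCa"] / gm["NAP"] <= 4.6

    def test_missing_reference_ct_excluded_with_warning(self):
        df = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "group": ["NAP", "NAP", "PCa"],
                "ct_REF": [20.0, np.nan, 20.0],
                "ct_T": [25.0, 25.0, 23.0],
            }
        )
        with pytest.warns(UserWarning):
            expr = relative_expression(df, ["T"], "REF", "NAP")
        assert list(expr["sample_id"]) == ["a", "c"]


class TestRatioScore:
    @pytest.mark.parametrize("a,b,expected", [(1, 1, 1.0), (4, 0.5, 8.0), (2.7, 2.7, 1.0)])
    def test_values(self, a, b, expected):
        assert ratio_score(a, b) == pytest.approx(expected)

    def test_reciprocity(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.01, 10, 2)
            assert ratio_score(a, b) * ratio_score(b, a) == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ratio_score(0.0, 1.0)


def brute_force_mw(a, b):
    """Exact enumeration oracle: U via pairwise comparisons, two-sided p as
    2 x smaller tail count / total labelings, capped at 1."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def u_of(subset):
        grp = [pooled[i] for i in subset]
        other = [pooled[i] for i in range(len(pooled)) if i not in set(subset)]
        u = 0.0
        for x in grp:
            for y in other:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    u_obs = u_of(tuple(range(n1)))
    total = n_le = n_ge = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = u_of(combo)
        total += 1
        n_le += u <= u_obs + 1e-9
        n_ge += u >= u_obs - 1e-9
    return u_obs, min(1.0, 2.0 * min(n_le, n_ge) / total)


class TestMannWhitney:
    def test_identical_multisets_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_complete_separation_small_n(self):
        u, p = mann_whitney([1, 2, 3], [10, 11, 12])
        assert u == 0  # min(U1, U2) convention
        assert p == pytest.approx(0.1)

    def test_shift_invariance(self):
        u1, p1 = mann_whitney([1, 5, 9, 2], [3, 7, 8])
        u2, p2 = mann_whitney([101, 105, 109, 102], [103, 107, 108])
        assert (u1, p1) == (u2, p2)

    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 3), (3, 3), (4, 5), (5, 2), (7, 7), (6, 4)])
    def test_exact_p_matches_enumeration(self, n1, n2, rng):
        for _ in range(5):
            a = rng.integers(0, 6, n1).astype(float)  # small range forces ties
            b = rng.integers(0, 6, n2).astype(float)
            u, p = mann_whitney(a, b)
            u_oracle, p_oracle = brute_force_mw(a, b)
            assert p == pytest.approx(p_oracle, abs=1e-12)
            assert u == pytest.approx(min(u_oracle, n1 * n2 - u_oracle), abs=1e-9)

    def test_large_n_matches_scipy_asymptotic(self, rng):
        from scipy.stats import mannwhitneyu

        a = rng.normal(0, 1, 25)
        b = rng.normal(0.5, 1, 30)
        _, p = mann_whitney(a, b)
        res = mannwhitneyu(a, b, method="asymptotic", use_continuity=False)
        assert p == pytest.approx(res.pvalue, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestDichotomize:
    def test_median_split_ties_to_low(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        labels = dichotomize(scores)
        assert set(labels[labels == "low"].index) == {"a", "b"}
        assert set(labels[labels == "high"].index) == {"c", "d"}

    def test_all_equal_scores_degenerate(self):
        with pytest.raises(ValueError):
            dichotomize(pd.Series([2.0, 2.0, 2.0, 2.0]))

    def test_fixed_cutoff_matches_median_here(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0])
        assert dichotomize(scores, policy="fixed", cutoff=2.5).tolist() == \
            dichotomize(scores).tolist()


class TestLogrank:
    def test_identical_strata(self):
        data = [(1.0, 1), (2.0, 1), (3.0, 1)]
        chi2, p = logrank({"a": data, "b": list(data)})
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_worked_fixture(self):
        # A: events at 1,2,3; B: events at 10,11,12; no censoring.
        # Risk tables give sum(O1-E1) = 0.5+0.6+0.75 = 37/20 and
        # V = 1/4 + 6/25 + 3/16 = 271/400, so chi2 = (37/20)^2/(271/400)
        # = 1369/271.
        strata = {
            "A": [(1.0, 1), (2.0, 1), (3.0, 1)],
            "B": [(10.0, 1), (11.0, 1), (12.0, 1)],
        }
        chi2, p = logrank(strata)
        assert chi2 == pytest.approx(1369 / 271, abs=1e-9)
        from scipy.stats import chi2 as chi2_dist

        assert p == pytest.approx(chi2_dist.sf(1369 / 271, 1), abs=1e-12)

    def test_all_censored_stratum_is_finite(self):
        strata = {
            "A": [(1.0, 1), (2.0, 1), (5.0, 0)],
            "B": [(3.0, 0), (4.0, 0), (6.0, 0)],
        }
        chi2, p = logrank(strata)
        assert math.isfinite(chi2) and 0 <= p <= 1

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        t1 = rng.exponential(10, 15)
        t2 = rng.exponential(20, 12)
        e1 = rng.integers(0, 2, 15)
        e2 = rng.integers(0, 2, 12)
        if e1.sum() == 0:
            e1[0] = 1
        if e2.sum() == 0:
            e2[0] = 1
        chi2, p = logrank(
            {"a": list(zip(t1, e1)), "b": list(zip(t2, e2))}
        )
        ref = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            logrank({"a": [(1.0, 1)], "b": []})

    def test_permutation_reference(self, rng):
        # chi-square p agrees with a label-permutation reference on n <= 30
        t1 = rng.exponential(10, 14)
        t2 = rng.exponential(25, 14)
        data = [(float(t), 1) for t in np.concatenate([t1, t2])]
        chi_obs, p_obs = logrank({"a": data[:14], "b": data[14:]})
        n_perm = 5000
        count = 0
        idx = np.arange(28)
        for _ in range(n_perm):
            rng.shuffle(idx)
            a = [data[i] for i in idx[:14]]
            b = [data[i] for i in idx[14:]]
            chi, _ = logrank({"a": a, "b": b})
            count += chi >= chi_obs - 1e-12
        p_perm = count / n_perm
        mc_sigma = math.sqrt(max(p_perm, 1e-4) * (1 - min(p_perm, 0.9999)) / n_perm)
        assert abs(p_perm - p_obs) <= 4 * mc_sigma + 0.02
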
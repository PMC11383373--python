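"""Rank tests, BH adjustment, dichotomization, Cox and Kaplan-Meier."""

import math

import numpy as np
import pytest

from tcrep.models import ClinicalRecord, Group
from tcrep.stats import (
    bh_adjust,
    cox_fit,
    km_curve,
    kruskal_wallis,
    median_dichotomize,
    pairwise_wilcoxon,
    spearman,
    wilcoxon_rank_sum,
)

from oracles import bh_stepup, exact_wilcoxon_p


def clinical_cohort(rng, n=120, hr=1.0, censor_rate=0.4, binary=None):
    """Exponential survival cohort with an optional binary covariate effect."""
    lam0 = math.log(2) / 12
    recs, values = [], {}
    for i in range(n):
        x = float(rng.random() < 0.5) if binary is None else binary[i]
        lam = lam0 * (hr if x else 1.0)
        t_d = rng.exponential(1 / lam)
        t_c = rng.exponential(1 / (lam0 * censor_rate / (1 - censor_rate)))
        t, e = (t_d, True) if t_d <= t_c else (t_c, False)
        pid = f"p{i:03d}"
        recs.append(
            ClinicalRecord(pid, Group.HIV_NEG, 50.0, "F", t, e, t, e)
        )
        values[pid] = x
    return recs, values


class TestWilcoxon:
    def test_exact_enumeration_example(self):
        """{1,2,3} vs {4,5,6}: 2/20 labelings are as extreme, p = 0.1."""
        comp = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert comp.p_value == pytest.approx(0.1, abs=1e-12)
        assert comp.p_value == pytest.approx(exact_wilcoxon_p([1, 2, 3], [4, 5, 6]))

    def test_exact_matches_enumeration_on_random_data(self, rng):
        for _ in range(10):
            x = list(rng.permutation(40)[:5].astype(float))
            y = list(rng.permutation(40)[20:27].astype(float))
            if set(x) & set(y):
                continue
            comp = wilcoxon_rank_sum(x, y)
            assert comp.p_value == pytest.approx(exact_wilcoxon_p(x, y), abs=1e-9)

    def test_identical_samples_no_signal(self):
        comp = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert comp.p_value >= 0.99

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=15)
        p1 = wilcoxon_rank_sum(x, y).p_value
        p2 = wilcoxon_rank_sum(np.exp(x), np.exp(y)).p_value
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestPairwiseWilcoxon:
    def test_three_groups_three_comparisons(self, rng):
        vals = {g: list(rng.normal(size=6)) for g in ("a", "b", "c")}
        comps = pairwise_wilcoxon(vals)
        assert len(comps) == 3
        assert {c.groups for c in comps} == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_identical_groups_fold_one(self):
        vals = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        comps = pairwise_wilcoxon(vals)
        assert comps[0].fold_change == pytest.approx(1.0)

    def test_zero_median_denominator_flagged(self):
        vals = {"a": [1.0, 2.0], "b": [0.0, 0.0]}
        comps = pairwise_wilcoxon(vals)
        assert comps[0].fold_change is None
        assert "zero-median" in comps[0].note

    def test_fold_orientation(self):
        vals = {"a": [4.0, 4.0, 4.0], "b": [2.0, 2.0, 2.0]}
        comps = pairwise_wilcoxon(vals)
        assert comps[0].groups == ("a", "b")
        assert comps[0].fold_change == pytest.approx(2.0)


class TestKruskalWallis:
    def test_identical_observations_h_zero(self):
        comp = kruskal_wallis({"a": [2.0, 2.0], "b": [2.0, 2.0, 2.0]})
        assert comp.statistic == 0.0
        assert comp.p_value == 1.0

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"a": [1.0, 2.0], "b": []})

    def test_two_groups_tracks_wilcoxon_asymptotically(self, rng):
        x = list(rng.normal(0, 1, size=150))
        y = list(rng.normal(0.3, 1, size=150))
        p_kw = kruskal_wallis({"a": x, "b": y}).p_value
        p_w = wilcoxon_rank_sum(x, y).p_value
        assert p_kw == pytest.approx(p_w, rel=0.10)

    def test_tiny_groups_match_permutation_null(self):
        """Full enumeration of group assignments at n=(3,3,3) calibrates the p."""
        from itertools import combinations

        data = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0]
        n = len(data)

        def h_stat(ranks_a, ranks_b, ranks_c):
            h = 0.0
            for ranks in (ranks_a, ranks_b, ranks_c):
                h += sum(ranks) ** 2 / len(ranks)
            return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)

        observed = kruskal_wallis(
            {"a": data[:3], "b": data[3:6], "c": data[6:]}
        ).statistic
        all_ranks = list(range(1, n + 1))
        count = total = 0
        for a in combinations(all_ranks, 3):
            rest = [r for r in all_ranks if r not in a]
            for b in combinations(rest, 3):
                c = [r for r in rest if r not in b]
                total += 1
                if h_stat(a, b, c) >= observed - 1e-9:
                    count += 1
        p_perm = count / total
        p_chi = kruskal_wallis({"a": data[:3], "b": data[3:6], "c": data[6:]}).p_value
        # chi-square approximation is rough at n=9; enumeration and the
        # implementation must agree on significance and roughly on level
        assert p_perm < 0.05 and p_chi < 0.05
        assert p_chi == pytest.approx(p_perm, abs=0.03)


class TestBHAdjust:
    def test_hand_stepup_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_reference_stepup_and_monotone(self, rng):
        for _ in range(20):
            ps = list(rng.uniform(size=int(rng.integers(1, 15))))
            adj = bh_adjust(ps)
            ref = bh_stepup(ps)
            assert adj == pytest.approx(ref, abs=1e-12)
            assert all(a >= p - 1e-12 for a, p in zip(adj, ps))
            # same rejection set at any threshold
            for alpha in (0.01, 0.05, 0.1):
                assert {i for i, a in enumerate(adj) if a <= alpha} == {
                    i for i, a in enumerate(ref) if a <= alpha
                }

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestSpearman:
    def test_perfect_monotone(self):
        up = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        down = spearman([1, 2, 3, 4], [9, 7, 5, 3])
        assert up.statistic == pytest.approx(1.0)
        assert down.statistic == pytest.approx(-1.0)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])

    def test_null_p_roughly_uniform(self, rng):
        ps = [
            spearman(rng.normal(size=20), rng.normal(size=20)).p_value
            for _ in range(300)
        ]
        assert 0.02 < np.mean(np.array(ps) < 0.05) < 0.10
        assert abs(np.mean(ps) - 0.5) < 0.08


class TestMedianDichotomize:
    def test_even_split(self):
        out = median_dichotomize({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        assert {k for k, v in out.items() if v == "high"} == {"c", "d"}

    def test_ties_at_median_go_low(self):
        out = median_dichotomize({"a": 1.0, "b": 2.0, "c": 2.0, "d": 3.0})
        assert {k for k, v in out.items() if v == "high"} == {"d"}

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            median_dichotomize({"a": 2.0, "b": 2.0})

    def test_split_sizes_near_half(self, rng):
        values = {f"p{i}": float(v) for i, v in enumerate(rng.normal(size=35))}
        out = median_dichotomize(values)
        n_high = sum(1 for v in out.values() if v == "high")
        assert abs(n_high - 35 / 2) <= 1


class TestCox:
    def test_planted_hr_recovered(self, rng):
        recs, values = clinical_cohort(rng, n=200, hr=0.3, censor_rate=0.3)
        res = cox_fit(recs, "OS", "x", values=values)
        se = (math.log(res.ci_high) - math.log(res.ci_low)) / (2 * 1.96)
        assert abs(math.log(res.hr) - math.log(0.3)) < 3 * se
        assert res.ci_low <= res.hr <= res.ci_high

    def test_constant_covariate_raises(self, rng):
        recs, _ = clinical_cohort(rng, n=50)
        with pytest.raises(ValueError, match="vary"):
            cox_fit(recs, "OS", "x", values={r.patient_id: 1.0 for r in recs})

    def test_sign_matches_km_separation(self, rng):
        recs, values = clinical_cohort(rng, n=200, hr=0.3)
        res = cox_fit(recs, "OS", "x", values=values)
        strata = {pid: ("x1" if v else "x0") for pid, v in values.items()}
        km = km_curve(recs, "OS", strata)
        med0, med1 = km["x0"].median, km["x1"].median
        assert res.hr < 1
        assert med1 is None or med0 is None or med1 > med0

    def test_dichotomized_string_values_accepted(self, rng):
        recs, values = clinical_cohort(rng, n=100, hr=0.4)
        labels = {pid: ("high" if v else "low") for pid, v in values.items()}
        res = cox_fit(recs, "PFS", "biomarker", values=labels)
        assert res.hr < 1


class TestKaplanMeier:
    def test_no_censoring_steps_by_tenth(self):
        recs = [
            ClinicalRecord(f"p{i}", Group.HIV_NEG, 50, "F", float(i + 1), True,
                           float(i + 1), True)
            for i in range(10)
        ]
        km = km_curve(recs, "OS")
        surv = km["all"].curve["survival"].tolist()
        assert surv[0] == pytest.approx(1.0)
        steps = np.diff(surv)
        assert np.allclose(steps, -0.1, atol=1e-9)
        assert km["all"].median == pytest.approx(5.0)

    def test_all_censored_flat_no_median(self):
        recs = [
            ClinicalRecord(f"p{i}", Group.HIV_NEG, 50, "F", float(i + 1), False,
                           float(i + 1), False)
            for i in range(8)
        ]
        km = km_curve(recs, "OS")
        assert (km["all"].curve["survival"] == 1.0).all()
        assert km["all"].median is None

    def test_exponential_median_near_closed_form(self, rng):
        lam = math.log(2) / 20
        recs = [
            ClinicalRecord(f"p{i}", Group.HIV_NEG, 50, "F", t, True, min(0.1, t), False)
            for i in range(400)
            for t in [float(rng.exponential(1 / lam))]
        ]
        km = km_curve(recs, "OS")
        assert km["all"].median == pytest.approx(20.0, rel=0.15)
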
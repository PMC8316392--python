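"""Statistical battery: summaries, normality gate, Welch/Games-Howell,
Kruskal-Wallis/Dunn, the dimorphism call rule and the confidence band."""

import math

import numpy as np
import pytest
from scipy import stats

from molmorph.dimorphism import (
    PAIR_F5_M5,
    analyze_species,
    brown_forsythe_anova,
    call_dimorphism,
    confidence_band,
    games_howell,
    gaussian_fit_check,
    kruskal_wallis_dunn,
    stars,
    summarize_group,
    welch_anova,
)


class TestSummarizeGroup:
    def test_constant_sample(self):
        s = summarize_group([1.0, 1.0, 1.0], N=2)
        assert (s.mean, s.SEM, s.min, s.max) == (1.0, 0.0, 1.0, 1.0)

    def test_two_point_closed_form(self):
        s = summarize_group([1.0, 2.0], N=1)
        assert s.mean == 1.5
        assert s.SD == pytest.approx(math.sqrt(0.5))
        assert s.SEM == pytest.approx(0.5)

    def test_moment_recovery_from_generator(self, rng):
        x = rng.normal(1.2, 0.1, size=10_000)
        s = summarize_group(x, N=5000)
        assert abs(s.mean - 1.2) < 3 * 0.1 / math.sqrt(10_000)
        assert s.SEM == pytest.approx(s.SD / 100.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([], N=0)


class TestGaussianCheck:
    def test_normal_groups_pass(self, rng):
        ok = 0
        for _ in range(200):
            gs = [rng.normal(1.0, 0.1, 60) for _ in range(3)]
            if gaussian_fit_check(gs)["gaussian_ok"]:
                ok += 1
        # each replicate passes with prob >= 0.95^3 ~ 0.857
        assert ok / 200 >= 0.80

    def test_heavy_tailed_groups_fail(self, rng):
        ok = 0
        for _ in range(100):
            gs = [
                np.concatenate([rng.normal(1, 0.1, 50), rng.standard_cauchy(10)])
                for _ in range(3)
            ]
            if gaussian_fit_check(gs)["gaussian_ok"]:
                ok += 1
        assert ok / 100 <= 0.2

    def test_lognormal_rescued_by_log_transform(self, rng):
        gs = [np.exp(rng.normal(0, 1.0, 100)) for _ in range(3)]
        res = gaussian_fit_check(gs)
        assert res["gaussian_ok"] and res["use_log"]

    def test_small_groups_not_assessable(self):
        res = gaussian_fit_check([[1, 2, 3, 4, 5]] * 3)
        assert not res["assessable"] and not res["gaussian_ok"]


class TestWelchAnova:
    def test_two_groups_equals_squared_welch_t(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.4, 2, 45)
        w = welch_anova([a, b])
        t = stats.ttest_ind(a, b, equal_var=False)
        assert w["statistic"] == pytest.approx(t.statistic**2, rel=1e-12)
        assert w["p"] == pytest.approx(t.pvalue, rel=1e-12)

    def test_identical_groups_give_p_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        w = welch_anova([g, list(reversed(g))])
        assert w["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert w["p"] == pytest.approx(1.0)

    def test_constant_equal_groups_convention(self):
        w = welch_anova([[2.0, 2.0], [2.0, 2.0]])
        assert w["p"] == 1.0

    def test_shift_invariance(self, rng):
        gs = [rng.normal(0, s, 20) for s in (1, 2, 3)]
        w0 = welch_anova(gs)
        w1 = welch_anova([g + 17.3 for g in gs])
        assert w1["statistic"] == pytest.approx(w0["statistic"], rel=1e-9)

    def test_brown_forsythe_agrees_under_homoscedasticity(self, rng):
        gs = [rng.normal(m, 1, 40) for m in (0, 0.5, 1)]
        bf = brown_forsythe_anova(gs)
        w = welch_anova(gs)
        assert bf["p"] == pytest.approx(w["p"], abs=0.05)
        assert 0 <= bf["p"] <= 1


class TestGamesHowell:
    def test_identical_groups_near_one(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [3.0, 2.0, 1.0]}
        for c in games_howell(g):
            assert c.adjusted_p == pytest.approx(1.0, abs=1e-9)

    def test_pair_order_symmetry(self, rng):
        g = {"a": rng.normal(0, 1, 20), "b": rng.normal(1, 2, 25)}
        p_ab = games_howell(g, [("a", "b")])[0].adjusted_p
        p_ba = games_howell(g, [("b", "a")])[0].adjusted_p
        assert p_ab == pytest.approx(p_ba)

    def test_adjustment_not_below_unadjusted_welch_p(self, rng):
        gs = {"a": rng.normal(0, 1, 25), "b": rng.normal(0.7, 2, 30),
              "c": rng.normal(0.2, 1.5, 28)}
        for comp in games_howell(gs):
            a, b = comp.pair
            p_un = stats.ttest_ind(np.asarray(gs[a]), np.asarray(gs[b]),
                                   equal_var=False).pvalue
            assert comp.adjusted_p >= p_un - 1e-12

    def test_decisions_match_permutation_oracle(self, rng):
        n = 40
        gs = {
            "a": rng.normal(0.0, 1.0, n),
            "b": rng.normal(0.0, 1.0, n),
            "c": rng.normal(3.0, 1.0, n),  # shifted by 3 SD
        }
        res = {c.pair: c.adjusted_p for c in games_howell(gs)}
        assert res[("a", "c")] < 0.001 and res[("b", "c")] < 0.001
        assert res[("a", "b")] > 0.05
        # permutation reference on each pair: same rejection decisions
        for (x, y), padj in res.items():
            pooled = np.concatenate([gs[x], gs[y]])
            obs = abs(np.mean(gs[x]) - np.mean(gs[y]))
            perm = np.array([
                abs(np.diff(rng.permutation(pooled).reshape(2, n).mean(1))[0])
                for _ in range(10_000)
            ])
            p_perm = (np.sum(perm >= obs) + 1) / 10_001
            assert (padj < 0.05) == (p_perm < 0.05)


class TestKruskalDunn:
    def test_identical_samples(self):
        res = kruskal_wallis_dunn({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res[0].omnibus_stat == pytest.approx(0.0, abs=1e-12)
        assert res[0].omnibus_p == pytest.approx(1.0)

    def test_all_constant(self):
        res = kruskal_wallis_dunn({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert res[0].omnibus_stat == 0.0 and res[0].omnibus_p == 1.0

    def test_tie_corrected_H_hand_case(self):
        # heavy ties: values only in {1.0, 1.1}
        groups = {"a": [1.0, 1.0, 1.1], "b": [1.1, 1.1, 1.0]}
        res = kruskal_wallis_dunn(groups)
        pooled = [1.0, 1.0, 1.1, 1.1, 1.1, 1.0]
        ranks = stats.rankdata(pooled)
        n = 6
        h = (12 / (n * (n + 1))) * (
            ranks[:3].sum() ** 2 / 3 + ranks[3:].sum() ** 2 / 3
        ) - 3 * (n + 1)
        ties = [3, 3]
        correction = 1 - sum(t**3 - t for t in ties) / (n**3 - n)
        assert res[0].omnibus_stat == pytest.approx(h / correction, rel=1e-12)

    def test_omnibus_matches_permutation_distribution(self, rng):
        groups = {"a": [1.2, 3.4, 0.1, 2.2], "b": [4.5, 2.1, 5.0, 3.3],
                  "c": [0.2, 1.1, 0.7, 2.9]}
        h_obs, p_obs = stats.kruskal(*groups.values())
        res = kruskal_wallis_dunn(groups)
        assert res[0].omnibus_stat == pytest.approx(h_obs)
        pooled = np.concatenate(list(groups.values()))
        ranks = stats.rankdata(pooled)
        n = ranks.size
        n_perm = 100_000
        # permute the (tie-free here) rank vector and recompute H directly
        keys = rng.random((n_perm, n)).argsort(axis=1)
        permuted = ranks[keys]
        rsums = permuted.reshape(n_perm, 3, 4).sum(axis=2)
        h_perm = (12.0 / (n * (n + 1))) * (rsums**2 / 4.0).sum(axis=1) - 3 * (n + 1)
        count = int(np.sum(h_perm >= h_obs - 1e-12))
        p_perm = (count + 1) / (n_perm + 1)
        assert abs(p_obs - p_perm) < 4 * math.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.01

    def test_relabel_and_shift_invariance(self, rng):
        gs = {"a": rng.normal(0, 1, 12), "b": rng.normal(1, 1, 10)}
        r1 = kruskal_wallis_dunn(gs, [("a", "b")])[0]
        r2 = kruskal_wallis_dunn(
            {"x": gs["b"] + 5.0, "y": gs["a"] + 5.0}, [("y", "x")]
        )[0]
        assert r1.adjusted_p == pytest.approx(r2.adjusted_p)
        assert r1.omnibus_stat == pytest.approx(r2.omnibus_stat)


class TestCallRule:
    def test_published_positive_case(self):
        # female 1.04 vs male 1.38, adjusted P < 0.001 -> dimorphic
        f = summarize_group(np.full(72, 1.04), N=36, species="baimaii")
        m = summarize_group(np.full(72, 1.38), N=36, species="baimaii")
        assert call_dimorphism(f, m, adjusted_p_f5_m5=5e-4).call == "+"

    def test_boundary_p_is_negative(self):
        # adjusted P exactly 0.001 must NOT be called dimorphic
        f = summarize_group(np.full(68, 1.07), N=34, species="burlai")
        m = summarize_group(np.full(64, 1.13), N=32, species="burlai")
        assert call_dimorphism(f, m, adjusted_p_f5_m5=0.001).call == "−"

    def test_direction_requirement(self):
        f = summarize_group(np.full(10, 1.1), N=5)
        m = summarize_group(np.full(10, 0.9), N=5)
        assert call_dimorphism(f, m, adjusted_p_f5_m5=1e-6).call == "−"

    def test_stars_mapping(self):
        assert [stars(p) for p in (0.2, 0.04, 0.009, 0.0009)] == [
            "ns", "*", "**", "***",
        ]


class TestConfidenceBand:
    def test_constant_sample(self):
        assert confidence_band([2.0, 2.0, 2.0]) == (2.0, 2.0)

    def test_exact_closed_form(self):
        # sample constructed with mean 1.0, SD 0.1 exactly
        x = np.array([0.9, 1.1, 0.9, 1.1])
        sd = np.std(x, ddof=1)
        lo, hi = confidence_band(x)
        assert lo == pytest.approx(1.0 - 3 * sd) and hi == pytest.approx(1.0 + 3 * sd)

    def test_gaussian_coverage(self, rng):
        x = rng.normal(0, 1, 200_000)
        lo, hi = confidence_band(x)
        inside = np.mean((x > lo) & (x < hi))
        assert inside == pytest.approx(0.9973, abs=0.002)


class TestAnalyzeSpecies:
    def test_clear_dimorphism_detected(self, rng):
        f5 = rng.normal(1.05, 0.08, 70)
        m4 = rng.normal(1.05, 0.08, 70)
        m5 = rng.normal(1.45, 0.15, 70)
        res = analyze_species(f5, m4, m5, species="synthetic")
        assert res["call"].call == "+"
        assert res["comparisons"][PAIR_F5_M5].adjusted_p < 0.001

    def test_null_species_not_called(self, rng):
        f5 = rng.normal(1.05, 0.08, 70)
        m4 = rng.normal(1.05, 0.08, 70)
        m5 = rng.normal(1.05, 0.08, 70)
        assert analyze_species(f5, m4, m5)["call"].call == "−"

    def test_nonnormal_data_use_kruskal_branch(self, rng):
        gs = [np.exp(rng.normal(0, 1.5, 60)) - 0.5 for _ in range(3)]
        gs = [np.abs(g) + 0.01 for g in gs]
        res = analyze_species(*gs)
        assert res["test_family"] in ("kruskal_wallis", "welch_anova")
        if not res["gaussian"]["gaussian_ok"]:
            assert res["test_family"] == "kruskal_wallis"
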
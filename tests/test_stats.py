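import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from gutquant.stats import (
    CountData,
    CtTable,
    comparative_ct,
    hatch_fraction,
    holm_adjust,
    mann_whitney,
    nb_glm_lrt,
    paired_t,
    welch_t,
)
from gutquant.synth import generate_counts, generate_ct_table, generate_hatch_table


def small_ct_table(rows):
    return CtTable(pd.DataFrame(rows, columns=["gene", "sample_id", "condition",
                                               "batch_id", "ct"]))


class TestComparativeCt:
    def test_closed_form_fold(self):
        table = small_ct_table(
            [
                ("bgm", "s1", "virgin", "b1", 25.0),
                ("bgm", "s2", "mated", "b1", 24.0),
                ("rp49", "s1", "virgin", "b1", 20.0),
                ("rp49", "s2", "mated", "b1", 20.0),
            ]
        )
        res = comparative_ct(table, "bgm")
        assert res["ddct"].iloc[0] == pytest.approx(-1.0)
        assert res["fold"].iloc[0] == pytest.approx(2.0)

    def test_identical_conditions_null(self):
        table = small_ct_table(
            [
                ("bgm", "s1", "virgin", "b1", 25.0),
                ("bgm", "s2", "mated", "b1", 25.0),
                ("rp49", "s1", "virgin", "b1", 20.0),
                ("rp49", "s2", "mated", "b1", 20.0),
            ]
        )
        res = comparative_ct(table, "bgm")
        assert res["ddct"].iloc[0] == pytest.approx(0.0)
        assert res["fold"].iloc[0] == pytest.approx(1.0)

    def test_per_sample_shift_cancels(self):
        base = [
            ("bgm", "s1", "virgin", "b1", 25.0),
            ("bgm", "s2", "mated", "b1", 24.0),
            ("rp49", "s1", "virgin", "b1", 20.0),
            ("rp49", "s2", "mated", "b1", 20.0),
        ]
        shifted = [
            (g, s, c, b, ct + (3.0 if s == "s2" else 0.0)) for g, s, c, b, ct in base
        ]
        f0 = comparative_ct(small_ct_table(base), "bgm")["fold"].iloc[0]
        f1 = comparative_ct(small_ct_table(shifted), "bgm")["fold"].iloc[0]
        assert f1 == pytest.approx(f0)

    def test_missing_housekeeping_names_sample(self):
        table = small_ct_table(
            [
                ("bgm", "s1", "virgin", "b1", 25.0),
                ("bgm", "s2", "mated", "b1", 24.0),
                ("rp49", "s1", "virgin", "b1", 20.0),
            ]
        )
        with pytest.raises(ValueError, match="s2"):
            comparative_ct(table, "bgm")

    def test_triplicates_averaged_before_delta(self):
        rows = []
        for ct in (24.0, 25.0, 26.0):  # mean 25
            rows.append(("bgm", "s1", "virgin", "b1", ct))
        rows += [
            ("bgm", "s2", "mated", "b1", 24.0),
            ("rp49", "s1", "virgin", "b1", 20.0),
            ("rp49", "s2", "mated", "b1", 20.0),
        ]
        res = comparative_ct(small_ct_table(rows), "bgm")
        assert res["fold"].iloc[0] == pytest.approx(2.0)

    def test_generator_closed_loop_exact(self):
        table = generate_ct_table({"bgm": 2.0}, sd=0.0, n_batches=3, seed=4)
        res = comparative_ct(table, "bgm")
        assert np.allclose(res["fold"], 2.0)

    def test_generator_noisy_recovery(self):
        folds = []
        for seed in range(100):
            table = generate_ct_table({"bgm": 2.0}, sd=0.2, n_batches=6, seed=seed)
            folds.append(comparative_ct(table, "bgm")["fold"].mean())
        assert np.mean(folds) == pytest.approx(2.0, rel=0.05)


class TestPairedT:
    def test_zero_variance_flagged(self):
        res = paired_t([1.0, 1.0, 1.0, 1.0])
        assert "zero_variance" in res.flags
        assert np.isnan(res.p_raw)

    def test_matches_hand_computed_t(self):
        d = np.array([2.1, 1.4, 3.0, 0.5])
        res = paired_t(d, tail="two")
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(4))
        p_hand = 2 * sps.t.sf(abs(t_hand), 3)
        assert res.statistic == pytest.approx(t_hand)
        assert res.p_raw == pytest.approx(p_hand)
        assert res.df == 3

    def test_one_tailed_is_half_two_tailed_in_direction(self):
        d = [2.1, 1.4, 3.0, 0.5]  # positive effect
        two = paired_t(d, tail="two").p_raw
        one = paired_t(d, tail="one").p_raw
        assert one == pytest.approx(two / 2)


class TestWelchT:
    def test_identical_samples(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_satterthwaite_df_closed_form(self):
        x = np.array([0.0, 0.0, 0.0, 0.0])
        y = np.array([1.0, 1.0, 1.0, 1.0001])
        res = welch_t(x, y)
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        nx, ny = len(x), len(y)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
        assert res.df == pytest.approx(df)
        assert res.p_raw < 1e-6

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 8)
        y = rng.normal(1, 2, 11)
        base = welch_t(x, y)
        scaled = welch_t(10 * x + 4, 10 * y + 4)
        assert scaled.statistic == pytest.approx(base.statistic)
        assert scaled.p_raw == pytest.approx(base.p_raw)

    def test_both_constant_flagged(self):
        res = welch_t([2.0, 2.0], [2.0, 2.0])
        assert "zero_variance" in res.flags


def brute_force_mw_p(x, y):
    """Independent enumeration oracle for the exact two-sided p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.r_[x, y]
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    mu = n1 * len(y) / 2
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = [
        ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    crit = abs(u_obs - mu) - 1e-12
    return float(np.mean([abs(u - mu) >= crit for u in us]))


class TestMannWhitney:
    def test_separated_pairs_exact_p(self):
        res = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0
        assert res.exact
        assert res.p_raw == pytest.approx(1 / 3)

    def test_interleaved_no_evidence(self):
        res = mann_whitney([1.0, 3.0, 5.0], [2.0, 4.0, 6.0])
        assert res.p_raw > 0.5

    def test_exact_matches_bruteforce_random_cases(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 11 - n1))
            x = rng.integers(0, 6, n1).astype(float)  # integers force ties
            y = rng.integers(0, 6, n2).astype(float)
            res = mann_whitney(x, y)
            assert res.exact
            assert res.p_raw == pytest.approx(brute_force_mw_p(x, y))

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = rng.normal(0, 1, 4)
            y = rng.normal(0.5, 1, 5)
            res = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.p_raw == pytest.approx(ref.pvalue)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, 20)
        y = rng.normal(1, 1, 20)
        res = mann_whitney(x, y)
        assert not res.exact
        assert res.p_raw < 0.05


class TestHolmAdjust:
    def test_hand_stepped_two_values(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_single_value_identity(self):
        assert holm_adjust([0.5]) == pytest.approx([0.5])

    def test_hand_stepped_four_values(self):
        # sorted: .005*4=.02, .01*3=.03, .03*2=.06, .9 -> capped monotone
        raw = [0.03, 0.005, 0.9, 0.01]
        assert holm_adjust(raw) == pytest.approx([0.06, 0.02, 0.9, 0.03])

    @settings(derandomize=True, max_examples=50)
    @given(hst.lists(hst.floats(min_value=0, max_value=1), min_size=1, max_size=12))
    def test_bounds_property(self, pvals):
        adj = holm_adjust(pvals)
        assert all(a >= p - 1e-12 for a, p in zip(adj, pvals))
        assert all(a <= 1.0 + 1e-12 for a in adj)
        # monotone in sorted order
        order = np.argsort(pvals)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)


class TestNbGlmLrt:
    def test_strong_effect_detected(self):
        hits = 0
        for seed in range(40):
            data = generate_counts({"virgin": 2.0, "mated": 10.0},
                                   dispersion=1.0, n_per_group=30, seed=seed)
            if nb_glm_lrt(data).p_raw < 0.001:
                hits += 1
        assert hits >= 38  # >= 95%

    def test_exact_null_by_duplication(self):
        counts = [3, 7, 2, 9, 5, 4, 6, 8]
        rows = [
            {"unit_id": f"{g}{i}", "group": g, "count": c}
            for g in ("a", "b")
            for i, c in enumerate(counts)
        ]
        res = nb_glm_lrt(CountData(pd.DataFrame(rows)))
        assert res.p_raw == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_counts_rejected(self):
        rows = [
            {"unit_id": f"{g}{i}", "group": g, "count": 0}
            for g in ("a", "b")
            for i in range(5)
        ]
        with pytest.raises(ValueError):
            nb_glm_lrt(CountData(pd.DataFrame(rows)))

    def test_dispersion_estimate_reported(self):
        data = generate_counts({"a": 5.0, "b": 5.0}, dispersion=2.0,
                               n_per_group=200, seed=1)
        res = nb_glm_lrt(data)
        assert 0.5 < res.extra["theta"] < 8.0


class TestHatchFraction:
    def test_simple_ratio(self):
        df = pd.DataFrame(
            [
                {"group": "ctrl", "eggs_laid": 10, "eggs_hatched": 9},
                {"group": "ctrl", "eggs_laid": 20, "eggs_hatched": 18},
                {"group": "rnai", "eggs_laid": 10, "eggs_hatched": 10},
                {"group": "rnai", "eggs_laid": 10, "eggs_hatched": 8},
            ]
        )
        per_vial, summary, results = hatch_fraction(df)
        assert per_vial["fraction"].iloc[0] == pytest.approx(0.9)
        assert set(summary["group"]) == {"ctrl", "rnai"}
        assert len(results) == 1

    def test_hatched_exceeding_laid_rejected(self):
        df = pd.DataFrame(
            [{"group": "g", "eggs_laid": 5, "eggs_hatched": 6}] * 2
        )
        with pytest.raises(ValueError):
            hatch_fraction(df)

    def test_zero_laid_excluded_with_warning(self):
        df = pd.DataFrame(
            [
                {"group": "a", "eggs_laid": 0, "eggs_hatched": 0},
                {"group": "a", "eggs_laid": 10, "eggs_hatched": 9},
                {"group": "a", "eggs_laid": 10, "eggs_hatched": 10},
                {"group": "b", "eggs_laid": 10, "eggs_hatched": 9},
                {"group": "b", "eggs_laid": 10, "eggs_hatched": 8},
            ]
        )
        with pytest.warns(UserWarning):
            per_vial, _, _ = hatch_fraction(df)
        assert len(per_vial) == 4

    def test_generator_hatch_probability_recovered(self):
        df = generate_hatch_table({"ctrl": (40, 60, 0.95)}, seed=3)
        per_vial, summary, _results = hatch_fraction(
            pd.concat([df, generate_hatch_table({"alt": (40, 60, 0.95)}, seed=4)])
        )
        mean = summary.loc[summary["group"] == "ctrl", "mean"].iloc[0]
        # binomial CI around 0.95 with ~2400 eggs
        assert abs(mean - 0.95) < 0.02
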
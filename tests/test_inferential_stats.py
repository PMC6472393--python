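"""Within-subject ANOVA, tests against zero, Holm correction, normality."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import alloreach as ar
from alloreach.inferential_stats import CELLS


def cells_to_table(y: np.ndarray) -> pd.DataFrame:
    rows = []
    for s in range(y.shape[0]):
        for i, (congruence, cluster) in enumerate(CELLS):
            rows.append((f"P{s:02d}", congruence, cluster, y[s, i // 2, i % 2]))
    return pd.DataFrame(rows, columns=["participant_id", "congruence", "cluster",
                                       "weight"])


class TestRmAnova:
    def test_null_data_gives_zero_f(self):
        y = np.tile(np.arange(8, dtype=float)[:, None, None], (1, 2, 2))
        res = ar.rm_anova_2x2(y)
        for e in res.effects.values():
            assert e.F == pytest.approx(0.0, abs=1e-20)
            assert e.partial_eta_sq == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("seed", range(5))
    def test_f_equals_squared_paired_t(self, seed):
        """In a 2-level within design, F of a main effect == paired t squared."""
        rng = np.random.default_rng(seed)
        y = rng.normal(0.2, 0.15, (15, 2, 2))
        res = ar.rm_anova_2x2(y)
        t_c, p_c = stats.ttest_rel(y.mean(axis=2)[:, 0], y.mean(axis=2)[:, 1])
        assert res.effects["congruence"].F == pytest.approx(t_c ** 2)
        assert res.effects["congruence"].p == pytest.approx(p_c)
        t_b, _ = stats.ttest_rel(y.mean(axis=1)[:, 0], y.mean(axis=1)[:, 1])
        assert res.effects["cluster"].F == pytest.approx(t_b ** 2)

    def test_brute_force_sums_of_squares(self):
        """Four-participant fixture checked against first-principles SS table."""
        y = np.array([
            [[0.30, 0.25], [0.10, 0.12]],
            [[0.40, 0.35], [0.22, 0.18]],
            [[0.22, 0.30], [0.05, 0.11]],
            [[0.35, 0.28], [0.15, 0.09]],
        ])
        res = ar.rm_anova_2x2(y)

        # independent brute force over all decomposition terms
        n = 4
        grand = y.mean()
        # SS_A = n * b * sum_i (mean_i - grand)^2 with n = 4 subjects, b = 2
        ss_a = sum(8 * (y[:, i, :].mean() - grand) ** 2 for i in range(2))
        ms_den = 0.0
        for s in range(n):
            for i in range(2):
                dev = (y[s, i, :].mean() - y[s].mean() - y[:, i, :].mean() + grand)
                ms_den += 2 * dev ** 2
        F = (ss_a / 1) / (ms_den / (n - 1))
        assert res.effects["congruence"].F == pytest.approx(F)
        assert res.effects["congruence"].partial_eta_sq == \
            pytest.approx(ss_a / (ss_a + ms_den))

    def test_matches_pingouin(self):
        """Independent reference implementation agrees on all three effects."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        y = rng.normal(0.2, 0.1, (12, 2, 2))
        y[:, 0, :] += 0.12
        res = ar.rm_anova_2x2(y)
        long = cells_to_table(y).rename(columns={"weight": "w"})
        ref = pg.rm_anova(data=long, dv="w", within=["congruence", "cluster"],
                          subject="participant_id", detailed=True, effsize="np2")
        for effect, source in (("congruence", "congruence"), ("cluster", "cluster"),
                               ("interaction", "congruence * cluster")):
            row = ref[ref["Source"] == source].iloc[0]
            assert res.effects[effect].F == pytest.approx(row["F"], rel=1e-9)
            assert res.effects[effect].p == pytest.approx(row["p_unc"], rel=1e-9)
            assert res.effects[effect].partial_eta_sq == pytest.approx(row["np2"], rel=1e-9)

    def test_accepts_weight_table_and_drops_incomplete(self):
        y = np.random.default_rng(1).normal(0.2, 0.1, (6, 2, 2))
        table = cells_to_table(y)
        res_full = ar.rm_anova_2x2(table)
        assert res_full.n_participants == 6
        table_missing = table.drop(index=[0])  # P00 loses one cell
        res = ar.rm_anova_2x2(table_missing)
        assert res.n_participants == 5
        assert res.effects["congruence"].df_error == 4

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            ar.rm_anova_2x2(np.zeros((1, 2, 2)))

    def test_type_one_error_calibrated(self):
        """Null simulations reject the congruence effect at ~alpha."""
        rng = np.random.default_rng(2024)
        n_sims, alpha = 2000, 0.05
        rejections = 0
        for _ in range(n_sims):
            y = rng.normal(0.2, 0.12, (21, 2, 2))
            if ar.rm_anova_2x2(y).effects["congruence"].p < alpha:
                rejections += 1
        rate = rejections / n_sims
        se = np.sqrt(alpha * (1 - alpha) / n_sims)
        assert rate == pytest.approx(alpha, abs=3.5 * se)


class TestHolm:
    def test_hand_example(self):
        assert np.allclose(ar.holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_single_p_unchanged(self):
        assert ar.holm_adjust([0.123])[0] == pytest.approx(0.123)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_step_down_formula_and_dominates(self, pvals):
        """Adjusted values equal the hand-rolled step-down recursion."""
        p = np.asarray(pvals)
        adj = ar.holm_adjust(p)
        order = np.argsort(p, kind="stable")
        m = len(p)
        expected = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * p[idx]))
            expected[idx] = running
        assert np.allclose(adj, expected)
        assert np.all(adj >= p)  # dominance

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10), st.randoms())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_order_invariant(self, pvals, rand):
        p = list(pvals)
        shuffled = p.copy()
        rand.shuffle(shuffled)
        a = ar.holm_adjust(p)
        b = ar.holm_adjust(shuffled)
        lookup = {v: adj for v, adj in zip(shuffled, b)}
        assert all(np.isclose(lookup[v], adj) for v, adj in zip(p, a))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            ar.holm_adjust([0.5, 1.2])


class TestTestsVsZero:
    def test_all_zero_cell(self):
        y = np.zeros((5, 2, 2))
        out = ar.tests_vs_zero(cells_to_table(y))
        assert (out["t"] == 0).all() and (out["p"] == 1).all()

    def test_large_effect_tiny_p(self):
        rng = np.random.default_rng(0)
        y = 0.5 + rng.normal(0, 1e-3, (10, 2, 2))
        out = ar.tests_vs_zero(cells_to_table(y))
        assert (out["p_holm"] < 1e-6).all()

    def test_matches_hand_formula(self):
        vals = np.array([0.1, 0.25, 0.3, 0.05, 0.2, 0.18])
        y = np.tile(vals[:, None, None], (1, 2, 2))
        out = ar.tests_vs_zero(cells_to_table(y))
        t_hand = vals.mean() / (vals.std(ddof=1) / np.sqrt(len(vals)))
        assert np.allclose(out["t"], t_hand)


class TestNormalityScreen:
    def test_matches_r_reference_values(self):
        """W and p frozen from R's shapiro.test on the same 10-vector."""
        vals = np.array([0.12, 0.31, -0.05, 0.44, 0.27, 0.08, 0.51, -0.12, 0.19, 0.33])
        y = np.tile(vals[:, None, None], (1, 2, 2))
        out = ar.normality_screen(cells_to_table(y))
        assert np.allclose(out["W"], 0.97467488, atol=1e-6)
        assert np.allclose(out["p"], 0.93048619, atol=1e-6)

    def test_skewed_samples_rejected_often(self):
        rng = np.random.default_rng(5)
        reject = 0
        for _ in range(50):
            y = rng.exponential(1.0, (50, 1, 1)) * np.ones((1, 2, 2))
            y = y + rng.normal(0, 1e-6, (50, 2, 2))  # break exact ties across cells
            out = ar.normality_screen(cells_to_table(y))
            reject += (out["p"] < 0.05).all()
        assert reject / 50 > 0.9

    def test_constant_cell_signalled(self):
        y = np.ones((5, 2, 2))
        with pytest.raises(ValueError, match="constant"):
            ar.normality_screen(cells_to_table(y))


class TestEmmPairwise:
    def test_null_contrasts_near_zero(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0.2, 0.02, (40, 2, 2))
        out = ar.emm_pairwise(cells_to_table(y), "cells")
        assert np.abs(out["contrast"]).max() < 0.02

    def test_constructed_congruence_effect(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0.2, 0.01, (30, 2, 2))
        y[:, 0, :] += 0.15
        out = ar.emm_pairwise(cells_to_table(y), "congruence")
        assert out["contrast"].iloc[0] == pytest.approx(0.15, abs=0.01)

    def test_contrast_equals_paired_t(self):
        rng = np.random.default_rng(6)
        y = rng.normal(0.25, 0.1, (4, 2, 2))
        out = ar.emm_pairwise(cells_to_table(y), "cluster")
        t_ref, p_ref = stats.ttest_rel(y.mean(axis=1)[:, 0], y.mean(axis=1)[:, 1])
        assert out["t"].iloc[0] == pytest.approx(t_ref)
        assert out["p"].iloc[0] == pytest.approx(p_ref)


def test_stats_report_mentions_all_effects(clean_cohort):
    clean, _ = clean_cohort
    report = ar.stats_report(ar.aggregate_weights(clean))
    for token in ("congruence", "cluster", "interaction", "Shapiro", "SEM"):
        assert token in report
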
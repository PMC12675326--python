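"""Friedman test, post-hoc pairs, Spearman correlation, normality screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stamps3d import (
    StudyDesign,
    condition_comparison,
    default_effect_profile,
    friedman_exact_p,
    friedman_test,
    normality_screen,
    posthoc_pairs,
    simulate_study,
    strain_pressure_correlation,
)
from stamps3d.errors import InsufficientPairs
from stamps3d.stats import bonferroni_adjust, correlation_band


class TestFriedman:
    def test_identical_blocks_give_null_result(self):
        X = np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0], [3.0, 3.0, 3.0]])
        r = friedman_test(X)
        assert r.statistic == 0.0 and r.pvalue == 1.0

    def test_perfect_ordering_reaches_maximum(self):
        # n blocks, k conditions, consistent ordering: statistic n(k-1)
        X = np.tile([1.0, 2.0, 3.0], (3, 1))
        r = friedman_test(X)
        assert r.statistic == pytest.approx(6.0)

    def test_exact_permutation_p_for_perfect_ordering(self):
        # all 3 blocks agree: 6 of 6^3 permutation outcomes reach the max
        X = np.tile([1.0, 2.0, 3.0], (3, 1))
        assert friedman_exact_p(X) == pytest.approx(1 / 36)

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(1)
        for _ in range(8):
            X = rng.normal(size=(6, 4))
            mine = friedman_test(X)
            ref = sps.friedmanchisquare(*X.T)
            assert mine.statistic == pytest.approx(ref.statistic)
            assert mine.pvalue == pytest.approx(ref.pvalue)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(1.0, 5.0, size=(5, 3))
        a = friedman_test(X)
        b = friedman_test(np.exp(X))
        assert a.statistic == pytest.approx(b.statistic)

    def test_incomplete_blocks_dropped_and_counted(self):
        X = np.array([[1.0, 2.0, 3.0], [np.nan, 1.0, 2.0], [2.0, 3.0, 1.0],
                      [3.0, 1.0, 2.0]])
        r = friedman_test(X)
        assert r.n_blocks == 3 and r.n_dropped == 1

    def test_type_one_error_calibrated(self):
        # null: exchangeable conditions, n = 5 blocks; chi-square reference
        # is conservative-but-usable at this n
        rej = 0
        n_sim = 1000
        for i in range(n_sim):
            X = np.random.default_rng(10_000 + i).normal(size=(5, 3))
            if friedman_test(X).pvalue < 0.05:
                rej += 1
        assert 0.02 <= rej / n_sim <= 0.08


class TestPosthoc:
    def test_identical_conditions_degenerate(self):
        X = np.tile(np.arange(5.0)[:, None], (1, 3))
        out = posthoc_pairs(X, ["a", "b", "c"])
        assert (out.p_adjusted == 1.0).all()
        assert out.note.str.contains("degenerate").all()

    def test_bonferroni_arithmetic_and_cap(self):
        np.testing.assert_allclose(bonferroni_adjust([0.02, 0.4], 3),
                                   [0.06, 1.0])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 3))
        out = posthoc_pairs(X)
        assert (out.p_adjusted >= out.p_raw - 1e-15).all()

    def test_clear_difference_detected(self):
        rng = np.random.default_rng(4)
        base = rng.normal(10.0, 0.5, 12)
        X = np.column_stack([base, base + 3.0, base - 3.0])
        out = posthoc_pairs(X, ["a", "b", "c"])
        assert out.significant.all()


class TestCorrelation:
    @staticmethod
    def _table(strain, pressure):
        rows = []
        for i, (s, p) in enumerate(zip(strain, pressure)):
            rows.append(("P01", "flat", 1, f"mth{i % 5 + 1}" if i < 5 else "heel",
                         s, p))
        return pd.DataFrame(rows, columns=["participant", "condition", "repeat",
                                           "region", "peak_smag_pct", "ppp_kpa"])

    def test_perfect_monotone_rho_one(self):
        t, _ = simulate_study(StudyDesign(seed=6), default_effect_profile(),
                              noise_cv=0.0, target_rho=None, pressure_cv=0.0,
                              pressure_link=lambda s: 10.0 + s**1.5)
        r = strain_pressure_correlation(t)
        assert r.rho == pytest.approx(1.0)

    def test_perfect_inverse_rho_minus_one(self):
        x = np.arange(1.0, 6.0)
        tab = self._table(x, x[::-1])
        r = strain_pressure_correlation(tab)
        assert r.rho == pytest.approx(-1.0)

    def test_insufficient_pairs_rejected(self):
        tab = self._table([1.0, 2.0], [2.0, 1.0])
        with pytest.raises(InsufficientPairs):
            strain_pressure_correlation(tab)

    def test_monotone_transform_invariance(self):
        t, _ = simulate_study(StudyDesign(seed=8), default_effect_profile(),
                              noise_cv=0.1, target_rho=0.5)
        r1 = strain_pressure_correlation(t)
        t2 = t.copy()
        t2["ppp_kpa"] = np.exp(t2.ppp_kpa / 200.0)
        r2 = strain_pressure_correlation(t2)
        assert r1.rho == pytest.approx(r2.rho)

    def test_interpretation_bands(self):
        assert correlation_band(0.2) == "weak"
        assert correlation_band(0.52) == "moderate"
        assert correlation_band(0.74) == "strong"

    def test_imposed_rank_correlation_recovered(self):
        # Monte-Carlo: mean estimated rho near the copula target
        rhos = []
        for i in range(150):
            t, _ = simulate_study(StudyDesign(seed=60_000 + i),
                                  default_effect_profile(),
                                  noise_cv=0.23, target_rho=0.5)
            rhos.append(strain_pressure_correlation(t).rho)
        assert abs(np.mean(rhos) - 0.5) <= 0.08


class TestNormality:
    def test_rejection_rate_near_alpha_under_normality(self):
        rej, n = 0, 800
        for i in range(n):
            x = np.random.default_rng(i).normal(size=5)
            if sps.shapiro(x).pvalue < 0.05:
                rej += 1
        assert 0.02 <= rej / n <= 0.09

    def test_skewed_cells_detected(self):
        hits = 0
        for i in range(40):
            x = np.exp(np.random.default_rng(100 + i).normal(0.0, 1.0, 30))
            if sps.shapiro(x).pvalue < 0.05:
                hits += 1
        assert hits > 32  # > 80 % power

    def test_constant_cell_flagged_degenerate(self):
        rows = [(f"P{i}", "flat", 1, "heel", 5.0, np.nan) for i in range(5)]
        tab = pd.DataFrame(rows, columns=["participant", "condition", "repeat",
                                          "region", "peak_smag_pct", "ppp_kpa"])
        screen, rec = normality_screen(tab)
        assert screen.note.str.contains("degenerate").any()
        assert rec == "nonparametric"


class TestFullStage:
    def test_null_study_rarely_significant(self):
        # identical condition truths: family-wise per region, > 90 % of
        # simulated studies should report no significant region
        profile = default_effect_profile()
        for c in profile.columns:
            profile[c] = profile[profile.columns[0]]
        clean = 0
        n_sim = 60
        for i in range(n_sim):
            t, _ = simulate_study(StudyDesign(seed=80_000 + i), profile,
                                  noise_cv=0.2)
            cc = condition_comparison(t)
            sig_cols = [c for c in cc.columns if c.startswith("sig[")]
            any_sig = cc[sig_cols].eq(True).to_numpy().any() if sig_cols \
                else False
            clean += not any_sig
        assert clean / n_sim > 0.9
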
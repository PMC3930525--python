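"""Rank tests and the decoupling GLM, each against independent oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from kakspipe.decoupling import (
    GLM_TERMS,
    SingularFitError,
    fit_decoupling_glm,
    glm_report,
    mann_whitney,
    partial_r2,
    stratified_kaks_compare,
)
from kakspipe.simulate import simulate_expression_table


# ---------------------------------------------------------------------------
# Exact Mann-Whitney oracle: enumerate all rank assignments

def oracle_u1(x, y):
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def oracle_exact_p(x, y):
    """Two-sided exact p by enumerating every C(n1+n2, n1) assignment
    of the pooled values to the first sample."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = oracle_u1(x, y)
    centre = n1 * (len(pooled) - n1) / 2.0
    dev = abs(u_obs - centre)
    total = extreme = 0
    for idx in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(oracle_u1(xs, ys) - centre) >= dev - 1e-12:
            extreme += 1
    return extreme / total


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        res = mann_whitney([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert res.w == 0.0
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(0.1)

    def test_identical_multisets_give_central_u(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(x, list(x))
        assert res.u1 == pytest.approx(len(x) ** 2 / 2)

    def test_swap_complements_u(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=6), rng.normal(size=9)
        fwd = mann_whitney(x, y)
        rev = mann_whitney(y, x)
        assert fwd.u1 == pytest.approx(rev.u2)
        assert fwd.u1 + fwd.u2 == pytest.approx(len(x) * len(y))
        assert fwd.p_two_sided == pytest.approx(rev.p_two_sided)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 4), (5, 5), (7, 6), (7, 7)])
    def test_exact_p_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(3):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            res = mann_whitney(x, y)
            assert res.method == "exact"
            assert res.u1 == pytest.approx(oracle_u1(x, y))
            assert res.p_two_sided == pytest.approx(oracle_exact_p(x, y), abs=1e-12)

    def test_large_or_tied_samples_use_normal_approximation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        assert mann_whitney(x, y).method == "normal-approximation"
        assert mann_whitney([1, 1, 2], [2, 3, 3]).method == "normal-approximation"


class TestStratifiedComparison:
    def _table(self, ratios, ids=None):
        ids = ids or [f"g{i}" for i in range(len(ratios))]
        return pd.DataFrame({"id_a": ids, "ratio": ratios})

    def test_groups_and_positive_counts(self):
        table = self._table([2.0, 3.0, 0.1, 0.2, 0.3],
                            ids=["h1", "h2", "b1", "b2", "b3"])
        cmp = stratified_kaks_compare(table, {"h1", "h2"})
        assert cmp.focal.n == 2 and cmp.focal.n_positive == 2
        assert cmp.background.n == 3 and cmp.background.n_positive == 0
        assert cmp.test.u1 == pytest.approx(oracle_u1([2.0, 3.0], [0.1, 0.2, 0.3]))

    def test_empty_focal_set(self):
        cmp = stratified_kaks_compare(self._table([0.1, 0.5, 1.2]), set())
        assert cmp.focal is None and cmp.test is None
        assert cmp.background.n == 3

    def test_missing_focal_id_warned_and_skipped(self, caplog):
        table = self._table([0.1, 0.2], ids=["a", "b"])
        with caplog.at_level("WARNING"):
            cmp = stratified_kaks_compare(table, {"a", "ghost"})
        assert "ghost" in caplog.text
        assert cmp.focal.n == 1

    def test_undefined_ratios_excluded(self):
        table = self._table([0.1, np.nan, 0.3])
        cmp = stratified_kaks_compare(table, set())
        assert cmp.background.n == 2

    def test_identical_ratios_give_p_one(self):
        table = self._table([0.5, 0.5, 0.5, 0.5], ids=["h1", "b1", "b2", "b3"])
        cmp = stratified_kaks_compare(table, {"h1"})
        assert cmp.test.p_two_sided == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# GLM

def refit_partial_r2_oracle(records, term, profile="log-biases"):
    """Drop-one-term SSE comparison: (SSE_reduced - SSE_full)/SSE_reduced."""
    import statsmodels.api as sm
    from kakspipe.decoupling import _build_design
    design, y, _ = _build_design(records, profile)
    X_full = sm.add_constant(design, prepend=True)
    sse_full = sm.OLS(y, X_full).fit().ssr
    X_red = sm.add_constant(design.drop(columns=[term]), prepend=True)
    sse_red = sm.OLS(y, X_red).fit().ssr
    return (sse_red - sse_full) / sse_red


class TestDecouplingGlm:
    def test_residual_df_is_n_minus_8(self):
        rec, _ = simulate_expression_table(249, seed=1)
        fit = fit_decoupling_glm(rec)
        assert fit.n == 249
        assert fit.residual_df == 241

    def test_noiseless_construction_recovered_exactly(self):
        rec, _ = simulate_expression_table(200, noise_sd=0.0, seed=2)
        fit = fit_decoupling_glm(rec)
        assert fit.adjusted_r2 == pytest.approx(1.0, abs=1e-9)
        from kakspipe.simulate import DEFAULT_COEFFICIENTS
        for term in GLM_TERMS:
            assert fit.term(term).estimate == pytest.approx(
                DEFAULT_COEFFICIENTS[term], abs=1e-8)

    @pytest.mark.parametrize("beta,n", [(0.230, 761), (0.384, 249)])
    def test_morph_coefficient_recovery(self, beta, n):
        rec, _ = simulate_expression_table(n, {"morph_bias": beta}, seed=42)
        fit = fit_decoupling_glm(rec)
        term = fit.term("morph_bias")
        assert abs(term.estimate - beta) <= 2 * term.se
        assert fit.residual_df == n - 8

    def test_partial_r2_formula_matches_refit_oracle(self):
        for seed in range(10):
            rec, _ = simulate_expression_table(120, seed=seed)
            fit = fit_decoupling_glm(rec)
            for term in GLM_TERMS:
                assert partial_r2(fit, term) == pytest.approx(
                    refit_partial_r2_oracle(rec, term), abs=1e-10), (seed, term)

    def test_partial_r2_arithmetic(self):
        rec, _ = simulate_expression_table(120, seed=3)
        fit = fit_decoupling_glm(rec)
        for t in fit.terms:
            assert t.partial_r2 == pytest.approx(
                t.t_value ** 2 / (t.t_value ** 2 + fit.residual_df))
            assert 0 <= t.partial_r2 < 1

    def test_intercept_has_no_partial_r2(self):
        rec, _ = simulate_expression_table(120, seed=4)
        fit = fit_decoupling_glm(rec)
        with pytest.raises(ValueError):
            partial_r2(fit, "intercept")

    def test_duplicated_covariate_is_singular_fit_error(self):
        rec, _ = simulate_expression_table(120, seed=5)
        rec["morph_bias"] = rec["sex_bias"]
        with pytest.raises(SingularFitError, match="morph"):
            fit_decoupling_glm(rec)

    def test_zero_ratio_rows_excluded_by_default(self):
        rec, _ = simulate_expression_table(120, seed=6)
        rec.loc[rec.index[:5], "ratio"] = 0.0
        fit = fit_decoupling_glm(rec)
        assert fit.n == 115
        assert fit.n_excluded == 5

    def test_zero_ratio_floor_mode_keeps_rows(self):
        rec, _ = simulate_expression_table(120, seed=7)
        rec.loc[rec.index[:5], "ratio"] = 0.0
        fit = fit_decoupling_glm(rec, zero_ratio_floor=True)
        assert fit.n == 120

    def test_length_logging_profile_changes_design(self):
        rec, _ = simulate_expression_table(150, seed=8)
        fit_m = fit_decoupling_glm(rec, "log-biases")
        fit_t = fit_decoupling_glm(rec, "log-lengths")
        # same data, different design: estimates for length terms differ
        assert fit_m.term("alignment_length").estimate != pytest.approx(
            fit_t.term("alignment_length").estimate)
        assert fit_t.transform_profile == "log-lengths"

    def test_null_model_has_near_zero_adjusted_r2(self):
        zero = {name: 0.0 for name in
                ("overall_expression", "alignment_length", "sequence_length",
                 "n_tissues", "sex_bias", "morph_bias", "morph_x_sex")}
        r2s = []
        for seed in range(20):
            rec, _ = simulate_expression_table(200, zero, noise_sd=1.0, seed=seed)
            r2s.append(fit_decoupling_glm(rec).adjusted_r2)
        assert abs(float(np.mean(r2s))) < 0.02

    def test_report_layout(self):
        rec, _ = simulate_expression_table(120, seed=9)
        report = glm_report(fit_decoupling_glm(rec))
        assert list(report.columns) == ["term", "estimate", "se", "partial_r2", "t_value"]
        assert list(report["term"]) == list(GLM_TERMS)


class TestCoefficientCoverage:
    def test_morph_ci_coverage_near_nominal(self):
        """95% CI for the morph-bias coefficient should cover the truth
        in roughly 90-99% of replicates."""
        from scipy import stats as sps
        beta = 0.3
        covered = 0
        n_reps = 60
        for seed in range(n_reps):
            rec, _ = simulate_expression_table(200, {"morph_bias": beta}, seed=seed)
            fit = fit_decoupling_glm(rec)
            term = fit.term("morph_bias")
            tcrit = sps.t.ppf(0.975, fit.residual_df)
            if abs(term.estimate - beta) <= tcrit * term.se:
                covered += 1
        assert 0.90 * n_reps <= covered <= 0.99 * n_reps + 1
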
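import numpy as np
import pandas as pd
import pytest

from distcat.corpus_io import CoarseTag
from distcat.stats_pipeline import (
    LOGIT_VARIANCE,
    RandomTerm,
    RegressionResult,
    TableFilters,
    UndefinedResultError,
    assemble_table,
    error_analysis,
    fit_logistic_mixed,
    forward_select,
    nakagawa_r2,
)

from conftest import simulate_glmm_table


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------


def _toy_frames():
    """Three corpora, three time points, four words with known membership.

    n1 (noun): everywhere, frequency always > 1 -> 9 rows survive.
    v1 (verb): corpora A and B only -> dropped by the all-corpora filter.
    a1 (adj): everywhere, but first occurs at t=2 in corpus C -> dropped
      by the first-half filter.
    f1 (funct): everywhere; frequency 1 at t=0 -> those 3 observations are
      dropped; 6 rows survive unless function words are excluded.
    """
    rows_out, rows_pred = [], []

    def add(corpus, t, word, fine, coarse, freq):
        rows_out.append(
            {
                "corpus_id": corpus,
                "time_index": t,
                "word_id": word,
                "wordform": word,
                "fine_tag": fine,
                "coarse_tag": coarse,
                "metric": "cosine",
                "neighbor_id": "x",
                "predicted_coarse": coarse,
                "hit": 1,
                "n_tied": 1,
                "tie_random": 0,
            }
        )
        rows_pred.append(
            {
                "corpus_id": corpus,
                "time_index": t,
                "word": word,
                "frequency": freq,
                "diversity": freq,
                "log_frequency": np.log(freq),
                "log_diversity": np.log(freq),
                "avg_cond_prob": 0.5,
                "median_ig": 0.1,
            }
        )

    for corpus in "ABC":
        for t in range(3):
            add(corpus, t, "n1", "n", "N", freq=2 + t)
            add(corpus, t, "f1", "det", "FUNCT", freq=1 + t)
    for corpus in "AB":
        for t in range(3):
            add(corpus, t, "v1", "v", "V", freq=3)
    for corpus in "AB":
        for t in range(3):
            add(corpus, t, "a1", "adj", "ADJ", freq=2)
    add("C", 2, "a1", "adj", "ADJ", freq=2)  # late arrival in corpus C
    return pd.DataFrame(rows_out), pd.DataFrame(rows_pred)


class TestAssembleTable:
    def test_hand_enumerated_survivors(self):
        outcomes, predictors = _toy_frames()
        table = assemble_table(outcomes, predictors, TableFilters())
        # n1: 9 rows; f1: 9 - 3 hapax observations = 6 rows
        assert len(table) == 15
        assert set(table["word"]) == {"n1/n", "f1/det"}

    def test_all_corpora_filter(self):
        outcomes, predictors = _toy_frames()
        table = assemble_table(outcomes, predictors, TableFilters())
        assert "v1/v" not in set(table["word"])

    def test_first_half_filter(self):
        outcomes, predictors = _toy_frames()
        table = assemble_table(outcomes, predictors, TableFilters())
        assert "a1/adj" not in set(table["word"])
        relaxed = assemble_table(
            outcomes, predictors, TableFilters(require_first_half=False)
        )
        assert "a1/adj" in set(relaxed["word"])

    def test_per_observation_hapax_filter(self):
        outcomes, predictors = _toy_frames()
        table = assemble_table(outcomes, predictors, TableFilters())
        f1 = table[table["word"] == "f1/det"]
        assert set(f1["time_index"]) == {1, 2}  # the t=0 hapax rows are gone

    def test_function_word_exclusion(self):
        outcomes, predictors = _toy_frames()
        table = assemble_table(
            outcomes, predictors, TableFilters(exclude_function_words=True)
        )
        assert set(table["word"]) == {"n1/n"}

    def test_key_mismatch_raises(self):
        outcomes, predictors = _toy_frames()
        with pytest.raises(KeyError, match="orphan"):
            assemble_table(outcomes, predictors.iloc[:-5], TableFilters())


# ---------------------------------------------------------------------------
# mixed-effects fitting
# ---------------------------------------------------------------------------


class TestFitLogisticMixed:
    def test_parameter_recovery_within_three_se(self):
        """Planted coefficients are recovered by the GLMM estimator."""
        truth = {"log_diversity": 0.6, "avg_cond_prob": -1.5, "time": 0.05}
        table = simulate_glmm_table(seed=2024)
        assert len(table) >= 5000
        res = fit_logistic_mixed(
            table, ["time", "log_diversity", "avg_cond_prob"], nagq=1
        )
        assert res.converged
        for term, b_true in truth.items():
            err = abs(res.beta[term] - b_true)
            assert err < 3 * res.se[term], f"{term}: {res.beta[term]} vs {b_true}"
        assert res.beta["log_diversity"] > 0
        assert res.beta["avg_cond_prob"] < 0
        assert res.marginal_r2 <= res.conditional_r2 <= 1

    def test_degenerate_response_reported_not_raised(self):
        table = simulate_glmm_table(seed=5, n_corpora=3, n_words=10, n_times=3)
        table["hit"] = 1
        res = fit_logistic_mixed(table, ["time"])
        assert not res.converged
        assert "degenerate" in res.message

    def test_fixed_effects_fallback_flagged(self):
        table = simulate_glmm_table(seed=8, n_corpora=4, n_words=25, n_times=4)
        res = fit_logistic_mixed(
            table, ["time", "log_diversity", "avg_cond_prob"], engine="fixed"
        )
        assert res.engine == "fixed_fallback"
        assert res.converged
        assert res.beta["log_diversity"] > 0
        assert res.beta["avg_cond_prob"] < 0
        assert np.isfinite(res.aic)


class TestNakagawaR2:
    @staticmethod
    def _result(beta, random_terms):
        res = RegressionResult(
            formula="hit ~ x", terms=list(beta), beta=dict(beta), converged=True
        )
        res.random_terms = random_terms
        return res

    def test_zero_random_variance_collapses(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"x": rng.normal(size=500)})
        res = self._result(
            {"(Intercept)": 0.1, "x": 0.7},
            [RandomTerm("g", ["(Intercept)"], np.zeros((1, 1)))],
        )
        m, c = nakagawa_r2(res, table)
        assert m == pytest.approx(c)

    def test_zero_fixed_variance_gives_zero_marginal(self):
        table = pd.DataFrame({"x": np.zeros(100)})
        res = self._result(
            {"(Intercept)": 0.5, "x": 1.0},
            [RandomTerm("g", ["(Intercept)"], np.array([[0.4]]))],
        )
        m, c = nakagawa_r2(res, table)
        assert m == pytest.approx(0.0)
        assert c == pytest.approx(0.4 / (0.4 + LOGIT_VARIANCE))

    def test_planted_variances_match_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=4000)
        t = rng.integers(0, 7, size=4000).astype(float)
        table = pd.DataFrame({"x": x, "time": t})
        cov = np.array([[0.5, 0.05], [0.05, 0.02]])  # intercept/slope over time
        res = self._result(
            {"(Intercept)": 0.0, "x": 0.8},
            [RandomTerm("w", ["(Intercept)", "time"], cov)],
        )
        var_f = np.var(0.8 * x)
        z = np.column_stack([np.ones_like(t), t])
        var_r = np.mean(np.einsum("ij,jk,ik->i", z, cov, z))
        m, c = nakagawa_r2(res, table)
        denom = var_f + var_r + LOGIT_VARIANCE
        assert m == pytest.approx(var_f / denom)
        assert c == pytest.approx((var_f + var_r) / denom)

    def test_nonconverged_fit_is_undefined(self):
        res = RegressionResult(formula="f", terms=["(Intercept)"], converged=False)
        with pytest.raises(UndefinedResultError):
            nakagawa_r2(res, pd.DataFrame({"x": [1.0]}))


class TestForwardSelect:
    def test_planted_candidate_selected_first_and_noise_rejected(self):
        table = simulate_glmm_table(seed=77, n_corpora=6, n_words=40, n_times=5)
        rng = np.random.default_rng(99)
        table["noise1"] = rng.normal(size=len(table))
        table["noise2"] = rng.normal(size=len(table))
        report = forward_select(
            table, ["log_diversity", "noise1", "noise2"], baseline_terms=("time",)
        )
        assert report.path, "no candidate was ever selected"
        first = report.path[0]
        assert "log_diversity" in first.beta
        assert "noise1" not in report.final.beta
        assert "noise2" not in report.final.beta
        # single-predictor ranking puts the real effect ahead of the nulls
        assert "log_diversity" in report.single[0].beta

    def test_no_predictive_candidates_stops_at_baseline(self):
        table = simulate_glmm_table(
            seed=31, beta_div=0.0, beta_cp=0.0, n_corpora=5, n_words=30, n_times=5
        )
        rng = np.random.default_rng(13)
        table["noise1"] = rng.normal(size=len(table))
        report = forward_select(table, ["noise1"], baseline_terms=("time",))
        # a pure-noise candidate should not beat the baseline by AIC
        assert report.final.formula == report.baseline.formula
        improvement = report.baseline.aic - report.single[0].aic
        assert improvement <= 2.0

    def test_collinear_duplicate_adds_nothing_after_first(self):
        table = simulate_glmm_table(seed=55, n_corpora=6, n_words=40, n_times=5)
        table["div_copy"] = table["log_diversity"]
        report = forward_select(
            table, ["log_diversity", "div_copy"], baseline_terms=("time",)
        )
        in_final = [
            t for t in ("log_diversity", "div_copy") if t in report.final.beta
        ]
        assert len(in_final) == 1

    def test_overlapping_baseline_raises(self):
        table = simulate_glmm_table(seed=1, n_corpora=3, n_words=10, n_times=3)
        with pytest.raises(ValueError):
            forward_select(table, ["time"], baseline_terms=("time",))


# ---------------------------------------------------------------------------
# error analysis
# ---------------------------------------------------------------------------


def _outcomes_from_counts(counts, cats):
    rows = []
    for i, ci in enumerate(cats):
        for j, cj in enumerate(cats):
            rows += [{"coarse_tag": ci, "predicted_coarse": cj}] * int(counts[i][j])
    return pd.DataFrame(rows)


class TestErrorAnalysis:
    def test_diagonal_table_all_diagonal_positive(self):
        cats = [t.value for t in CoarseTag]
        counts = np.diag([40, 40, 40, 40, 40])
        err = error_analysis(_outcomes_from_counts(counts, cats))
        for c in cats:
            assert err.flags.loc[c, c] == "+"

    def test_independent_table_all_ns(self):
        cats = ["N", "V"]
        counts = [[40, 10], [80, 20]]  # rows proportional -> independence
        err = error_analysis(_outcomes_from_counts(counts, cats), categories=cats)
        assert (err.flags.to_numpy() == "").all()

    def test_residuals_match_direct_chi_square_formula(self):
        # independent oracle: scipy expected counts + the textbook formula
        from scipy.stats import chi2_contingency

        cats = ["N", "V", "ADJ"]
        counts = np.array([[30, 5, 2], [4, 40, 6], [1, 9, 20]], dtype=float)
        err = error_analysis(_outcomes_from_counts(counts, cats), categories=cats)
        expected = chi2_contingency(counts).expected_freq
        n = counts.sum()
        r = counts.sum(axis=1, keepdims=True) / n
        c = counts.sum(axis=0, keepdims=True) / n
        oracle = (counts - expected) / np.sqrt(expected * (1 - r) * (1 - c))
        np.testing.assert_allclose(err.residuals.to_numpy(), oracle, rtol=1e-12)
        np.testing.assert_allclose(err.expected.to_numpy(), expected, rtol=1e-12)

    def test_counts_conserved(self):
        cats = ["N", "V"]
        counts = [[12, 3], [5, 9]]
        err = error_analysis(_outcomes_from_counts(counts, cats), categories=cats)
        assert err.observed.to_numpy().sum() == pytest.approx(
            err.expected.to_numpy().sum()
        )
        np.testing.assert_array_equal(err.observed.to_numpy(), np.array(counts))

    def test_empty_outcomes_raise(self):
        with pytest.raises(ValueError):
            error_analysis(pd.DataFrame({"coarse_tag": [], "predicted_coarse": []}))

    def test_mosaic_rendering_writes_file(self, tmp_path):
        from distcat.stats_pipeline import plot_mosaic

        cats = [t.value for t in CoarseTag]
        counts = np.diag([10, 10, 10, 10, 10]) + 1
        err = error_analysis(_outcomes_from_counts(counts, cats))
        out = tmp_path / "mosaic.png"
        plot_mosaic(err, out)
        assert out.stat().st_size > 0
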
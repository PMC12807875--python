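import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from xiescape.errors import InsufficientDataError
from xiescape.imbalance import (AllelicImbalanceModel, adjust_pvalues,
                                call_silencing, compare_categories,
                                correlate_escape_xist, fit_binomial_glm)
from xiescape.io import validate_sample_sheet


def _design(control_obs, treated_obs, gene="g"):
    """Build (ratios, sheet) from per-replicate (xi, total) pairs."""
    rows, sheet_rows = [], []
    for label, day, obs in (("c", "0", control_obs), ("t", "3", treated_obs)):
        for i, (xi, total) in enumerate(obs):
            sample = f"{label}{i}"
            sheet_rows.append({"sample_id": sample, "dox_days": day,
                               "washout_days": "0", "auxin": "false",
                               "replicate": str(i + 1), "xi_haplotype": "hap1"})
            rows.append((gene, sample, xi, total - xi, total,
                         xi / total if total else np.nan, total > 0))
    ratios = pd.DataFrame(rows, columns=[
        "gene_id", "sample_id", "xi_count", "xa_count", "total", "ratio",
        "defined"])
    sheet = validate_sample_sheet(pd.DataFrame(sheet_rows))
    return ratios, sheet


from oracles import bh_oracle, exact_rank_sum_p, holm_oracle, newton_logistic_mle


class TestBinomialGLM:
    def test_identical_groups_give_null_result(self):
        ratios, sheet = _design([(50, 100), (50, 100)],
                                [(50, 100), (50, 100)])
        out = fit_binomial_glm(ratios, sheet, ("untreated", "dox3d"))
        assert out.beta_treatment.iloc[0] == pytest.approx(0.0)
        assert out.p_value.iloc[0] == pytest.approx(1.0)

    def test_boundary_group_not_estimable(self):
        ratios, sheet = _design([(30, 100), (25, 100)],
                                [(0, 100), (0, 100)])
        out = fit_binomial_glm(ratios, sheet, ("untreated", "dox3d"))
        assert not out.estimable.iloc[0]
        assert np.isnan(out.p_value.iloc[0])

    def test_matches_newton_oracle(self):
        ratios, sheet = _design([(30, 100)], [(10, 100)])
        out = fit_binomial_glm(ratios, sheet, ("untreated", "dox3d")).iloc[0]
        b0, b1, se = newton_logistic_mle([(30, 100, 0), (10, 100, 1)])
        assert out.beta_treatment == pytest.approx(b1, abs=1e-6)
        assert out.std_error == pytest.approx(se, abs=1e-6)
        expected_p = 2 * stats.norm.sf(abs(b1 / se))
        assert out.p_value == pytest.approx(expected_p, abs=1e-6)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        for _ in range(5):
            control = [(int(rng.integers(5, 95)), 100) for _ in range(3)]
            treated = [(int(rng.integers(5, 95)), 100) for _ in range(3)]
            ratios, sheet = _design(control, treated)
            ours = fit_binomial_glm(ratios, sheet,
                                    ("untreated", "dox3d")).iloc[0]
            endog = np.array([[k, n - k] for k, n in control + treated])
            exog = sm.add_constant(np.array([0] * 3 + [1] * 3, dtype=float))
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
            assert ours.beta_treatment == pytest.approx(fit.params[1], abs=1e-6)
            assert ours.std_error == pytest.approx(fit.bse[1], abs=1e-6)

    def test_swapping_conditions_negates_beta(self):
        ratios, sheet = _design([(30, 100), (28, 90)], [(12, 110), (9, 100)])
        fwd = fit_binomial_glm(ratios, sheet, ("untreated", "dox3d")).iloc[0]
        rev = fit_binomial_glm(ratios, sheet, ("dox3d", "untreated")).iloc[0]
        assert fwd.beta_treatment == pytest.approx(-rev.beta_treatment)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_results_summary_mentions_contrast(self):
        ratios, sheet = _design([(30, 100)], [(10, 100)])
        model = AllelicImbalanceModel(ratios, sheet, ("untreated", "dox3d"))
        assert "untreated vs dox3d" in model.fit().summary()


class TestAdjustPvalues:
    def test_holm_textbook_example(self):
        assert adjust_pvalues([0.01, 0.04], "holm") == pytest.approx(
            [0.02, 0.04])

    def test_single_p_is_identity(self):
        for method in ("holm", "benjamini_hochberg"):
            assert adjust_pvalues([0.03], method) == pytest.approx([0.03])

    def test_random_vectors_match_oracles(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            p = rng.uniform(size=rng.integers(1, 40))
            assert adjust_pvalues(p, "holm") == pytest.approx(holm_oracle(p))
            assert adjust_pvalues(p, "benjamini_hochberg") == pytest.approx(
                bh_oracle(p))

    def test_holm_dominated_by_bonferroni(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=25)
        holm = adjust_pvalues(p, "holm")
        assert (holm <= np.minimum(1.0, len(p) * p) + 1e-12).all()

    def test_nan_propagates_and_shrinks_family(self):
        out = adjust_pvalues([0.01, np.nan, 0.04], "holm")
        assert np.isnan(out[1])
        assert out[[0, 2]] == pytest.approx(holm_oracle(np.array([0.01, 0.04])))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "holm")


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                min_size=1, max_size=30))
def test_adjustment_matches_oracles_on_arbitrary_vectors(p):
    """Holm/BH equal the textbook procedures for any valid p-vector."""
    p = np.asarray(p)
    np.testing.assert_allclose(adjust_pvalues(p, "holm"), holm_oracle(p),
                               atol=1e-12)
    np.testing.assert_allclose(adjust_pvalues(p, "benjamini_hochberg"),
                               bh_oracle(p), atol=1e-12)


class TestCallSilencing:
    def _inputs(self, control, treated, p_adj, estimable=True):
        tests = pd.DataFrame({
            "gene_id": ["g"], "condition_control": ["untreated"],
            "condition_treated": ["dox3d"], "p_adjusted": [p_adj],
            "estimable": [estimable]})
        means = pd.DataFrame({
            "gene_id": ["g", "g"],
            "condition_label": ["untreated", "dox3d"],
            "mean_ratio": [control, treated]})
        return tests, means

    def test_strong_significant_reduction_is_silenced(self):
        out = call_silencing(*self._inputs(0.40, 0.15, 0.001))
        assert out.silenced_by_dox.iloc[0]
        assert out.reduction_fraction.iloc[0] == pytest.approx(0.625)

    def test_small_reduction_not_silenced(self):
        out = call_silencing(*self._inputs(0.40, 0.30, 0.001))
        assert not out.silenced_by_dox.iloc[0]

    def test_insignificant_not_silenced(self):
        out = call_silencing(*self._inputs(0.40, 0.10, 0.2))
        assert not out.silenced_by_dox.iloc[0]

    def test_zero_control_mean_is_undefined(self):
        out = call_silencing(*self._inputs(0.0, 0.1, 0.001))
        assert np.isnan(out.reduction_fraction.iloc[0])
        assert not out.silenced_by_dox.iloc[0]


class TestCompareCategories:
    def test_identical_samples_give_p_one(self):
        values = pd.DataFrame({"value": [1, 2, 3, 1, 2, 3],
                               "group": list("aaabbb")})
        out = compare_categories(values, paired=True)
        assert out.p_value.iloc[0] == pytest.approx(1.0)

    def test_small_n_matches_exact_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(size=4)
            b = rng.normal(size=3)
            values = pd.DataFrame({"value": np.concatenate([a, b]),
                                   "group": ["a"] * 4 + ["b"] * 3})
            out = compare_categories(values)
            assert out.p_value.iloc[0] == pytest.approx(exact_rank_sum_p(a, b))

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(4)
        detected = 0
        n_sims = 40
        for _ in range(n_sims):
            a = rng.normal(0, 1, 50)
            b = rng.normal(1, 1, 50)
            values = pd.DataFrame({"value": np.concatenate([a, b]),
                                   "group": ["a"] * 50 + ["b"] * 50})
            detected += compare_categories(values).p_value.iloc[0] < 0.05
        assert detected / n_sims >= 0.95

    def test_paired_unequal_lengths_rejected(self):
        values = pd.DataFrame({"value": [1, 2, 3], "group": ["a", "a", "b"]})
        with pytest.raises(ValueError):
            compare_categories(values, paired=True)

    def test_single_group_rejected(self):
        values = pd.DataFrame({"value": [1, 2], "group": ["a", "a"]})
        with pytest.raises(InsufficientDataError):
            compare_categories(values)


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        out = correlate_escape_xist(-x, x)
        assert out.r == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlate_escape_xist(np.ones(5), np.arange(5.0))

    def test_matches_closed_form(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        out = correlate_escape_xist(y, x)
        closed = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert out.r == pytest.approx(closed, abs=1e-12)
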
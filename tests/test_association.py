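"""Descriptive tests, crude ORs, genotype codings, IRLS logistic fits and
the permutation-corrected p-value."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lepmel.association import (
    Contingency2x2,
    adjusted_genotype_fit,
    build_design,
    code_genotype,
    crude_or,
    fit_logistic,
    pearson_chi2,
    permutation_p_association,
    two_sample_t,
    wald_effect,
)


class TestPearsonChi2:
    def test_published_lifestyle_margins(self):
        chi2, df, p = pearson_chi2([[144, 964], [171, 1045]])
        assert chi2 == pytest.approx(0.56, abs=0.005)
        assert p == pytest.approx(0.453, abs=0.001)
        chi2, _, _ = pearson_chi2([[204, 902], [252, 960]])
        assert chi2 == pytest.approx(2.02, abs=0.005)

    def test_identical_rows_give_zero(self):
        chi2, df, p = pearson_chi2([[30, 70], [60, 140]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_transpose_invariance(self):
        t = [[12, 34, 5], [7, 8, 20]]
        assert pearson_chi2(t)[0] == pytest.approx(
            pearson_chi2(np.transpose(t))[0])

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [5, 10]])


class TestTwoSampleT:
    def test_identical_means(self):
        t, _ = two_sample_t([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_unit_shift_magnitude(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 1000)
        b = rng.normal(1, 1, 1000)
        t, p = two_sample_t(a, b)
        assert abs(abs(t) - 22.4) < 3  # |t| ~ 1/sqrt(2/1000)

    def test_group_of_one_errors(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


class TestCrudeOr:
    def test_published_grs_tables(self):
        e = crude_or(Contingency2x2(350, 195, 300, 233))
        assert round(e.or_point, 2) == 1.39
        assert round(e.ci_low, 2) == 1.09 and round(e.ci_high, 2) == 1.78
        assert round(crude_or(Contingency2x2(350, 772, 300, 928)).or_point,
                     2) == 1.40
        assert round(crude_or(Contingency2x2(360, 195, 324, 233)).or_point,
                     2) == 1.33

    def test_uniform_cells_give_unity(self):
        e = crude_or(Contingency2x2(40, 40, 40, 40))
        assert e.or_point == pytest.approx(1.0)

    @given(st.integers(1, 500), st.integers(1, 500),
           st.integers(1, 500), st.integers(1, 500))
    @settings(max_examples=50, deadline=None)
    def test_exposure_relabeling_inverts(self, a, b, c, d):
        e1 = crude_or(Contingency2x2(a, b, c, d))
        e2 = crude_or(Contingency2x2(b, a, d, c))
        assert e2.or_point == pytest.approx(1 / e1.or_point)
        # simultaneous row and column swap leaves the OR unchanged
        e3 = crude_or(Contingency2x2(d, c, b, a))
        assert e3.or_point == pytest.approx(e1.or_point)

    def test_zero_cell_policy(self):
        with pytest.raises(ValueError):
            crude_or(Contingency2x2(0, 10, 10, 10))
        e = crude_or(Contingency2x2(0, 10, 10, 10), zero_cell_correction=True)
        assert e.or_point > 0


class TestCodeGenotype:
    @pytest.mark.parametrize("dosage,model,expected", [
        (1, "dominant", {"dominant": 1.0}),
        (1, "recessive", {"recessive": 0.0}),
        (2, "genotypic", {"het": 0.0, "hom": 1.0}),
        (2, "additive", {"additive": 2.0}),
        (0, "dominant", {"dominant": 0.0}),
    ])
    def test_definitions(self, dosage, model, expected):
        row = code_genotype([dosage], model).iloc[0].to_dict()
        assert row == expected

    def test_missing_propagates(self):
        assert code_genotype([np.nan], "dominant").isna().all().all()


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        X = np.ones((100, 1))
        y = np.repeat([0.0, 1.0], 50)
        fit = fit_logistic(X, y, ["intercept"])
        assert fit.params[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.converged

    def test_saturated_2x2_equals_crude_or(self):
        # cells (a=350 exposed case, b=772, c=300, d=928)
        y = np.concatenate([np.ones(350 + 772), np.zeros(300 + 928)])
        x = np.concatenate([np.ones(350), np.zeros(772),
                            np.ones(300), np.zeros(928)])
        fit = fit_logistic(np.column_stack([np.ones_like(x), x]), y,
                           ["intercept", "exposed"])
        assert np.exp(fit.coef("exposed")) == pytest.approx(
            crude_or(Contingency2x2(350, 772, 300, 928)).or_point, abs=1e-8)

    def test_matches_statsmodels(self, small_cohort):
        sm = pytest.importorskip("statsmodels.api")
        extra = pd.DataFrame(
            {"additive": small_cohort["rs17782313"].to_numpy()})
        X, y, terms, _ = build_design(small_cohort, extra=extra)
        fit = fit_logistic(X, y, terms)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.bse, ref.bse, atol=1e-6)

    def test_separation_flagged(self):
        y = np.repeat([0.0, 1.0], 20)
        x = y.copy()  # perfect predictor
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_logistic(np.column_stack([np.ones_like(x), x]), y,
                               ["intercept", "x"])
        assert fit.separation


class TestPermutationP:
    def _null_cohort(self, rng, n=300):
        return pd.DataFrame({
            "status": rng.integers(0, 2, n).astype(np.int8),
            "sex": rng.choice(["boy", "girl"], n),
            "income": rng.choice(["<5000", "5000-9999", ">=10000"], n),
        })

    def test_add_one_lower_bound(self):
        rng = np.random.default_rng(0)
        coh = self._null_cohort(rng)
        dos = rng.choice([0.0, 1.0, 2.0], len(coh), p=[0.49, 0.42, 0.09])
        p = permutation_p_association(coh, dos, "additive", "additive",
                                      B=99, seed=1,
                                      covariates=["sex", "income"])
        assert p >= 1 / 100

    def test_strong_effect_reaches_floor(self):
        """A simulated OR-2 effect at n=2000/2000 beats every permutation."""
        rng = np.random.default_rng(3)
        n = 4000
        dos = rng.choice([0.0, 1.0, 2.0], n, p=[0.49, 0.42, 0.09])
        logit = -0.35 + np.log(2) * dos
        status = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(np.int8)
        coh = pd.DataFrame({
            "status": status,
            "sex": rng.choice(["boy", "girl"], n),
            "income": rng.choice(["<5000", "5000-9999", ">=10000"], n)})
        p = permutation_p_association(coh, dos, "additive", "additive",
                                      B=199, seed=2,
                                      covariates=["sex", "income"])
        assert p == pytest.approx(1 / 200)


def test_adjusted_fit_recovers_simulated_effect(small_cohort, small_config):
    """The adjusted additive-model OR for the strongest simulated variant
    lands near its configured value (log-OR within 3 SE)."""
    spec = small_config.variants[0]
    fit, terms = adjusted_genotype_fit(
        small_cohort, small_cohort[spec.id].to_numpy(), "additive")
    b, se = fit.coef("additive"), fit.se("additive")
    assert abs(b - spec.beta) < 3 * se
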
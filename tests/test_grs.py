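"""Risk-allele orientation, score construction, quartile snapping,
association contrasts and stratified heterogeneity."""

import numpy as np
import pandas as pd
import pytest

from lepmel.datamodel import VariantInfo
from lepmel.grs import (
    GrsWeights,
    categorize,
    cochran_q,
    compute_grs,
    grs_association,
    heterogeneity_z,
    orient_to_risk,
    risk_dosage_frame,
    stratified_grs,
)
from lepmel.reference_data import GRS_BETAS, GRS_CATEGORY_COUNTS, GRS_RISK_ALLELES

PUBLISHED_WEIGHTS = GrsWeights(
    variant_ids=list(GRS_BETAS), risk_alleles=dict(GRS_RISK_ALLELES),
    betas=dict(GRS_BETAS))


class TestOrientToRisk:
    def test_alt_is_risk_identity(self):
        v = VariantInfo("x", "T", "C", risk_allele="C")
        assert orient_to_risk([2.0], v)[0] == 2.0

    def test_ref_is_risk_complement(self):
        v = VariantInfo("x", "T", "C", risk_allele="T")
        assert orient_to_risk([2.0], v)[0] == 0.0
        assert orient_to_risk([1.0], v)[0] == 1.0

    def test_missing_propagates(self):
        v = VariantInfo("x", "T", "C", risk_allele="C")
        assert np.isnan(orient_to_risk([np.nan], v)[0])


class TestComputeGrs:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=list(GRS_BETAS))

    def test_one_risk_allele_each(self):
        out = compute_grs(self._frame([[1, 1, 1, 1]]), PUBLISHED_WEIGHTS)
        assert out["unweighted"].iloc[0] == 4
        assert out["weighted"].iloc[0] == pytest.approx(0.639)

    def test_zero_and_double(self):
        out = compute_grs(self._frame([[0, 0, 0, 0], [2, 2, 2, 2]]),
                          PUBLISHED_WEIGHTS)
        assert out["unweighted"].tolist() == [0, 8]
        assert out["weighted"].iloc[1] == pytest.approx(1.278)

    def test_incomplete_profile_flagged(self):
        out = compute_grs(self._frame([[1, np.nan, 1, 1]]), PUBLISHED_WEIGHTS)
        assert not out["complete"].iloc[0]
        assert np.isnan(out["unweighted"].iloc[0])

    def test_absent_component_errors(self):
        with pytest.raises(ValueError):
            compute_grs(pd.DataFrame({"other": [1.0]}), PUBLISHED_WEIGHTS)

    def test_unit_betas_collapse_to_unweighted(self):
        w = GrsWeights(list(GRS_BETAS), dict(GRS_RISK_ALLELES),
                       {v: 1.0 for v in GRS_BETAS})
        rng = np.random.default_rng(0)
        frame = self._frame(rng.integers(0, 3, size=(50, 4)))
        out = compute_grs(frame, w)
        np.testing.assert_array_equal(out["unweighted"], out["weighted"])


class TestCategorize:
    def test_published_style_integer_snapping(self):
        """A score distribution with the published category shares yields
        low={0}, medium={1,2}, high={3..6}."""
        counts = GRS_CATEGORY_COUNTS["unweighted"]
        n_low = sum(counts["low"])        # 428 zeros
        n_med = sum(counts["medium"])     # 1272 in {1,2}
        n_high = sum(counts["high"])      # 650 in {3..6}
        scores = np.concatenate([
            np.zeros(n_low),
            np.repeat([1, 2], [n_med // 2, n_med - n_med // 2]),
            np.repeat([3, 4, 5, 6], [n_high - 190, 120, 50, 20]),
        ])
        cats, cuts = categorize(scores)
        assert cuts == {"low_max": 0.0, "medium_max": 2.0}
        df = pd.DataFrame({"s": scores, "c": cats})
        assert set(df.loc[df.c == "low", "s"]) == {0}
        assert set(df.loc[df.c == "medium", "s"]) == {1, 2}
        assert set(df.loc[df.c == "high", "s"]) == {3, 4, 5, 6}

    def test_constant_scores_error(self):
        with pytest.raises(ValueError):
            categorize(np.ones(100))

    def test_explicit_cutpoints_passthrough(self):
        cats, cuts = categorize(np.array([0.0, 0.2, 0.5, 0.9]),
                                explicit_cutpoints=(0.0, 0.485))
        assert cats.tolist() == ["low", "medium", "high", "high"]
        assert cuts == {"low_max": 0.0, "medium_max": 0.485}

    def test_missing_scores_uncategorized(self):
        cats, _ = categorize(np.array([0, 0, 1, 1, 2, 2, 3, 3, np.nan]))
        assert pd.isna(cats.iloc[-1])


class TestHeterogeneity:
    def test_identical_strata_z_zero(self):
        z, p = heterogeneity_z(0.3, 0.1, 0.3, 0.1)
        assert z == 0.0 and p == 1.0

    def test_closed_form(self):
        z, _ = heterogeneity_z(np.log(2), 0.1, 0.0, 0.1)
        assert z == pytest.approx(np.log(2) / (0.1 * np.sqrt(2)), abs=1e-6)
        assert z == pytest.approx(4.90, abs=0.01)

    def test_cochran_q_homogeneous_zero(self):
        q, df, p = cochran_q([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == 2


@pytest.fixture(scope="module")
def scored_cohort():
    from lepmel.simulate import study_like_config, simulate_cohort
    cfg = study_like_config(n_cases=500, n_controls=550, seed=31)
    cohort, _ = simulate_cohort(cfg, n_pool=15000)
    variants = [s.to_variant_info() for s in cfg.variants[:4]]
    risk = risk_dosage_frame(cohort, variants)
    profiles = compute_grs(risk, PUBLISHED_WEIGHTS)
    return cohort, profiles


def test_grs_orientation_invariance(scored_cohort):
    """Flipping a variant's REF/ALT labels (dosage -> 2-dosage, risk allele
    to the other strand) leaves the GRS unchanged."""
    cohort, profiles = scored_cohort
    flipped = cohort.copy()
    flipped["rs17782313"] = 2 - flipped["rs17782313"]
    variants = [
        VariantInfo("rs17782313", "C", "T", risk_allele="C"),  # now REF=risk
        VariantInfo("rs12970134", "G", "A", risk_allele="A"),
        VariantInfo("rs1137101", "G", "A", risk_allele="A"),
        VariantInfo("rs6713532", "C", "T", risk_allele="T"),
    ]
    risk = risk_dosage_frame(flipped, variants)
    out = compute_grs(risk, PUBLISHED_WEIGHTS)
    pd.testing.assert_series_equal(out["unweighted"],
                                   scored_cohort[1]["unweighted"])


def test_cases_carry_higher_mean_grs(scored_cohort):
    """All-positive betas imply cases average a higher GRS than controls."""
    cohort, profiles = scored_cohort
    mean_case = profiles.loc[cohort["status"] == 1, "unweighted"].mean()
    mean_ctrl = profiles.loc[cohort["status"] == 0, "unweighted"].mean()
    assert mean_case > mean_ctrl


def test_grs_association_contrasts(scored_cohort):
    cohort, profiles = scored_cohort
    cats, _ = categorize(profiles["unweighted"])
    table = grs_association(cohort, profiles["unweighted"], cats)
    assert set(table["contrast"]) == {
        "medium vs low", "high vs low", "high vs low/medium",
        "per 1 score increment"}
    assert (table["ci_low"] <= table["odds_ratio"]).all()
    assert (table["odds_ratio"] <= table["ci_high"]).all()
    assert table["p_trend"].nunique() == 1


def test_stratified_grs_heterogeneity(scored_cohort):
    cohort, profiles = scored_cohort
    cats, _ = categorize(profiles["unweighted"])
    out = stratified_grs(cohort, profiles["unweighted"], cats, "sex")
    fitted = out[~out["skipped"]]
    assert len(fitted) == 2
    assert np.isnan(fitted["het_z_vs_first"].iloc[0])
    assert 0 <= fitted["het_p_vs_first"].iloc[1] <= 1
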
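"""GLM trait association, effect sizes and FDR control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from traitconn import (
    GLMDesign,
    SyntheticCohortConfig,
    bh_fdr,
    combined_trait_score,
    design_matrix,
    fit_glm,
    generate_fa,
    generate_phenotypes,
    partial_eta_squared,
    run_regional_association,
)
from oracles import brute_bh


@pytest.fixture(scope="module")
def pheno():
    return generate_phenotypes(SyntheticCohortConfig(n_subjects=127, seed=42))


class TestDesigns:
    def test_design_columns(self):
        assert GLMDesign(design_id=1).predictors == (
            "intercept", "assq", "srs", "age", "gender")
        assert GLMDesign(design_id=2).predictors == (
            "intercept", "assq", "srs", "age", "gender", "verbal_iq")

    def test_contrast_selects_trait_terms(self):
        c = GLMDesign(design_id=1).contrast()
        assert c.shape == (2, 5)
        assert c[0, 1] == 1 and c[1, 2] == 1 and c.sum() == 2

    def test_combined_score_design_is_single_df(self):
        d = GLMDesign(design_id=1, combined_score=True)
        assert d.contrast().shape[0] == 1
        assert "trait_combined" in d.predictors

    def test_gender_coded_female_zero_male_one(self, pheno):
        x = design_matrix(pheno, GLMDesign())
        col = x[:, GLMDesign().predictors.index("gender")]
        assert set(np.unique(col)) <= {0.0, 1.0}
        assert np.array_equal(col == 1.0, (pheno["gender"] == "male").to_numpy())


class TestFitGlm:
    def test_exact_linear_response_recovered(self, pheno):
        y = 3.0 - 0.25 * pheno["assq"].to_numpy(dtype=float)
        res = fit_glm(y, pheno, GLMDesign(design_id=1))
        assert res.slopes["assq"].b == pytest.approx(-0.25, abs=1e-10)
        assert res.partial_eta_sq == pytest.approx(1.0, abs=1e-6)

    def test_rank_deficient_design_raises(self, pheno):
        dup = pheno.copy()
        dup["verbal_iq"] = dup["assq"]  # collinear with the trait term
        with pytest.raises(ValueError, match="rank deficient"):
            fit_glm(np.ones(len(dup)), dup, GLMDesign(design_id=2))

    def test_missing_values_rejected(self, pheno):
        y = np.ones(len(pheno))
        y[3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_glm(y, pheno, GLMDesign())

    def test_vectorized_family_matches_statsmodels_fit(self, pheno):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(len(pheno), 5))
        y[:, 2] += 0.2 * pheno["assq"].to_numpy(dtype=float)
        table = run_regional_association(y, pheno, GLMDesign(design_id=2))
        for j in range(5):
            ref = fit_glm(y[:, j], pheno, GLMDesign(design_id=2))
            row = table.iloc[j]
            assert row["f"] == pytest.approx(ref.f_stat, rel=1e-8)
            assert row["p"] == pytest.approx(ref.p_value, rel=1e-8)
            assert row["partial_eta_sq"] == pytest.approx(ref.partial_eta_sq, rel=1e-8)
            for term in ("assq", "srs", "age", "gender", "verbal_iq"):
                assert row[f"b_{term}"] == pytest.approx(ref.slopes[term].b, rel=1e-8)
                assert row[f"p_{term}"] == pytest.approx(ref.slopes[term].p, rel=1e-8)


class TestPartialEtaSquared:
    def test_zero_f_gives_zero(self):
        assert partial_eta_squared(0.0, 1, 100) == 0.0

    def test_closed_form_example(self):
        assert partial_eta_squared(25, 1, 100) == pytest.approx(0.2)

    def test_infinite_f_limits_to_one(self):
        assert partial_eta_squared(np.inf, 1, 100) == 1.0
        assert partial_eta_squared(1e12, 2, 50) == pytest.approx(1.0, abs=1e-9)

    def test_equals_sums_of_squares_definition_on_random_fits(self, pheno):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        design = GLMDesign(design_id=1)
        x = design_matrix(pheno, design)
        for _ in range(20):
            y = rng.normal(size=len(pheno)) + 0.1 * x[:, 1]
            fit = sm.OLS(y, x).fit()
            for j in (1, 2, 3):
                c = np.zeros(x.shape[1])
                c[j] = 1
                ss_error = fit.ssr
                # SS of a single-df contrast
                ss_effect = float(
                    (c @ fit.params) ** 2 / (c @ np.linalg.inv(x.T @ x) @ c)
                )
                f = float(fit.tvalues[j] ** 2)
                assert partial_eta_squared(f, 1, int(fit.df_resid)) == pytest.approx(
                    ss_effect / (ss_effect + ss_error)
                )

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            partial_eta_squared(-1.0, 1, 10)
        with pytest.raises(ValueError):
            partial_eta_squared(1.0, 0, 10)


class TestBhFdr:
    def test_all_small_pvalues_rejected(self):
        assert bh_fdr(np.full(10, 0.01), alpha=0.05).all()

    def test_single_large_pvalue_not_rejected(self):
        assert not bh_fdr([0.06], alpha=0.05).any()

    def test_step_up_worked_example(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216]
        flags = bh_fdr(p, alpha=0.05)
        # brute-force evaluation: k* = 2 (0.008 <= 2/10 * 0.05; for k >= 3
        # every sorted p exceeds k/10 * 0.05), so exactly the two smallest
        # p-values are rejected
        assert np.array_equal(flags, brute_bh(np.asarray(p), 0.05))
        assert flags[:2].sum() == 2 and flags[2:].sum() == 0

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            m = rng.integers(1, 200)
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            assert np.array_equal(bh_fdr(p, 0.05), brute_bh(p, 0.05))

    def test_matches_statsmodels_multipletests(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.uniform(size=149)
            ours = bh_fdr(p, 0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(ours, ref)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestRegionalAssociation:
    def test_null_contrast_pvalues_uniform(self, pheno):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(len(pheno), 2000))
        table = run_regional_association(y, pheno, GLMDesign(design_id=1))
        ks = stats.kstest(table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_permuting_subjects_consistently_leaves_results_unchanged(self, pheno):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(len(pheno), 8))
        base = run_regional_association(y, pheno, GLMDesign())
        perm = rng.permutation(len(pheno))
        shuffled = run_regional_association(
            y[perm], pheno.iloc[perm].reset_index(drop=True), GLMDesign()
        )
        pd.testing.assert_frame_equal(base, shuffled, atol=1e-10, rtol=1e-8)

    def test_injected_fa_effect_detected_with_negative_sign(self):
        cfg = SyntheticCohortConfig(
            n_subjects=127, n_regions=30, seed=6,
            effect_sizes={"hub_coupling": 0.0, "local_efficiency": 0.0, "fa": -0.4},
        )
        ph = generate_phenotypes(cfg)
        fa = generate_fa(cfg, ph)
        table = run_regional_association(fa, ph, GLMDesign(design_id=1))
        hits = table[table["fdr_significant"]].index
        assert set(cfg.fa_effect_indices) <= set(hits)

    def test_trait_slopes_unbiased_over_replicates(self):
        # parameter recovery on the FA family: standardized slope -0.4
        biases = []
        for rep in range(60):
            cfg = SyntheticCohortConfig(
                n_subjects=127, n_regions=12, seed=700 + rep,
                effect_sizes={"hub_coupling": 0.0, "local_efficiency": 0.0, "fa": -0.4},
            )
            ph = generate_phenotypes(cfg)
            fa = generate_fa(cfg, ph)
            trait = combined_trait_score(ph)
            region = cfg.fa_effect_indices[0]
            slope = np.polyfit(trait, stats.zscore(fa.iloc[:, region]), 1)[0]
            biases.append(slope - (-0.4))
        assert abs(np.mean(biases)) < 0.04  # < 10% of the true slope
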
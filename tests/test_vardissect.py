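"""Variance dissection: imputation, per-term attribution, pooling."""

import numpy as np
import pandas as pd
import pytest

from placeboprot.linmod import design_matrix, ols
from placeboprot.synth import plant_variance_response
from placeboprot.vardissect import (
    VarianceComposition,
    dissect_variance,
    fit_variance_model,
    impute_missing,
    significant_factor_proteins,
    summarize_imputations,
)


@pytest.fixture(scope="module")
def factors():
    rng = np.random.default_rng(0)
    n = 90
    subjects = [f"S{i:03d}" for i in range(n)]
    das = pd.Series(rng.standard_normal(n), index=subjects)
    arm = pd.Series(["placebo"] * 60 + ["control"] * 30, index=subjects)
    sex = pd.Series((["f", "m"] * 45), index=subjects)
    return subjects, das, arm, sex


class TestImputation:
    def test_complete_table_returned_unchanged(self, factors):
        subjects, das, arm, sex = factors
        fc = pd.DataFrame(np.random.default_rng(1).standard_normal((4, 90)),
                          columns=subjects)
        for comp in impute_missing(fc, das, arm, sex, m=5):
            pd.testing.assert_frame_equal(comp, fc)

    def test_imputed_values_come_from_observed_donors(self, factors):
        subjects, das, arm, sex = factors
        rng = np.random.default_rng(2)
        fc = pd.DataFrame(rng.standard_normal((6, 90)), columns=subjects)
        mask = rng.random((6, 90)) < 0.05
        fc_missing = fc.mask(mask)
        for comp in impute_missing(fc_missing, das, arm, sex, m=3, seed=4):
            assert comp.notna().all().all()
            for i in range(6):
                observed = set(fc_missing.iloc[i].dropna())
                imputed = set(comp.iloc[i][mask[i]])
                assert imputed <= observed  # PMM: donors are observed values

    def test_mask_and_recover_rmse_close_to_regression_oracle(self, factors):
        """On MCAR-masked data generated from the linear model itself, the
        PMM imputation error stays within 1.5× the oracle regression RMSE."""
        subjects, das, arm, sex = factors
        rng = np.random.default_rng(3)
        X = design_matrix([("das",), ("grp",), ("sex",)], {
            "das": das.to_numpy(),
            "grp": np.where(arm == "placebo", 0.5, -0.5),
            "sex": np.where(sex == "f", 0.5, -0.5),
        })
        beta = np.array([0.1, 0.8, 0.5, 0.3])
        truth = np.vstack([X @ beta + rng.standard_normal(90) * 0.4
                           for _ in range(20)])
        mask = rng.random(truth.shape) < 0.05
        fc = pd.DataFrame(truth, columns=subjects).mask(mask)
        completions = impute_missing(fc, das, arm, sex, m=5, seed=5)
        errs, oracle_errs = [], []
        for i in range(truth.shape[0]):
            obs = ~mask[i]
            fit_beta = ols(X[obs], truth[i][obs]).beta
            for j in np.where(mask[i])[0]:
                imputed = np.mean([c.iloc[i, j] for c in completions])
                errs.append(imputed - truth[i, j])
                oracle_errs.append(X[j] @ fit_beta - truth[i, j])
        rmse = np.sqrt(np.mean(np.square(errs)))
        oracle = np.sqrt(np.mean(np.square(oracle_errs)))
        assert rmse <= 1.5 * oracle

    def test_determinism_under_seed(self, factors):
        subjects, das, arm, sex = factors
        rng = np.random.default_rng(6)
        fc = pd.DataFrame(rng.standard_normal((3, 90)),
                          columns=subjects).mask(rng.random((3, 90)) < 0.04)
        a = impute_missing(fc, das, arm, sex, m=2, seed=7)
        b = impute_missing(fc, das, arm, sex, m=2, seed=7)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)


class TestVarianceModel:
    def test_exact_das_response_gives_full_das_fraction(self, factors):
        _, das, arm, sex = factors
        comp = fit_variance_model(das.to_numpy(), das.to_numpy(),
                                  arm.to_numpy(), sex.to_numpy())
        assert comp.fractions["DAS"] == pytest.approx(1.0, abs=1e-6)
        assert comp.r2 == pytest.approx(1.0, abs=1e-9)
        assert sum(v for k, v in comp.fractions.items() if k != "DAS") < 1e-6

    def test_null_r2_matches_theory(self, factors):
        """Pure-noise response: mean model R² ≈ 7/(n−1)."""
        _, das, arm, sex = factors
        rng = np.random.default_rng(8)
        r2s = [
            fit_variance_model(rng.standard_normal(90), das.to_numpy(),
                               arm.to_numpy(), sex.to_numpy()).r2
            for _ in range(400)
        ]
        assert np.mean(r2s) == pytest.approx(7 / 89, abs=0.012)

    def test_planted_composition_recovered(self, factors):
        _, das, arm, sex = factors
        grp_fracs, inter_fracs = [], []
        for seed in range(50):
            y = plant_variance_response(
                das.to_numpy(), arm.to_numpy(), sex.to_numpy(),
                {("grp",): 0.5, ("das", "grp"): 0.2}, seed=seed)
            comp = fit_variance_model(y, das.to_numpy(), arm.to_numpy(),
                                      sex.to_numpy())
            grp_fracs.append(comp.fractions["grp"])
            inter_fracs.append(comp.fractions["DASxgrp"])
        assert np.median(grp_fracs) == pytest.approx(0.5, abs=0.10)
        assert np.median(inter_fracs) == pytest.approx(0.2, abs=0.10)

    def test_fraction_sum_equals_r2(self, factors):
        _, das, arm, sex = factors
        y = plant_variance_response(das.to_numpy(), arm.to_numpy(),
                                    sex.to_numpy(), {("das",): 0.3}, seed=1)
        comp = fit_variance_model(y, das.to_numpy(), arm.to_numpy(),
                                  sex.to_numpy())
        assert sum(comp.fractions.values()) == pytest.approx(comp.r2, abs=1e-9)
        assert all(v >= 0 for v in comp.fractions.values())

    def test_fractions_invariant_to_response_rescaling(self, factors):
        _, das, arm, sex = factors
        y = plant_variance_response(das.to_numpy(), arm.to_numpy(),
                                    sex.to_numpy(), {("grp",): 0.4}, seed=2)
        a = fit_variance_model(y, das.to_numpy(), arm.to_numpy(), sex.to_numpy())
        b = fit_variance_model(7.3 * y, das.to_numpy(), arm.to_numpy(),
                               sex.to_numpy())
        for k in a.fractions:
            assert a.fractions[k] == pytest.approx(b.fractions[k], abs=1e-9)

    def test_too_few_subjects_rejected(self):
        das = np.arange(10.0)
        arm = np.array(["placebo", "control"] * 5)
        sex = np.array(["f", "m"] * 5)
        with pytest.raises(ValueError):
            fit_variance_model(np.random.default_rng(0).standard_normal(10),
                               das, arm, sex)


class TestPooling:
    @staticmethod
    def _comp(frac_das, r2=0.5):
        fr = {l: 0.0 for l in
              ("DAS", "grp", "sex", "DASxgrp", "DASxsex", "grpxsex", "3way")}
        fr["DAS"] = frac_das
        return VarianceComposition("P", fr, r2, {l: 0.5 for l in fr}, 0)

    def test_identical_compositions_identity(self):
        pooled = summarize_imputations([self._comp(0.3)] * 5)
        assert pooled.fractions["DAS"] == 0.3
        assert pooled.n_imputations == 5

    def test_median_robust_to_one_aberrant(self):
        comps = [self._comp(0.3)] * 4 + [self._comp(0.99, r2=0.99)]
        pooled = summarize_imputations(comps)
        assert pooled.fractions["DAS"] == 0.3

    def test_equals_brute_force_median(self):
        comps = [self._comp(f) for f in (0.1, 0.5, 0.2, 0.4, 0.3)]
        pooled = summarize_imputations(comps)
        assert pooled.fractions["DAS"] == np.median([0.1, 0.5, 0.2, 0.4, 0.3])


class TestSignificantFactorMap:
    def test_planted_group_protein_maps_to_group(self, factors):
        subjects, das, arm, sex = factors
        rng = np.random.default_rng(9)
        y_grp = plant_variance_response(das.to_numpy(), arm.to_numpy(),
                                        sex.to_numpy(), {("grp",): 0.5}, seed=3)
        fc = pd.DataFrame([y_grp, rng.standard_normal(90)],
                          index=["grp_protein", "noise_protein"],
                          columns=subjects)
        comp = dissect_variance(fc, das, arm, sex, m=2, seed=1)
        sig = significant_factor_proteins(comp, 0.05)
        assert "grp" in sig.get("grp_protein", [])

    def test_alpha_zero_empty(self, factors):
        subjects, das, arm, sex = factors
        fc = pd.DataFrame(np.random.default_rng(10).standard_normal((2, 90)),
                          columns=subjects)
        comp = dissect_variance(fc, das, arm, sex, m=1, seed=1)
        assert significant_factor_proteins(comp, 0.0) == {}
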
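"""HWE tests, regression fits, sign test, Bonferroni, interactions, conversions."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gpscore import (
    ModelSpec,
    PhenotypeTable,
    bmi_to_weight_delta,
    bonferroni_threshold,
    directional_consistency_test,
    fit_linear,
    fit_logistic,
    hwe_chi2_test,
    interaction_test,
    variance_explained,
)
from gpscore.assoc import AssociationError, BASIC_ADJUSTMENT


class TestHwe:
    def test_exact_proportions_give_zero_statistic(self):
        chi2, p = hwe_chi2_test(250, 500, 250)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_arithmetic_excess_homozygosity(self):
        # freq 0.5 -> expected (250, 500, 250); chi2 = 10 + 20 + 10 = 40
        chi2, p = hwe_chi2_test(300, 400, 300)
        assert chi2 == pytest.approx(40.0)
        assert p == pytest.approx(2.54e-10, rel=0.01)

    def test_monomorphic_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            chi2, p = hwe_chi2_test(0, 0, 100)
        assert (chi2, p) == (0.0, 1.0)

    def test_empty_counts_error(self):
        with pytest.raises(AssociationError):
            hwe_chi2_test(0, 0, 0)

    def test_type_i_error_near_nominal(self):
        """2000 HWE draws (n = 1000, freq 0.3): rejection rate in [3.5%, 6.5%]."""
        rng = np.random.default_rng(12345)
        f = 0.3
        probs = [f**2, 2 * f * (1 - f), (1 - f) ** 2]
        counts = rng.multinomial(1000, probs, size=2000)
        rejections = sum(hwe_chi2_test(*row)[1] < 0.05 for row in counts)
        assert 0.035 <= rejections / 2000 <= 0.065


def _simple_pheno(y, name="bmi", extra=None):
    df = pd.DataFrame({name: y}, index=[f"S{i}" for i in range(len(y))])
    if extra is not None:
        for k, v in extra.items():
            df[k] = v
    return PhenotypeTable(df)


class TestFitLinear:
    def test_matches_normal_equations_oracle(self, pheno_for_fit):
        """OLS estimates agree with an independent (X'X)^-1 X'y solve to 1e-8."""
        rng = np.random.default_rng(3)
        g = pd.Series(rng.binomial(2, 0.4, 400).astype(float), index=pheno_for_fit.sample_ids)
        res = fit_linear(ModelSpec(outcome="bmi", predictor="snp"), g.rename("snp"), pheno_for_fit)

        df = pheno_for_fit.data.assign(snp=g)
        X = np.column_stack(
            [
                np.ones(400),
                df["snp"],
                df["age"],
                (df["gender"] == 1),
                (df["smoking"] == 1),
                (df["smoking"] == 2),
                (df["physical_activity"] == 1),
                (df["physical_activity"] == 2),
                df["alcohol"],
            ]
        ).astype(float)
        y = df["bmi"].to_numpy()
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta_hat
        sigma2 = resid @ resid / (400 - X.shape[1])
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.beta == pytest.approx(beta_hat[1], rel=1e-8)
        assert res.se == pytest.approx(se, rel=1e-8)
        assert res.ucl - res.beta == pytest.approx(1.959964 * res.se, rel=1e-4)

    def test_fto_scale_effect_recovered_with_nominal_coverage(self):
        """Per-allele effect of 0.49 kg/m2 at one locus, n = 1578: the 95% CI
        covers the truth at close to the nominal rate."""
        rng = np.random.default_rng(99)
        covered = 0
        n_rep = 120
        for _ in range(n_rep):
            g = rng.binomial(2, 0.4, 1578).astype(float)
            y = 25 + 0.49 * g + rng.normal(0, 4.8, 1578)
            pheno = _simple_pheno(y)
            res = fit_linear(
                ModelSpec(outcome="bmi", predictor="snp", adjustment=()),
                pd.Series(g, index=pheno.sample_ids, name="snp"),
                pheno,
            )
            covered += res.lcl <= 0.49 <= res.ucl
        assert 0.88 <= covered / n_rep <= 0.995

    def test_null_type_i_error(self):
        rng = np.random.default_rng(2024)
        n_rep, hits = 600, 0
        for _ in range(n_rep):
            g = rng.binomial(2, 0.3, 250).astype(float)
            y = rng.normal(25, 4, 250)
            pheno = _simple_pheno(y)
            res = fit_linear(
                ModelSpec(outcome="bmi", predictor="snp", adjustment=()),
                pd.Series(g, index=pheno.sample_ids, name="snp"),
                pheno,
            )
            hits += res.p < 0.05
        assert 0.03 <= hits / n_rep <= 0.07

    def test_constant_outcome_is_degenerate(self, pheno_for_fit):
        g = pd.Series(1.0, index=pheno_for_fit.sample_ids, name="snp")
        pheno = PhenotypeTable(pheno_for_fit.data.assign(bmi=25.0))
        with pytest.raises(AssociationError, match="constant"):
            fit_linear(ModelSpec(outcome="bmi", predictor="snp"), g, pheno)

    def test_collinear_design_names_columns(self, pheno_for_fit):
        pheno = PhenotypeTable(pheno_for_fit.data.assign(alcohol=lambda d: d["age"] * 2.0))
        g = pd.Series(
            np.random.default_rng(0).binomial(2, 0.5, 400).astype(float),
            index=pheno.sample_ids,
            name="snp",
        )
        with pytest.raises(AssociationError, match="collinear") as err:
            fit_linear(ModelSpec(outcome="bmi", predictor="snp"), g, pheno)
        assert "age" in str(err.value) and "alcohol" in str(err.value)

    def test_complete_case_sample_size_reported(self, pheno_for_fit):
        data = pheno_for_fit.data.copy()
        data.loc[data.index[:25], "bmi"] = np.nan
        g = pd.Series(1.0 * np.arange(400) % 3 % 2, index=data.index, name="snp")
        res = fit_linear(ModelSpec(outcome="bmi", predictor="snp"), g, PhenotypeTable(data))
        assert res.n == 375

    def test_log_transform_restricted_to_glycaemic_traits(self):
        with pytest.raises(AssociationError, match="log transform"):
            ModelSpec(outcome="bmi", transform="log")


class TestFitLogistic:
    def test_single_class_outcome_is_error(self, pheno_for_fit):
        pheno = PhenotypeTable(pheno_for_fit.data.assign(obesity=1))
        g = pd.Series(
            np.random.default_rng(1).binomial(2, 0.5, 400).astype(float),
            index=pheno.sample_ids,
            name="gps",
        )
        with pytest.raises(AssociationError, match="single class"):
            fit_logistic(ModelSpec(outcome="obesity"), g, pheno)

    def test_null_effect_or_ci_covers_one(self):
        rng = np.random.default_rng(42)
        covered = 0
        n_rep = 80
        for _ in range(n_rep):
            g = rng.normal(27, 4, 900)
            y = rng.binomial(1, 0.25, 900)
            pheno = _simple_pheno(y, name="obesity")
            res = fit_logistic(
                ModelSpec(outcome="obesity", adjustment=()),
                pd.Series(g, index=pheno.sample_ids, name="gps"),
                pheno,
            )
            assert res.odds_ratio == pytest.approx(math.exp(res.beta), rel=1e-9)
            covered += res.or_lcl <= 1.0 <= res.or_ucl
        assert 0.87 <= covered / n_rep <= 1.0

    def test_complete_separation_diagnosed(self):
        g = np.concatenate([np.zeros(30), np.ones(30) * 2])
        y = (g > 1).astype(int)
        pheno = _simple_pheno(y, name="obesity")
        with pytest.raises(AssociationError, match="separation|converge"):
            fit_logistic(
                ModelSpec(outcome="obesity", adjustment=()),
                pd.Series(g, index=pheno.sample_ids, name="gps"),
                pheno,
            )


class TestVarianceExplained:
    def test_null_gps_increment_is_small(self, pheno_for_fit):
        rng = np.random.default_rng(5)
        gps = pd.Series(rng.normal(27, 4, 400), index=pheno_for_fit.sample_ids, name="gps")
        table = variance_explained(gps, pheno_for_fit)
        inc = float(table.loc[table["model"] == "gps_increment", "r_squared_pct"].iloc[0])
        assert 0 <= inc < 1.5  # null increment, small-sample noise only

    def test_all_three_models_share_one_sample(self, pheno_for_fit):
        data = pheno_for_fit.data.copy()
        data.loc[data.index[:40], "alcohol"] = np.nan
        gps = pd.Series(27.0 + np.arange(400) % 7, index=data.index, name="gps")
        table = variance_explained(gps, PhenotypeTable(data))
        assert (table["n"] == 360).all()

    def test_duplicated_predictor_raises_collinearity(self, pheno_for_fit):
        gps = pd.Series(
            pheno_for_fit.data["age"].to_numpy(), index=pheno_for_fit.sample_ids, name="gps"
        )
        with pytest.raises(AssociationError, match="collinear"):
            variance_explained(gps, pheno_for_fit)


class TestDirectionTest:
    def test_printed_value_normal_approximation(self):
        assert directional_consistency_test(25, 31, "normal-approx") == pytest.approx(
            3.22e-4, rel=0.01
        )

    def test_exact_tail(self):
        assert directional_consistency_test(25, 31, "exact") == pytest.approx(4.39e-4, rel=0.01)

    def test_all_consistent_closed_form(self):
        assert directional_consistency_test(31, 31, "exact") == pytest.approx(2.0**-31, rel=1e-12)

    @pytest.mark.parametrize("n", [1, 5, 9, 12])
    def test_exact_matches_brute_force_enumeration(self, n):
        """Enumerate all 2^n sign patterns and count tail outcomes exactly."""
        for k in range(n + 1):
            tail = sum(
                1 for signs in itertools.product([0, 1], repeat=n) if sum(signs) >= k
            )
            assert directional_consistency_test(k, n, "exact") == pytest.approx(
                tail / 2**n, rel=1e-12
            )

    def test_invalid_counts(self):
        with pytest.raises(AssociationError):
            directional_consistency_test(5, 4)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, m, raw, rounded",
        [(0.05, 31, 0.05 / 31, 0.0016), (0.05, 1, 0.05, 0.05), (0.10, 4, 0.025, 0.025)],
    )
    def test_threshold_values(self, alpha, m, raw, rounded):
        got_raw, got_rounded = bonferroni_threshold(alpha, m)
        assert got_raw == pytest.approx(raw, rel=1e-12)
        assert got_rounded == pytest.approx(rounded)

    def test_invalid_inputs(self):
        with pytest.raises(AssociationError):
            bonferroni_threshold(1.5, 31)


class TestInteraction:
    @staticmethod
    def _cohort(rng, n, interaction_effect=0.0):
        gps = rng.normal(27, 3.7, n)
        gender = rng.integers(0, 2, n)
        df = pd.DataFrame(
            {
                "age": rng.uniform(35, 74, n),
                "gender": gender,
                "physical_activity": rng.integers(0, 3, n),
                "smoking": rng.integers(0, 3, n),
                "alcohol": rng.gamma(1.2, 8, n),
            },
            index=[f"S{i}" for i in range(n)],
        )
        df["bmi"] = 22 + 0.13 * gps + interaction_effect * gps * gender + rng.normal(0, 4.8, n)
        return PhenotypeTable(df), pd.Series(gps, index=df.index, name="gps")

    def test_modifier_whitelist(self, pheno_for_fit):
        gps = pd.Series(27.0, index=pheno_for_fit.sample_ids, name="gps")
        with pytest.raises(AssociationError, match="modifier"):
            interaction_test(gps, pheno_for_fit, modifier="age", outcome="bmi")

    def test_null_interaction_rejects_at_nominal_rate(self):
        rng = np.random.default_rng(77)
        hits, n_rep = 0, 300
        for _ in range(n_rep):
            pheno, gps = self._cohort(rng, 350)
            res = interaction_test(gps, pheno, modifier="gender", outcome="bmi")
            hits += res.p < 0.05
        assert 0.025 <= hits / n_rep <= 0.085

    def test_power_rises_with_sample_size(self):
        rng = np.random.default_rng(88)
        rates = []
        for n in (300, 1500):
            hits = 0
            for _ in range(80):
                pheno, gps = self._cohort(rng, n, interaction_effect=0.12)
                hits += interaction_test(gps, pheno, modifier="gender", outcome="bmi").p < 0.05
            rates.append(hits / 80)
        assert rates[1] > rates[0]


class TestUnitConversion:
    @pytest.mark.parametrize(
        "delta, height, grams", [(0.13, 1.70, 376), (0.0, 1.70, 0), (1.0, 1.00, 1000)]
    )
    def test_bmi_increment_to_grams(self, delta, height, grams):
        assert bmi_to_weight_delta(delta, height) == grams

    def test_nonpositive_height(self):
        with pytest.raises(AssociationError):
            bmi_to_weight_delta(0.1, 0.0)
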
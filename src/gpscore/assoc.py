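"""Association statistics for single variants and the GPS.

Covers the whole battery used in a replication analysis of BMI loci:
Hardy-Weinberg chi-square tests, additive linear models with lifestyle
adjustment (age, gender, smoking, physical activity, alcohol, optionally
BMI), logistic models for obesity and type 2 diabetes, variance-explained
decomposition, the directional-consistency sign test against the discovery
GWAS, Bonferroni thresholds, score x covariate interaction tests and the
BMI-to-body-weight unit conversion.

Model fits go through statsmodels; confidence intervals use the normal
1.96-sigma multiplier throughout (with n in the ~1500 range the difference
from t quantiles is negligible).  Glucose, insulin and both HOMA indices
are natural-log transformed before fitting, and coefficients are reported
on the transformed scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import PhenotypeTable
from .score import ScoreResult

Z95 = 1.959963984540054  # Phi^-1(0.975)

#: the basic adjustment set used for anthropometric outcomes
BASIC_ADJUSTMENT = ("age", "gender", "smoking", "physical_activity", "alcohol")
#: covariates expanded into indicator contrasts against their first level
CATEGORICAL_COVARIATES = ("gender", "smoking", "physical_activity")
#: traits normalised by natural-log transformation before fitting
LOG_TRANSFORMED_TRAITS = ("glucose", "insulin", "homa_ir", "homa_b")
#: covariates allowed as interaction modifiers of the score
INTERACTION_MODIFIERS = ("gender", "physical_activity", "smoking", "alcohol")


class AssociationError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """One regression model: outcome, genetic predictor, adjustment set."""

    outcome: str
    predictor: str = "gps"
    adjustment: tuple[str, ...] = BASIC_ADJUSTMENT
    transform: str = "none"  # "none" | "log"

    def __post_init__(self) -> None:
        if self.transform not in ("none", "log"):
            raise AssociationError(f"unknown transform {self.transform!r}")
        if self.transform == "log" and self.outcome not in LOG_TRANSFORMED_TRAITS:
            raise AssociationError(
                f"log transform is reserved for {LOG_TRANSFORMED_TRAITS}, not {self.outcome!r}"
            )


@dataclass
class AssociationResult:
    """Estimate for one fitted term: beta, SE, normal-approximation 95% CI,
    two-sided p, sample size after complete-case filtering and model R^2
    (pseudo-R^2 for logistic fits).  ``odds_ratio`` = exp(beta) for logistic
    terms."""

    term: str
    beta: float
    se: float
    lcl: float
    ucl: float
    p: float
    n: int
    covariates: tuple[str, ...]
    r_squared: float
    odds_ratio: float | None = None
    or_lcl: float | None = None
    or_ucl: float | None = None


def _design(df: pd.DataFrame, predictors: list[str], adjustment: tuple[str, ...]) -> pd.DataFrame:
    """Intercept + predictors + adjustment covariates, categoricals as
    indicator contrasts against the first (lowest) level."""
    cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    for name in predictors:
        cols[name] = df[name].to_numpy(dtype=float)
    for name in adjustment:
        if name in CATEGORICAL_COVARIATES:
            levels = sorted(df[name].dropna().unique())
            for lev in levels[1:]:
                cols[f"{name}[{lev}]"] = (df[name] == lev).to_numpy(dtype=float)
        else:
            cols[name] = df[name].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns involved in the near-null singular directions
        _, s, vt = np.linalg.svd(X.to_numpy(), full_matrices=False)
        null = vt[s < s.max() * 1e-10]
        implicated = sorted(
            {X.columns[j] for row in null for j in np.where(np.abs(row) > 1e-6)[0]}
        )
        raise AssociationError(f"rank-deficient design; collinear columns: {implicated}")


def _complete_cases(
    pheno: PhenotypeTable, predictor: pd.Series, spec: ModelSpec
) -> pd.DataFrame:
    needed = [spec.outcome, *spec.adjustment]
    missing_cols = [c for c in needed if c not in pheno.data.columns]
    if missing_cols:
        raise AssociationError(f"phenotype table lacks columns {missing_cols}")
    df = pheno.data[needed].join(predictor.rename(spec.predictor), how="inner")
    return df.dropna()


def fit_linear(
    spec: ModelSpec, predictor: pd.Series, pheno: PhenotypeTable
) -> AssociationResult:
    """OLS fit of ``spec.outcome`` on the genetic predictor plus adjustment.

    ``predictor`` is a per-sample dosage or score keyed by sample id;
    samples missing any required value are dropped (complete-case).  The
    reported term is the genetic predictor; R^2 is for the full model.
    """
    df = _complete_cases(pheno, predictor, spec)
    y = df[spec.outcome].to_numpy(dtype=float)
    if spec.transform == "log":
        if (y <= 0).any():
            raise AssociationError(f"{spec.outcome}: nonpositive values cannot be log-transformed")
        y = np.log(y)
    X = _design(df, [spec.predictor], spec.adjustment)
    if len(df) < X.shape[1] + 10:
        raise AssociationError(
            f"only {len(df)} complete cases for {X.shape[1]} parameters (need >= {X.shape[1] + 10})"
        )
    if np.ptp(y) == 0:
        raise AssociationError(f"outcome {spec.outcome} is constant; degenerate fit")
    _check_rank(X)
    fit = sm.OLS(y, X).fit()
    beta = float(fit.params[spec.predictor])
    se = float(fit.bse[spec.predictor])
    return AssociationResult(
        term=spec.predictor,
        beta=beta,
        se=se,
        lcl=beta - Z95 * se,
        ucl=beta + Z95 * se,
        p=float(fit.pvalues[spec.predictor]),
        n=len(df),
        covariates=spec.adjustment,
        r_squared=float(fit.rsquared),
    )


def fit_logistic(
    spec: ModelSpec, predictor: pd.Series, pheno: PhenotypeTable
) -> AssociationResult:
    """Maximum-likelihood logistic fit; Wald p-values, OR = exp(beta)."""
    df = _complete_cases(pheno, predictor, spec)
    y = df[spec.outcome].to_numpy(dtype=float)
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all():
        raise AssociationError(f"outcome {spec.outcome} is not binary 0/1")
    if classes.size < 2:
        raise AssociationError(
            f"outcome {spec.outcome} has a single class ({int(classes[0])}) after filtering"
        )
    X = _design(df, [spec.predictor], spec.adjustment)
    _check_rank(X)
    from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise AssociationError(
            f"complete separation in logistic fit of {spec.outcome} on {spec.predictor}: {exc}"
        ) from exc
    if not fit.mle_retvals.get("converged", True):
        raise AssociationError(f"logistic fit of {spec.outcome} failed to converge")
    beta = float(fit.params[spec.predictor])
    se = float(fit.bse[spec.predictor])
    return AssociationResult(
        term=spec.predictor,
        beta=beta,
        se=se,
        lcl=beta - Z95 * se,
        ucl=beta + Z95 * se,
        p=float(fit.pvalues[spec.predictor]),
        n=len(df),
        covariates=spec.adjustment,
        r_squared=float(fit.prsquared),
        odds_ratio=math.exp(beta),
        or_lcl=math.exp(beta - Z95 * se),
        or_ucl=math.exp(beta + Z95 * se),
    )


def variance_explained(
    scores: ScoreResult | pd.Series,
    pheno: PhenotypeTable,
    adjustment: tuple[str, ...] = BASIC_ADJUSTMENT,
    outcome: str = "bmi",
) -> pd.DataFrame:
    """R^2 decomposition on one identical complete-case sample.

    Fits score alone, covariates alone and score + covariates, reporting
    each R^2 in percent plus the score's increment over the covariates.
    """
    gps = scores.series() if isinstance(scores, ScoreResult) else scores
    needed = [outcome, *adjustment]
    df = pheno.data[needed].join(gps.rename("gps"), how="inner").dropna()
    y = df[outcome].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise AssociationError(f"outcome {outcome} is constant; degenerate fit")

    def r2(predictors: list[str], adj: tuple[str, ...]) -> float:
        X = _design(df, predictors, adj)
        _check_rank(X)
        return float(sm.OLS(y, X).fit().rsquared)

    r2_gps = r2(["gps"], ())
    r2_cov = r2([], adjustment)
    r2_full = r2(["gps"], adjustment)
    return pd.DataFrame(
        {
            "model": ["gps_alone", "covariates_alone", "gps_plus_covariates", "gps_increment"],
            "r_squared_pct": [
                100 * r2_gps,
                100 * r2_cov,
                100 * r2_full,
                100 * (r2_full - r2_cov),
            ],
            "n": len(df),
        }
    )


def hwe_chi2_test(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """Chi-square goodness-of-fit test of Hardy-Weinberg proportions (1 df).

    Expected genotype counts derive from the observed allele frequency;
    a monomorphic variant gives chi2 = 0, p = 1 with a warning.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise AssociationError("genotype counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise AssociationError("no genotype calls; HWE test undefined")
    p = (2 * n_AA + n_Aa) / (2 * total)
    if p in (0.0, 1.0):
        warnings.warn("monomorphic variant: HWE test degenerate (chi2=0, p=1)")
        return 0.0, 1.0
    expected = total * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def directional_consistency_test(
    n_consistent: int, n_total: int, method: str = "normal-approx"
) -> float:
    """One-sided sign test of per-SNP effect directions against chance.

    Tests whether ``n_consistent`` of ``n_total`` replication estimates
    sharing the discovery direction exceeds the Binomial(n, 1/2)
    expectation.  ``normal-approx`` uses Phi(-(k - n/2)/sqrt(n/4)) with no
    continuity correction; ``exact`` sums the upper binomial tail.
    """
    if not (0 <= n_consistent <= n_total) or n_total < 1:
        raise AssociationError(f"invalid counts ({n_consistent}, {n_total})")
    if method == "normal-approx":
        z = (n_consistent - n_total / 2.0) / math.sqrt(n_total / 4.0)
        return float(stats.norm.sf(z))
    if method == "exact":
        return sum(math.comb(n_total, j) for j in range(n_consistent, n_total + 1)) / 2.0**n_total
    raise AssociationError(f"unknown method {method!r}")


def bonferroni_threshold(alpha: float, m: int) -> tuple[float, float]:
    """Familywise threshold alpha/m, returned raw and rounded to 2 significant figures."""
    if not (0.0 < alpha < 1.0) or m < 1:
        raise AssociationError(f"invalid alpha/m ({alpha}, {m})")
    raw = alpha / m
    rounded = float(f"{raw:.1e}")  # 2 significant figures
    return raw, rounded


def interaction_test(
    scores: ScoreResult | pd.Series,
    pheno: PhenotypeTable,
    modifier: str,
    outcome: str,
    adjustment: tuple[str, ...] = BASIC_ADJUSTMENT,
) -> AssociationResult:
    """Test a score x covariate product term in a linear model.

    The model contains the score, the modifier (numeric-coded) and their
    product, plus the adjustment covariates; the reported term is the
    product coefficient.
    """
    if modifier not in INTERACTION_MODIFIERS:
        raise AssociationError(
            f"modifier {modifier!r} not one of {INTERACTION_MODIFIERS}"
        )
    gps = scores.series() if isinstance(scores, ScoreResult) else scores
    needed = [outcome, modifier, *[a for a in adjustment if a != modifier]]
    df = pheno.data[list(dict.fromkeys(needed))].join(gps.rename("gps"), how="inner").dropna()
    y = df[outcome].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise AssociationError(f"outcome {outcome} is constant; degenerate fit")
    df = df.assign(**{f"gps_x_{modifier}": df["gps"] * df[modifier].astype(float)})
    adj = tuple(a for a in adjustment if a != modifier)
    X = _design(df, ["gps", modifier, f"gps_x_{modifier}"], adj)
    _check_rank(X)
    fit = sm.OLS(y, X).fit()
    term = f"gps_x_{modifier}"
    beta, se = float(fit.params[term]), float(fit.bse[term])
    return AssociationResult(
        term=term,
        beta=beta,
        se=se,
        lcl=beta - Z95 * se,
        ucl=beta + Z95 * se,
        p=float(fit.pvalues[term]),
        n=len(df),
        covariates=adj,
        r_squared=float(fit.rsquared),
    )


def bmi_to_weight_delta(delta_bmi: float, height: float) -> int:
    """Convert a BMI increment (kg/m2) to grams of body weight at a given
    height in metres: delta_bmi * height^2 * 1000, nearest gram."""
    if height <= 0:
        raise AssociationError(f"height must be positive (got {height})")
    return int(round(delta_bmi * height**2 * 1000.0))
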
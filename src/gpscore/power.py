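"""Analytic power for genetic association with a continuous trait.

Closed-form normal (large-sample) approximations, the framework used by the
Quanto program for single-SNP tests and by correlation-based calculators
for score tests.  Both functions are deterministic and pure; tests validate
them against Monte-Carlo simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats


class PowerError(ValueError):
    pass


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for a power calculation.

    Single-SNP mode uses (n, maf, beta, trait_sd): the additive predictor
    has variance 2*maf*(1-maf) under HWE.  Score mode uses either
    (beta, score_sd, trait_sd) or a direct r2 fraction of variance
    explained.  ``alpha`` is the test size; ``sided`` is "one" or "two".
    """

    n: int
    alpha: float = 0.05
    sided: str = "one"
    maf: float | None = None
    beta: float | None = None
    trait_sd: float | None = None
    score_sd: float | None = None
    r2: float | None = None

    def __post_init__(self) -> None:
        if self.n < 10:
            raise PowerError("n must be >= 10")
        if not (0.0 < self.alpha < 0.5):
            raise PowerError("alpha must lie in (0, 0.5)")
        if self.sided not in ("one", "two"):
            raise PowerError(f"sided must be 'one' or 'two', got {self.sided!r}")
        if self.maf is not None and not (0.0 < self.maf < 1.0):
            raise PowerError("maf must lie in (0, 1)")
        if self.trait_sd is not None and self.trait_sd <= 0:
            raise PowerError("trait_sd must be positive")


def _tail_power(z_star: float, alpha: float, sided: str) -> float:
    if sided == "one":
        return float(stats.norm.cdf(z_star - stats.norm.ppf(1 - alpha)))
    crit = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(z_star - crit) + stats.norm.cdf(-z_star - crit))


def power_single_snp(spec: PowerSpec) -> float:
    """Power to detect a per-allele effect ``beta`` at an additive SNP.

    Predictor variance is 2*maf*(1-maf); the noncentral mean of the Wald z
    statistic is beta*sqrt(n*2*maf*(1-maf))/sigma_resid with
    sigma_resid^2 = trait_sd^2 - beta^2*2*maf*(1-maf).
    """
    if spec.maf is None or spec.beta is None or spec.trait_sd is None:
        raise PowerError("single-SNP mode needs maf, beta and trait_sd")
    var_g = 2.0 * spec.maf * (1.0 - spec.maf)
    var_resid = spec.trait_sd**2 - spec.beta**2 * var_g
    if var_resid <= 0:
        raise PowerError(
            "beta-implied genetic variance meets or exceeds the total trait variance"
        )
    z_star = abs(spec.beta) * math.sqrt(spec.n * var_g) / math.sqrt(var_resid)
    return _tail_power(z_star, spec.alpha, spec.sided)


def power_score(spec: PowerSpec) -> float:
    """Power to detect a score-trait correlation via the Fisher-z approximation.

    The score-trait correlation is r = beta*score_sd/trait_sd, or sqrt(r2)
    when the variance-explained fraction is given directly; power is
    Phi(atanh(r)*sqrt(n-3) - z_crit).
    """
    if spec.r2 is not None:
        if not (0.0 <= spec.r2 < 1.0):
            raise PowerError("r2 must lie in [0, 1)")
        r = math.sqrt(spec.r2)
    else:
        if spec.beta is None or spec.score_sd is None or spec.trait_sd is None:
            raise PowerError("score mode needs r2, or beta with score_sd and trait_sd")
        r = spec.beta * spec.score_sd / spec.trait_sd
    if abs(r) >= 1.0:
        raise PowerError(f"implied correlation |r| = {abs(r):.3f} >= 1")
    z_star = math.atanh(abs(r)) * math.sqrt(spec.n - 3)
    return _tail_power(z_star, spec.alpha, spec.sided)
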
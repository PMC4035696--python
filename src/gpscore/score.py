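"""Weighted, rescaled genetic predisposition score (GPS).

The score is the standard weighted GWAS construction: each effect-allele dosage is
weighted by its per-allele BMI effect and the weighted sum is rescaled by
n_loci / sum(beta) so that one point of the score corresponds to one average
risk allele.  Missing-data rules: a missing call is replaced by the mean
observed dosage of that variant, but samples missing more than 10% of loci
are excluded from scoring altogether.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, VariantWeight

MAX_MISSING_FRACTION = 0.10


class ScoreError(ValueError):
    pass


@dataclass
class ScoreResult:
    """Per-sample GPS with missingness accounting.

    ``gps`` is NaN for excluded samples; ``rescale_factor`` is
    n_loci / sum of weights, so a score of k reads as "k risk alleles".
    """

    sample_ids: list[str]
    gps: np.ndarray
    n_missing_loci: np.ndarray
    missing_fraction: np.ndarray
    excluded: np.ndarray
    n_loci: int
    rescale_factor: float

    @property
    def n_excluded(self) -> int:
        return int(self.excluded.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gps": self.gps,
                "n_missing_loci": self.n_missing_loci,
                "missing_fraction": self.missing_fraction,
                "excluded": self.excluded.astype(int),
            },
            index=self.sample_ids,
        )

    def series(self) -> pd.Series:
        """GPS indexed by sample id, excluded samples dropped."""
        s = pd.Series(self.gps, index=self.sample_ids, name="gps")
        return s[~self.excluded]


def flag_exclusions(matrix: GenotypeMatrix) -> np.ndarray:
    """Samples whose raw missing-locus fraction strictly exceeds 10%.

    For 31 loci: 3 missing (9.7%) is retained, 4 missing (12.9%) excluded.
    """
    if matrix.imputed:
        raise ScoreError("exclusion flags must be computed on the raw (pre-imputation) matrix")
    frac = matrix.missing_per_sample() / matrix.n_variants
    return frac > MAX_MISSING_FRACTION


def impute_missing_dosages(
    matrix: GenotypeMatrix, exclude: np.ndarray | None = None
) -> GenotypeMatrix:
    """Replace missing calls with each variant's mean observed dosage.

    The mean is taken over non-excluded samples only, so heavily missing
    individuals do not pollute the imputation means.  A variant with no
    observed call among the retained samples is a hard error.
    """
    dosage = matrix.dosage.copy()
    keep = ~exclude if exclude is not None else np.ones(matrix.n_samples, dtype=bool)
    for j, rsid in enumerate(matrix.variant_ids):
        col = dosage[keep, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ScoreError(f"variant {rsid}: no observed genotype calls; cannot impute")
        missing = np.isnan(dosage[:, j])
        dosage[missing, j] = obs.mean()
    return GenotypeMatrix(
        sample_ids=list(matrix.sample_ids),
        variant_ids=list(matrix.variant_ids),
        dosage=dosage,
        oriented=matrix.oriented,
        imputed=True,
    )


def compute_gps(
    matrix: GenotypeMatrix,
    weights: Sequence[VariantWeight],
    excluded: np.ndarray | None = None,
    n_missing_raw: np.ndarray | None = None,
) -> ScoreResult:
    """gps_j = (n_loci / sum_i beta_i) * sum_i beta_i * g_ij.

    ``matrix`` must be oriented and imputed (no NaN dosages among retained
    samples).  ``excluded``/``n_missing_raw`` carry the pre-imputation
    accounting; excluded samples receive no score.
    """
    if not matrix.oriented:
        raise ScoreError("genotype matrix must be oriented to effect alleles before scoring")
    order = {w.rsid: w for w in weights}
    if set(order) != set(matrix.variant_ids):
        extra = sorted(set(order) - set(matrix.variant_ids))
        missing = sorted(set(matrix.variant_ids) - set(order))
        raise ScoreError(
            f"weight/matrix variant mismatch (weights without genotypes: {extra}; "
            f"genotypes without weights: {missing})"
        )
    betas = np.array([order[r].weight_beta for r in matrix.variant_ids])
    total = betas.sum()
    if total <= 0:
        raise ScoreError(f"sum of weights must be positive (got {total})")
    n_loci = matrix.n_variants
    rescale = n_loci / total

    if excluded is None:
        excluded = np.zeros(matrix.n_samples, dtype=bool)
    if n_missing_raw is None:
        n_missing_raw = np.isnan(matrix.dosage).sum(axis=1)
    n_missing_raw = np.asarray(n_missing_raw)

    retained_dosage = matrix.dosage[~excluded]
    if np.isnan(retained_dosage).any():
        raise ScoreError("retained samples still carry missing dosages; impute first")
    gps = np.full(matrix.n_samples, np.nan)
    gps[~excluded] = rescale * (retained_dosage @ betas)
    return ScoreResult(
        sample_ids=list(matrix.sample_ids),
        gps=gps,
        n_missing_loci=n_missing_raw.astype(int),
        missing_fraction=n_missing_raw / n_loci,
        excluded=np.asarray(excluded, dtype=bool),
        n_loci=n_loci,
        rescale_factor=rescale,
    )


def score_cohort(raw: GenotypeMatrix, weights: Sequence[VariantWeight]) -> ScoreResult:
    """Exclude > 10%-missing samples, mean-impute the rest, compute the GPS."""
    excluded = flag_exclusions(raw)
    imputed = impute_missing_dosages(raw, exclude=excluded)
    return compute_gps(
        imputed, weights, excluded=excluded, n_missing_raw=raw.missing_per_sample()
    )


def write_scores(result: ScoreResult, path) -> None:
    df = result.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")
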
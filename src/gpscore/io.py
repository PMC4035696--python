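"""Readers and writers for weight tables, genotype matrices and phenotype tables.

Genotypes are held as effect-allele dosages (0/1/2, ``NaN`` = missing) in a
samples x variants array.  VCF input counts ALT alleles and is then
harmonized so that every dosage counts the *effect* (BMI-raising) allele of
the weight table; dosage-TSV input is taken to be pre-oriented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID_ALLELE = frozenset("ACGT")
#: strand-ambiguous allele pairs: indistinguishable from their reverse complement
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})

MISSING_TSV = "NA"

#: phenotype columns recognised by the association battery (exact lowercase names)
PHENOTYPE_COLUMNS = (
    "age", "gender", "bmi", "body_fat_pct", "waist_cm", "hip_cm", "whr",
    "glucose", "insulin", "hba1c", "homa_ir", "homa_b", "obesity", "t2d",
    "physical_activity", "smoking", "alcohol",
)


class VariantIOError(ValueError):
    """Malformed or inconsistent variant/genotype/phenotype input."""


@dataclass(frozen=True)
class VariantWeight:
    """One scored locus: alleles and its per-allele effect on BMI (kg/m2).

    The sign convention is that ``weight_beta`` is positive for the
    BMI-raising (effect) allele, as in GWAS-derived score weights.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    weight_beta: float
    chrom: str | None = None
    pos: int | None = None
    effect_allele_freq: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise VariantIOError(
                f"{self.rsid}: effect and other allele are both {self.effect_allele!r}"
            )
        for allele in (self.effect_allele, self.other_allele):
            if not allele or not set(allele) <= _VALID_ALLELE:
                raise VariantIOError(f"{self.rsid}: invalid allele {allele!r}")
        if not np.isfinite(self.weight_beta):
            raise VariantIOError(f"{self.rsid}: non-finite weight {self.weight_beta!r}")
        if self.effect_allele_freq is not None and not (0.0 < self.effect_allele_freq < 1.0):
            raise VariantIOError(
                f"{self.rsid}: effect_allele_freq {self.effect_allele_freq} not in (0, 1)"
            )

    @property
    def is_strand_ambiguous(self) -> bool:
        return {self.effect_allele, self.other_allele} in _AMBIGUOUS_PAIRS


@dataclass
class GenotypeMatrix:
    """Samples x variants effect-allele dosage matrix.

    ``dosage`` is float with ``NaN`` marking missing calls.  Until
    ``imputed`` is set, all non-missing entries are integral in {0, 1, 2}.
    ``oriented`` records that harmonization to the effect allele has been
    applied (dosages count BMI-raising alleles).
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray
    oriented: bool = False
    imputed: bool = False

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise VariantIOError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise VariantIOError("duplicate variant identifiers in genotype matrix")
        obs = self.dosage[~np.isnan(self.dosage)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise VariantIOError("dosages outside [0, 2]")
        if not self.imputed and obs.size and not np.allclose(obs, np.round(obs)):
            raise VariantIOError("raw dosages must be integral in {0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def missing_per_sample(self) -> np.ndarray:
        return np.isnan(self.dosage).sum(axis=1)

    def genotype_counts(self, variant: str) -> tuple[int, int, int]:
        """(n with 0, 1, 2 effect alleles) for one variant, missing excluded."""
        col = self.dosage[:, self.variant_ids.index(variant)]
        col = col[~np.isnan(col)].astype(int)
        return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.sample_ids, columns=self.variant_ids)


@dataclass
class PhenotypeTable:
    """Per-sample outcomes and covariates, indexed by sample id.

    Thin wrapper around a DataFrame; ``validate`` enforces the cross-field
    consistency rules (WHR = waist/hip, obesity = BMI >= 30, positivity of
    glycaemic measurements).  Any cell may be missing (``NaN``).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise VariantIOError("duplicate sample identifiers in phenotype table")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def __len__(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        df = self.data
        if {"waist_cm", "hip_cm", "whr"} <= set(df.columns):
            rows = df[["waist_cm", "hip_cm", "whr"]].dropna()
            bad = (rows["whr"] - rows["waist_cm"] / rows["hip_cm"]).abs() >= 1e-6
            if bad.any():
                raise VariantIOError(
                    f"whr inconsistent with waist/hip for samples {list(rows.index[bad])[:5]}"
                )
        if {"bmi", "obesity"} <= set(df.columns):
            rows = df[["bmi", "obesity"]].dropna()
            bad = rows["obesity"].astype(bool) != (rows["bmi"] >= 30.0)
            if bad.any():
                raise VariantIOError(
                    f"obesity flag inconsistent with BMI >= 30 for {list(rows.index[bad])[:5]}"
                )
        for col in ("glucose", "insulin", "homa_ir", "homa_b"):
            if col in df.columns:
                vals = df[col].dropna()
                if (vals <= 0).any():
                    raise VariantIOError(f"{col} must be strictly positive when present")


# ---------------------------------------------------------------------------
# weight tables
# ---------------------------------------------------------------------------

def read_weight_table(path) -> list[VariantWeight]:
    """Read a TSV of score weights (rsid, effect_allele, other_allele, weight_beta).

    Optional columns ``chrom``, ``pos`` and ``effect_allele_freq`` are
    populated when present.  Duplicate rsids, equal or malformed alleles and
    unparseable weights are hard errors carrying the offending row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"rsid", "effect_allele", "other_allele", "weight_beta"}
    if not required <= set(df.columns):
        raise VariantIOError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    weights: list[VariantWeight] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 2 = first data line
        rsid = str(row.rsid)
        if rsid in seen:
            raise VariantIOError(f"{path} line {i}: duplicate rsid {rsid}")
        seen.add(rsid)
        try:
            beta = float(row.weight_beta)
        except (TypeError, ValueError) as exc:
            raise VariantIOError(f"{path} line {i}: unparseable weight {row.weight_beta!r}") from exc
        freq = getattr(row, "effect_allele_freq", None)
        pos = getattr(row, "pos", None)
        try:
            weights.append(
                VariantWeight(
                    rsid=rsid,
                    effect_allele=str(row.effect_allele).upper(),
                    other_allele=str(row.other_allele).upper(),
                    weight_beta=beta,
                    chrom=str(row.chrom) if getattr(row, "chrom", None) is not None else None,
                    pos=int(pos) if pos is not None and not pd.isna(pos) else None,
                    effect_allele_freq=float(freq) if freq is not None and not pd.isna(freq) else None,
                )
            )
        except VariantIOError as exc:
            raise VariantIOError(f"{path} line {i}: {exc}") from exc
    return weights


def write_weight_table(weights: Sequence[VariantWeight], path) -> None:
    df = pd.DataFrame(
        {
            "rsid": [w.rsid for w in weights],
            "effect_allele": [w.effect_allele for w in weights],
            "other_allele": [w.other_allele for w in weights],
            "weight_beta": [repr(w.weight_beta) for w in weights],
            "effect_allele_freq": [
                "" if w.effect_allele_freq is None else repr(w.effect_allele_freq) for w in weights
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def harmonize_alleles(
    matrix: GenotypeMatrix,
    observed_alleles: Mapping[str, tuple[str, str]],
    weights: Sequence[VariantWeight],
    ambiguous_orientation: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Flip dosages so that they count the effect allele of each weight.

    ``observed_alleles`` maps rsid to the (counted, uncounted) allele pair of
    the incoming matrix.  Where that pair equals (effect, other) the column
    is kept; where it equals (other, effect) the column is complemented
    (dosage -> 2 - dosage, missing stays missing).  Strand-ambiguous A/T and
    C/G pairs cannot be resolved by allele labels alone and require an entry
    in ``ambiguous_orientation`` ("as-is" or "swap"); anything else is a
    hard error.
    """
    if matrix.oriented:
        raise VariantIOError("matrix is already oriented to effect alleles")
    ambiguous_orientation = dict(ambiguous_orientation or {})
    by_rsid = {w.rsid: w for w in weights}
    dosage = matrix.dosage.copy()
    for j, rsid in enumerate(matrix.variant_ids):
        w = by_rsid.get(rsid)
        if w is None:
            raise VariantIOError(f"{rsid}: no weight available for harmonization")
        if w.is_strand_ambiguous:
            action = ambiguous_orientation.get(rsid)
            if action not in ("as-is", "swap"):
                raise VariantIOError(
                    f"{rsid}: strand-ambiguous alleles {w.effect_allele}/{w.other_allele}; "
                    "declare orientation explicitly ('as-is' or 'swap') in the config"
                )
            if action == "swap":
                dosage[:, j] = 2.0 - dosage[:, j]
            continue
        observed = tuple(a.upper() for a in observed_alleles[rsid])
        if observed == (w.effect_allele, w.other_allele):
            continue
        if observed == (w.other_allele, w.effect_allele):
            dosage[:, j] = 2.0 - dosage[:, j]
        else:
            raise VariantIOError(
                f"{rsid}: observed alleles {observed[0]}/{observed[1]} match neither "
                f"orientation of {w.effect_allele}/{w.other_allele}"
            )
    return GenotypeMatrix(
        sample_ids=list(matrix.sample_ids),
        variant_ids=list(matrix.variant_ids),
        dosage=dosage,
        oriented=True,
    )


def read_genotypes_vcf(
    path,
    wanted: Sequence[VariantWeight],
    ambiguous_orientation: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read effect-allele dosages for ``wanted`` variants from a VCF (GT field).

    ALT-allele counts are harmonized to the effect allele.  ``./.`` (any GT
    containing ``.``) is missing.  A wanted variant absent from the file
    becomes an all-missing column with a logged warning; multi-allelic
    records and malformed GT fields are hard errors.
    """
    from cyvcf2 import VCF

    wanted_ids = [w.rsid for w in wanted]
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    columns = {rsid: np.full(n, np.nan) for rsid in wanted_ids}
    observed: dict[str, tuple[str, str]] = {}
    wanted_set = set(wanted_ids)
    for record in vcf:
        rsid = record.ID
        if rsid not in wanted_set:
            continue
        if len(record.ALT) != 1:
            raise VariantIOError(
                f"{record.CHROM}:{record.POS} ({rsid}): multi-allelic record; "
                "biallelic input required"
            )
        col = np.full(n, np.nan)
        for i, gt in enumerate(record.genotypes):
            alleles = gt[:-1]  # trailing element is phasing flag
            if any(a < 0 for a in alleles):  # GT containing '.' -> missing call
                continue
            if len(alleles) != 2:
                raise VariantIOError(
                    f"{record.CHROM}:{record.POS} ({rsid}): malformed GT for sample "
                    f"{sample_ids[i]} (ploidy {len(alleles)})"
                )
            if any(a > 1 for a in alleles):
                raise VariantIOError(
                    f"{record.CHROM}:{record.POS} ({rsid}): GT allele index out of range"
                )
            col[i] = float(sum(alleles))
        columns[rsid] = col
        observed[rsid] = (record.ALT[0].upper(), record.REF.upper())
    vcf.close()
    for rsid in wanted_ids:
        if rsid not in observed:
            logger.warning("variant %s absent from VCF: recorded as all-missing", rsid)
            # orientation of an absent variant is vacuous
            by = next(w for w in wanted if w.rsid == rsid)
            observed[rsid] = (by.effect_allele, by.other_allele)
    dosage = np.column_stack([columns[rsid] for rsid in wanted_ids])
    raw = GenotypeMatrix(sample_ids=sample_ids, variant_ids=list(wanted_ids), dosage=dosage)
    return harmonize_alleles(raw, observed, wanted, ambiguous_orientation)


def read_genotypes_tsv(path, wanted: Sequence[VariantWeight]) -> GenotypeMatrix:
    """Read a pre-oriented dosage TSV (first column sample id, one column per rsid).

    Cells must be 0, 1, 2 or ``NA``; anything else is an error naming the
    sample and variant.  Dosages are already effect-allele counts, so the
    result is marked oriented.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    wanted_ids = [w.rsid for w in wanted]
    n = len(df)
    dosage = np.full((n, len(wanted_ids)), np.nan)
    for j, rsid in enumerate(wanted_ids):
        if rsid not in df.columns:
            logger.warning("variant %s absent from %s: recorded as all-missing", rsid, path)
            continue
        for i, (sample, cell) in enumerate(df[rsid].items()):
            if pd.isna(cell) or cell == MISSING_TSV:
                continue
            if cell not in ("0", "1", "2"):
                raise VariantIOError(
                    f"{path}: invalid dosage {cell!r} at sample {sample}, variant {rsid}"
                )
            dosage[i, j] = float(cell)
    return GenotypeMatrix(
        sample_ids=[str(s) for s in df.index],
        variant_ids=list(wanted_ids),
        dosage=dosage,
        oriented=True,
    )


def write_genotypes_tsv(matrix: GenotypeMatrix, path) -> None:
    """Write an oriented dosage matrix as TSV (``NA`` for missing); exact round-trip."""
    if not matrix.oriented:
        raise VariantIOError("refusing to write an unoriented genotype matrix")
    df = matrix.to_frame()
    out = df.map(lambda v: MISSING_TSV if np.isnan(v) else str(int(v)))
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path, validate: bool = True) -> PhenotypeTable:
    """Read a phenotype/covariate TSV keyed by sample id.

    Column headers are matched by their exact lowercase names; unknown
    columns are carried through untouched.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TSV])
    df.index = df.index.map(str)
    table = PhenotypeTable(df)
    if validate:
        table.validate()
    return table


def write_phenotypes(table: PhenotypeTable, path) -> None:
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep=MISSING_TSV, float_format=None)
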
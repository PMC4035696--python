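import numpy as np
import pandas as pd
import pytest

from gpscore import GenotypeMatrix, PhenotypeTable, VariantWeight


@pytest.fixture
def three_weights():
    return [
        VariantWeight("rs1", "A", "G", 0.1),
        VariantWeight("rs2", "C", "T", 0.2),
        VariantWeight("rs3", "G", "A", 0.3),
    ]


@pytest.fixture
def weight_tsv(tmp_path, three_weights):
    path = tmp_path / "weights.tsv"
    lines = ["rsid\teffect_allele\tother_allele\tweight_beta"]
    for w in three_weights:
        lines.append(f"{w.rsid}\t{w.effect_allele}\t{w.other_allele}\t{w.weight_beta}")
    path.write_text("\n".join(lines) + "\n")
    return path


def make_matrix(dosage, oriented=True, imputed=False, prefix="S"):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return GenotypeMatrix(
        sample_ids=[f"{prefix}{i}" for i in range(n)],
        variant_ids=[f"rs{j + 1}" for j in range(m)],
        dosage=dosage,
        oriented=oriented,
        imputed=imputed,
    )


@pytest.fixture
def tiny_vcf(tmp_path):
    """Three biallelic variants, five samples; rs2 has REF = effect allele
    (swapped orientation relative to the rs2 weight) and rs3 carries missing
    and phased calls."""
    text = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4\ts5
1\t100\trs1\tG\tA\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\t0/1\t1/1
2\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t1|1\t0/1
3\t300\trs3\tA\tG\t.\tPASS\t.\tGT\t./.\t0|1\t1/1\t0/0\t.
"""
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path


@pytest.fixture
def pheno_for_fit():
    """Deterministic phenotype table large enough for adjusted fits."""
    rng = np.random.default_rng(7)
    n = 400
    df = pd.DataFrame(
        {
            "age": rng.uniform(35, 74, n),
            "gender": rng.integers(0, 2, n),
            "physical_activity": rng.integers(0, 3, n),
            "smoking": rng.integers(0, 3, n),
            "alcohol": rng.gamma(1.2, 8.0, n),
        },
        index=[f"S{i}" for i in range(n)],
    )
    df["bmi"] = 25 + 0.05 * df["age"] + rng.normal(0, 4, n)
    df["obesity"] = (df["bmi"] >= 30).astype(int)
    return PhenotypeTable(df)
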
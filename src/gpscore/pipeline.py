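"""End-to-end orchestration: cohort in, report tables out.

Stage order mirrors the analysis plan of a replication study of BMI loci:
per-variant HWE tests, per-variant additive models, GPS models for
anthropometry (with and without BMI adjustment where meaningful),
variance-explained decomposition, glycaemic models under both adjustment
sets, logistic models for obesity and diabetes, the directional-consistency
sign test and an analytic power summary.  Every sample and variant entering
the run is accounted for as analyzed or excluded-with-reason, and the whole
run is a deterministic function of config + seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, power as power_mod, score as score_mod
from .io import (
    GenotypeMatrix,
    PhenotypeTable,
    VariantWeight,
    read_genotypes_tsv,
    read_genotypes_vcf,
    read_phenotypes,
    read_weight_table,
    write_genotypes_tsv,
    write_phenotypes,
    write_weight_table,
)
from .simulate import SimulationConfig, default_config, simulate_cohort

logger = logging.getLogger(__name__)

ANTHROPOMETRIC_TRAITS = ("bmi", "body_fat_pct", "waist_cm", "hip_cm", "whr")
GLYCAEMIC_TRAITS = ("glucose", "insulin", "hba1c", "homa_ir", "homa_b")
BINARY_TRAITS = ("obesity", "t2d")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run (simulate a cohort or load files)."""

    mode: str = "simulate"  # "simulate" | "load"
    out_dir: str | Path = "gpscore_run"
    seed: int = 0
    alpha: float = 0.05
    sim: SimulationConfig | None = None
    weights_path: str | Path | None = None
    genotypes_path: str | Path | None = None
    phenotypes_path: str | Path | None = None
    genotype_format: str = "tsv"  # "tsv" | "vcf"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"mode must be 'simulate' or 'load', got {self.mode!r}")
        if self.mode == "load":
            missing = [
                n
                for n, p in (
                    ("weights", self.weights_path),
                    ("genotypes", self.genotypes_path),
                    ("phenotypes", self.phenotypes_path),
                )
                if p is None
            ]
            if missing:
                raise ValueError(f"load mode requires paths for: {missing}")


@dataclass
class RunReport:
    """All tables from one run, plus exclusion accounting."""

    tables: dict[str, pd.DataFrame]
    n_samples_in: int
    n_excluded_score: int
    direction_p: float
    out_dir: Path
    summary: str = ""


def _result_row(trait: str, model: str, res: assoc.AssociationResult) -> dict:
    row = {
        "outcome": trait,
        "model": model,
        "beta": res.beta,
        "se": res.se,
        "lcl": res.lcl,
        "ucl": res.ucl,
        "p": res.p,
        "n": res.n,
        "r_squared": res.r_squared,
    }
    if res.odds_ratio is not None:
        row.update(odds_ratio=res.odds_ratio, or_lcl=res.or_lcl, or_ucl=res.or_ucl)
    return row


def _fmt(x, col: str) -> str:
    """Report-table display precision: betas to 3 decimals, p scientific below 1e-3."""
    if isinstance(x, float):
        if col == "p":
            return f"{x:.1e}" if x < 1e-3 else f"{x:.4f}"
        if col in ("beta", "se", "lcl", "ucl", "odds_ratio", "or_lcl", "or_ucl"):
            return f"{x:.3f}"
        if col in ("r_squared", "r_squared_pct", "chi2", "missing_fraction"):
            return f"{x:.3f}"
        return repr(x)
    return str(x)


def _write_tables(report: RunReport) -> None:
    out = report.out_dir
    for name, df in report.tables.items():
        df.to_csv(out / f"{name}_full.tsv", sep="\t", index=False, na_rep="NA")
        disp = df.copy()
        for col in disp.columns:
            disp[col] = [_fmt(v, col) for v in disp[col]]
        disp.to_csv(out / f"{name}.tsv", sep="\t", index=False, na_rep="NA")
    (out / "summary.txt").write_text(report.summary + "\n")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage and write the report tables under ``config.out_dir``.

    On any stage failure, files already written for this run are removed and
    a ``PipelineError`` naming the stage is raised.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        logger.info("[%s] %s", stage, msg)
        log_lines.append(f"[{stage}] {msg}")

    try:
        # ---- inputs -------------------------------------------------------
        if config.mode == "simulate":
            sim = config.sim or default_config(seed=config.seed)
            weights = list(sim.variants)
            genos, pheno = simulate_cohort(sim)
            log("input", f"simulated cohort of {sim.n_samples} samples, {len(weights)} loci")
            write_weight_table(weights, out_dir / "weights_used.tsv")
            write_genotypes_tsv(genos, out_dir / "genotypes_used.tsv")
            write_phenotypes(pheno, out_dir / "phenotypes_used.tsv")
            written += [
                out_dir / "weights_used.tsv",
                out_dir / "genotypes_used.tsv",
                out_dir / "phenotypes_used.tsv",
            ]
        else:
            weights = read_weight_table(config.weights_path)
            if config.genotype_format == "vcf":
                genos = read_genotypes_vcf(config.genotypes_path, weights)
            else:
                genos = read_genotypes_tsv(config.genotypes_path, weights)
            pheno = read_phenotypes(config.phenotypes_path)
            log(
                "input",
                f"loaded {genos.n_samples} samples x {genos.n_variants} variants "
                f"and {len(pheno)} phenotype rows",
            )

        by_rsid = {w.rsid: w for w in weights}
        m = genos.n_variants

        # ---- HWE ----------------------------------------------------------
        stage = "hwe"
        hwe_alpha = config.alpha / m
        hwe_rows = []
        for rsid in genos.variant_ids:
            n0, n1, n2 = genos.genotype_counts(rsid)
            chi2, p = assoc.hwe_chi2_test(n2, n1, n0)  # n_AA = effect homozygotes
            hwe_rows.append(
                {
                    "rsid": rsid,
                    "n_other_hom": n0,
                    "n_het": n1,
                    "n_effect_hom": n2,
                    "chi2": chi2,
                    "p": p,
                    "hwe_ok": p > hwe_alpha,
                }
            )
        hwe_table = pd.DataFrame(hwe_rows)
        log(stage, f"{int(hwe_table['hwe_ok'].sum())}/{m} variants conform to HWE at alpha/m")

        # ---- per-SNP additive models -------------------------------------
        stage = "per_snp"
        threshold_raw, threshold = assoc.bonferroni_threshold(config.alpha, m)
        snp_rows = []
        geno_df = genos.to_frame()
        for rsid in genos.variant_ids:
            spec = assoc.ModelSpec(outcome="bmi", predictor=rsid)
            res = assoc.fit_linear(spec, geno_df[rsid], pheno)
            consistent = np.sign(res.beta) == np.sign(by_rsid[rsid].weight_beta)
            snp_rows.append(
                {
                    "rsid": rsid,
                    "beta": res.beta,
                    "se": res.se,
                    "p": res.p,
                    "n": res.n,
                    "direction_consistent": bool(consistent),
                    "significant_bonferroni": res.p <= threshold_raw,
                }
            )
        snp_table = pd.DataFrame(snp_rows)
        n_consistent = int(snp_table["direction_consistent"].sum())
        log(stage, f"{n_consistent}/{m} per-SNP effects directionally consistent")

        # ---- direction test ----------------------------------------------
        stage = "direction_test"
        direction_p = assoc.directional_consistency_test(n_consistent, m, "normal-approx")
        direction_p_exact = assoc.directional_consistency_test(n_consistent, m, "exact")
        direction_table = pd.DataFrame(
            {
                "n_consistent": [n_consistent],
                "n_total": [m],
                "p_normal_approx": [direction_p],
                "p_exact": [direction_p_exact],
            }
        )

        # ---- GPS ----------------------------------------------------------
        stage = "gps"
        scores = score_mod.score_cohort(genos, weights)
        score_mod.write_scores(scores, out_dir / "gps_scores.tsv")
        written.append(out_dir / "gps_scores.tsv")
        log(
            stage,
            f"scored {scores.gps.size - scores.n_excluded} samples; "
            f"{scores.n_excluded} excluded (> 10% missing loci)",
        )
        gps = scores.series()

        stage = "gps_anthropometry"
        anthro_rows = []
        for trait in ANTHROPOMETRIC_TRAITS:
            if trait not in pheno.data.columns or pheno.data[trait].dropna().empty:
                continue
            res = assoc.fit_linear(assoc.ModelSpec(outcome=trait), gps, pheno)
            anthro_rows.append(_result_row(trait, "basic", res))
            if trait != "bmi" and "bmi" in pheno.data.columns:
                res_b = assoc.fit_linear(
                    assoc.ModelSpec(outcome=trait, adjustment=assoc.BASIC_ADJUSTMENT + ("bmi",)),
                    gps,
                    pheno,
                )
                anthro_rows.append(_result_row(trait, "basic+bmi", res_b))
        anthro_table = pd.DataFrame(anthro_rows)

        stage = "variance_explained"
        var_table = assoc.variance_explained(scores, pheno)

        stage = "glycaemia"
        gly_rows = []
        for trait in GLYCAEMIC_TRAITS:
            if trait not in pheno.data.columns or pheno.data[trait].dropna().empty:
                continue
            transform = "log" if trait in assoc.LOG_TRANSFORMED_TRAITS else "none"
            for label, adj in (
                ("basic", assoc.BASIC_ADJUSTMENT),
                ("basic+bmi", assoc.BASIC_ADJUSTMENT + ("bmi",)),
            ):
                res = assoc.fit_linear(
                    assoc.ModelSpec(outcome=trait, adjustment=adj, transform=transform),
                    gps,
                    pheno,
                )
                gly_rows.append(_result_row(trait, label, res))
        gly_table = pd.DataFrame(gly_rows)

        stage = "disease"
        logit_rows = []
        for trait, adj in (
            ("obesity", assoc.BASIC_ADJUSTMENT),
            ("t2d", assoc.BASIC_ADJUSTMENT + ("bmi",)),
        ):
            if trait not in pheno.data.columns:
                continue
            res = assoc.fit_logistic(assoc.ModelSpec(outcome=trait, adjustment=adj), gps, pheno)
            label = "basic" if adj == assoc.BASIC_ADJUSTMENT else "basic+bmi"
            logit_rows.append(_result_row(trait, label, res))
        logit_table = pd.DataFrame(logit_rows)

        # ---- power summary -------------------------------------------------
        stage = "power"
        gps_r2 = float(var_table.loc[var_table["model"] == "gps_alone", "r_squared_pct"].iloc[0]) / 100
        n_scored = int(var_table["n"].iloc[0])
        score_power = power_mod.power_score(
            power_mod.PowerSpec(n=n_scored, alpha=config.alpha, sided="one", r2=gps_r2)
        )
        power_table = pd.DataFrame(
            {"quantity": ["gps_bmi_power_one_sided"], "r2": [gps_r2], "n": [n_scored], "power": [score_power]}
        )

        # ---- exclusion accounting ------------------------------------------
        stage = "accounting"
        excl = pd.DataFrame(
            {
                "sample_id": scores.sample_ids,
                "status": np.where(scores.excluded, "excluded_gt10pct_missing", "analyzed"),
                "n_missing_loci": scores.n_missing_loci,
            }
        )
        log(stage, f"{(excl['status'] == 'analyzed').sum()} analyzed, "
                   f"{(excl['status'] != 'analyzed').sum()} excluded")

        report = RunReport(
            tables={
                "hwe": hwe_table,
                "per_snp": snp_table,
                "direction_test": direction_table,
                "gps_anthropometry": anthro_table,
                "variance_explained": var_table,
                "glycaemic": gly_table,
                "disease_logistic": logit_table,
                "power_summary": power_table,
                "sample_accounting": excl,
            },
            n_samples_in=genos.n_samples,
            n_excluded_score=scores.n_excluded,
            direction_p=direction_p,
            out_dir=out_dir,
        )
        report.summary = summarize_run(report)
        _write_tables(report)
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
        return report
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        for stale in out_dir.glob("*.tsv"):
            stale.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage if "stage" in dir() else "input", str(exc)) from exc


def summarize_run(report: RunReport) -> str:
    """One-paragraph digest: n analyzed, n excluded, GPS-BMI effect with CI,
    variance explained and the direction-test p."""
    anthro = report.tables["gps_anthropometry"]
    bmi_row = anthro[anthro["outcome"] == "bmi"].iloc[0]
    var = report.tables["variance_explained"]
    r2 = float(var.loc[var["model"] == "gps_alone", "r_squared_pct"].iloc[0])
    n_analyzed = report.n_samples_in - report.n_excluded_score
    return (
        f"Analyzed {n_analyzed} of {report.n_samples_in} samples "
        f"({report.n_excluded_score} excluded for > 10% missing loci). "
        f"Each additional risk allele of the GPS was associated with "
        f"{bmi_row['beta']:+.3f} kg/m2 of BMI "
        f"[95% CI {bmi_row['lcl']:.3f} to {bmi_row['ucl']:.3f}, p = {bmi_row['p']:.2e}, "
        f"n = {int(bmi_row['n'])}]. "
        f"The GPS alone explained {r2:.2f}% of the BMI variance. "
        f"Directional-consistency sign test: p = {report.direction_p:.2e}."
    )


def load_summary(out_dir: str | Path) -> str:
    """Read back the summary of a completed run."""
    path = Path(out_dir) / "summary.txt"
    if not path.exists():
        raise FileNotFoundError(f"no completed run found at {path}")
    return path.read_text().strip()
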
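"""End-to-end orchestration: simulate/load -> QC -> association -> selection
-> scoring -> survival -> AUC evaluation.

Every stage writes plain TSV artifacts into the output directory so any
stage can be rerun in isolation, and a ``run_report.json`` summarizes the
whole run.  Given the same config (including seed) a rerun produces
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__, grs, qc, simulate
from .assoc import manhattan_frame, results_frame, run_association, select_snps
from .errors import GrsurvError
from .evaluate import compare_auc_paired, fit_evaluation_models, roc_auc, roc_points
from .io import (
    read_genotype_tsv,
    read_phenotypes,
    read_vcf,
    write_genotype_tsv,
    write_phenotypes,
    write_vcf,
)
from .survival import fit_bcr_models, km_estimate, logrank_test

log = logging.getLogger("grsurv")


class StageError(GrsurvError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Flat, fully serializable run configuration."""

    # input cohort: either file paths or simulation parameters
    genotypes: str | None = None  # .vcf or genotype .tsv
    phenotypes: str | None = None
    n_samples: int = 912
    outcome_model: str = "retrospective"
    n_null_variants: int = 84
    event_rate_target: float = simulate.panel.EVENT_RATE
    censoring_rate: float = 0.0
    missing_rate: float = 1.3e-4
    hazard_scale: float = simulate.panel.GRS_LOG_HAZARD
    event_time_scale: float = 40.0
    t_max: float = 120.0
    # QC thresholds
    marker_max_missing: float = 0.05
    sample_min_call_rate: float = 0.95
    hwe_alpha: float = 1e-6
    het_sd_limit: float = 3.0
    relatedness_max_pihat: float = 0.1875
    # association / selection
    assoc_method: str = "allelic"
    alpha: float = 1e-3
    # scoring / survival / evaluation
    grs_cutoff: float = grs.DEFAULT_CUTOFF
    gleason_coding: str = "binary"
    ties_method: str = "efron"
    auc_method: str = "delong"
    seed: int = 0

    def simulation_config(self) -> simulate.SimulationConfig:
        return simulate.SimulationConfig(
            n_samples=self.n_samples,
            outcome_model=self.outcome_model,
            n_null_variants=self.n_null_variants,
            event_rate_target=self.event_rate_target,
            censoring_rate=self.censoring_rate,
            missing_rate=self.missing_rate,
            hazard_scale=self.hazard_scale,
            event_time_scale=self.event_time_scale,
            t_max=self.t_max,
            seed=self.seed,
        )

    def qc_thresholds(self) -> qc.QCThresholds:
        return qc.QCThresholds(
            marker_max_missing=self.marker_max_missing,
            sample_min_call_rate=self.sample_min_call_rate,
            hwe_alpha=self.hwe_alpha,
            het_sd_limit=self.het_sd_limit,
            relatedness_max_pihat=self.relatedness_max_pihat,
        )

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise GrsurvError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _assoc_table(results) -> pd.DataFrame:
    """Association results shaped like the published per-SNP summary table."""
    df = results_frame(results)
    out = pd.DataFrame(
        {
            "SNPID": df["variant_id"],
            "Chr": df["chromosome"],
            "Alleles": df["other_allele"] + " > " + df["effect_allele"],
            "Gene": df["gene"].replace("", "."),
            "MAF_noBCR": df["maf_controls"],
            "MAF_BCR": df["maf_cases"],
            "OR": df["or_estimate"],
            "CI_low": df["ci_low"],
            "CI_high": df["ci_high"],
            "p": df["p_value"],
            "p_bonferroni": df["p_bonferroni"],
            "p_bh": df["p_bh"],
            "flags": df["flags"],
        }
    )
    return out


def _cox_table(model) -> pd.DataFrame:
    s = model.summary()
    s["converged"] = model.converged
    return s


def run_pipeline(config: RunConfig, out_dir: str) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    os.makedirs(out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out_dir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    log.info("grsurv %s", __version__)
    log.info("resolved config: %s", json.dumps(report["config"], sort_keys=True))
    config.to_file(os.path.join(out_dir, "config.yaml"))

    def _write_report():
        with open(os.path.join(out_dir, "run_report.json"), "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)

    try:
        # ---------------- cohort ----------------
        stage = "cohort"
        if config.genotypes is not None and config.phenotypes is not None:
            genotypes = (
                read_vcf(config.genotypes)
                if config.genotypes.endswith(".vcf")
                else read_genotype_tsv(config.genotypes)
            )
            phenotypes = read_phenotypes(config.phenotypes)
            log.info("loaded cohort: %d samples, %d markers",
                     genotypes.n_samples, genotypes.n_variants)
        else:
            genotypes, phenotypes = simulate.simulate_cohort(config.simulation_config())
            write_vcf(genotypes, os.path.join(out_dir, "genotypes.vcf"))
            write_phenotypes(phenotypes, os.path.join(out_dir, "phenotypes.tsv"))
            log.info("simulated cohort: %d samples, %d markers, %d events",
                     genotypes.n_samples, genotypes.n_variants,
                     int(phenotypes["bcr_event"].sum()))
        report["stages"][stage] = {
            "n_samples": genotypes.n_samples,
            "n_markers": genotypes.n_variants,
            "n_events": int(phenotypes["bcr_event"].sum()),
        }

        # ---------------- qc ----------------
        stage = "qc"
        genotypes, qc_report = qc.apply_qc(genotypes, config.qc_thresholds())
        qc_report.markers.to_csv(os.path.join(out_dir, "qc_markers.tsv"), sep="\t", index=False)
        qc_report.samples.to_csv(os.path.join(out_dir, "qc_samples.tsv"), sep="\t", index=False)
        keep = phenotypes["sample_id"].isin(genotypes.sample_ids)
        phenotypes = phenotypes[keep].reset_index(drop=True)
        write_genotype_tsv(genotypes, os.path.join(out_dir, "genotypes_qc.tsv"))
        log.info("QC: %s", qc_report.summary)
        report["stages"][stage] = qc_report.summary

        # ---------------- association ----------------
        stage = "assoc"
        results = run_association(genotypes, phenotypes, method=config.assoc_method)
        _assoc_table(results).to_csv(os.path.join(out_dir, "association.tsv"),
                                     sep="\t", index=False)
        manhattan_frame(results).to_csv(os.path.join(out_dir, "manhattan.tsv"),
                                        sep="\t", index=False)
        selected = select_snps(results, alpha=config.alpha)
        _assoc_table(selected).to_csv(os.path.join(out_dir, "selection.tsv"),
                                      sep="\t", index=False)
        log.info("association: %d markers tested, %d selected at p < %g",
                 len(results), len(selected), config.alpha)
        report["stages"][stage] = {"n_tested": len(results), "n_selected": len(selected)}

        # ---------------- scoring ----------------
        stage = "score"
        model = grs.build_model(selected, alpha_used=config.alpha)
        grs.write_model(model, os.path.join(out_dir, "grs_model.tsv"))
        scores = grs.score_samples(genotypes, model, cutoff=config.grs_cutoff)
        grs.write_scores(scores, os.path.join(out_dir, "grs_scores.tsv"))
        by_event = scores.merge(phenotypes[["sample_id", "bcr_event"]], on="sample_id")
        medians = by_event.groupby("bcr_event")["grs"].median()
        report["stages"][stage] = {
            "n_snps": len(model.entries),
            "median_grs": float(scores["grs"].median()),
            "median_grs_no_bcr": float(medians.get(0, math.nan)),
            "median_grs_bcr": float(medians.get(1, math.nan)),
            "n_high": int((scores["group"] == "high").sum()),
            "n_low": int((scores["group"] == "low").sum()),
        }
        log.info("scoring: %s", report["stages"][stage])

        # ---------------- survival ----------------
        stage = "survival"
        merged = phenotypes.merge(scores, on="sample_id")
        times = merged["followup_months"].to_numpy()
        events = merged["bcr_event"].to_numpy()
        for label in ("high", "low"):
            mask = (merged["group"] == label).to_numpy()
            if mask.any():
                km_estimate(times[mask], events[mask]).to_frame().to_csv(
                    os.path.join(out_dir, f"km_{label}.tsv"), sep="\t", index=False
                )
        chi2, p_lr = logrank_test(times, events, merged["group"].to_numpy())
        clinical, genetic = fit_bcr_models(
            phenotypes, scores,
            gleason_coding=config.gleason_coding, ties_method=config.ties_method,
        )
        _cox_table(clinical).to_csv(os.path.join(out_dir, "cox_clinical.tsv"),
                                    sep="\t", index=False)
        _cox_table(genetic).to_csv(os.path.join(out_dir, "cox_clinico_genetic.tsv"),
                                   sep="\t", index=False)
        grs_row = genetic.summary().set_index("covariate").loc["grs"]
        report["stages"][stage] = {
            "logrank_chi2": chi2,
            "logrank_p": p_lr,
            "grs_hr": float(grs_row["hr"]),
            "grs_hr_ci": [float(grs_row["ci_low"]), float(grs_row["ci_high"])],
            "grs_p": float(grs_row["p"]),
        }
        log.info("survival: %s", report["stages"][stage])

        # ---------------- evaluation ----------------
        stage = "evaluate"
        probs = fit_evaluation_models(phenotypes, scores,
                                      gleason_coding=config.gleason_coding)
        y = probs["bcr_event"].to_numpy()
        roc_points(probs["p_clinical"], y).to_csv(
            os.path.join(out_dir, "roc_clinical.tsv"), sep="\t", index=False)
        roc_points(probs["p_genetic"], y).to_csv(
            os.path.join(out_dir, "roc_clinico_genetic.tsv"), sep="\t", index=False)
        cmp = compare_auc_paired(
            probs["p_clinical"], probs["p_genetic"], y,
            method=config.auc_method, seed=config.seed,
        )
        pd.DataFrame([dataclasses.asdict(cmp)]).to_csv(
            os.path.join(out_dir, "auc_comparison.tsv"), sep="\t", index=False)
        report["stages"][stage] = {
            "auc_clinical": cmp.auc_clinical,
            "auc_clinico_genetic": cmp.auc_genetic,
            "auc_diff": cmp.auc_diff,
            "p_value": cmp.p_value,
        }
        log.info("evaluation: %s", report["stages"][stage])

    except GrsurvError as exc:
        _write_report()
        log.error("stage %s failed: %s", stage, exc)
        log.removeHandler(handler)
        handler.close()
        raise StageError(stage, exc) from exc
    _write_report()
    log.removeHandler(handler)
    handler.close()
    return report
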